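"""Cohort demographics and clinical statistics from the packaged table.

Reports per-arm age and course summaries, the pooled between-group t
tests, and the paired T0-vs-T2 test on total CRS-R across all 21
patients.
"""

import argparse
from pathlib import Path

import pandas as pd

from msdoc import cohort_fixture
from msdoc.pipeline import format_cohort_report, report_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--table", type=Path, default=None,
                    help="optional external cohort CSV (defaults to packaged)")
    ap.add_argument("--out", type=Path, default=Path("results/cohort_stats.csv"))
    args = ap.parse_args()

    cohort = pd.read_csv(args.table) if args.table else cohort_fixture()
    rep = report_cohort(cohort)
    print(format_cohort_report(rep))

    rows = []
    for key in ("age_test", "course_test", "sex_test", "crsr_test"):
        if key in rep:
            r = rep[key]
            rows.append({"comparison": key, "method": r.method,
                         "statistic": r.statistic, "df": r.df, "p": r.p})
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"tidy test table written to {args.out}")


if __name__ == "__main__":
    main()
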