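patient_id,group,sex,age,etiology,course_days,crsr_t0,diagnosis_t0,crsr_t1,diagnosis_t1,crsr_t2,diagnosis_t2,followup_3mo
RE1,RE,M,52,Trauma,84,11,MCS+,11,MCS+,12,MCS+,EMCS
RE2,RE,F,49,HIE,30,6,MCS-,7,MCS-,15,MCS+,EMCS
RE3,RE,M,53,Trauma,34,5,MCS-,7,MCS-,14,MCS+,EMCS
RE4,RE,F,74,Hemorrhage,101,11,MCS+,11,MCS+,15,MCS+,Dead
RE5,RE,M,49,Hemorrhage,50,5,VS,6,VS,7,VS,VS
RE6,RE,M,55,Trauma,302,6,VS,6,VS,8,MCS-,MCS-
RE7,RE,M,72,CI,42,5,MCS-,5,MCS-,9,MCS+,MCS+
RE8,RE,M,47,Hemorrhage,29,6,VS,6,VS,12,MCS+,MCS+
RE9,RE,M,58,Trauma,53,9,MCS-,9,MCS-,10,MCS-,EMCS
RE10,RE,F,68,Hemorrhage,30,8,MCS-,9,MCS+,15,MCS+,MCS+
RE11,RE,M,59,CI,68,5,VS,5,VS,6,MCS+,MCS+
RE12,RE,M,72,CI,200,2,VS,2,VS,4,VS,VS
N-RE1,N-RE,M,54,Hemorrhage,73,6,VS,6,VS,6,VS,VS
N-RE2,N-RE,M,56,HIE,41,2,VS,2,VS,2,VS,VS
N-RE3,N-RE,F,39,HIE,128,4,VS,4,VS,4,VS,VS
N-RE4,N-RE,M,18,Disseminated encephalomyelitis,48,4,VS,4,VS,4,VS,MCS-
N-RE5,N-RE,M,56,Hemorrhage,88,3,VS,3,VS,3,VS,VS
N-RE6,N-RE,M,64,Hemorrhage,34,10,MCS-,10,MCS-,10,MCS-,MCS-
N-RE7,N-RE,F,70,CI,58,4,VS,4,VS,4,VS,MCS+
N-RE8,N-RE,F,39,HIE,215,3,VS,3,VS,3,VS,VS
N-RE9,N-RE,M,57,Hemorrhage,52,6,VS,6,VS,6,VS,MCS+
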