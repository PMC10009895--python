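subject_id,diagnosis,years_to_first_met,age,ecog,tnm_stage,grade,er_pr,her2
A001,Breast,3.5,73,1,T1N0M0,3,Neg/Neg,+
A002,Breast,0,58.7,1,T2N3M1,2,ER+/PR+,-
A003,Ovarian,24,72.2,1,T4,,NA,+
B001,Breast,0,60.8,2,T2NXM1,2,ER+/PR+,-
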