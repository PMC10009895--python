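term,n_patients,grade_range
Back pain,3,1-3
Constipation,2,1-2
Itch,2,2-3
Fatigue,2,2
Anemia,1,2
Colitis,1,3
Coughing,1,2
Diarrhea,1,2
Diverticulosis,1,2
Fever,1,2
Hemorrhoids,1,2
Induration at inoculation sites,1,2
Mucus plug,1,1
Nausea,1,1
Positional vertigo,1,1
Rash,1,3
Redness,1,2
Slight cough,1,1
Urinate frequently,1,2
Weakness,1,2
Wheel and flare,1,2
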