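subject_id,n_inoculations_series1,days_on_treatment_series1,ttp_series1,dx_to_rx_years,survival_months,tumor_regression,retreated,n_inoculations_series23,days_on_treatment_series23,ttp_series23
A001,5,98,128,6,40.7,False,False,,,
A002,6,117,223,2,33.7,True,True,13,229,160
A003,5,91,159,33,35.6,False,False,,,
B001,4,58,64,10,7.0,False,False,,,
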