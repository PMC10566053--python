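id,age,psa_ng_ml,family_history,prior_negative_biopsy,abnormal_dre,risk_group,gleason_sum,cohort
S0001,72,9.19,0,0,0,benign,,training
S0002,71,3.85,0,1,0,benign,,training
S0003,82,9.47,0,0,1,VLR,6.0,training
S0004,84,8.12,0,0,0,FIR,7.0,training
S0005,53,16.4,0,1,0,UIR,7.0,training
S0006,71,8.9,0,1,0,VHR,8.0,training
S0007,65,36.93,0,0,1,mPC,9.0,training
S0008,76,7.58,0,1,0,benign,,validation
S0009,73,6.81,1,1,0,UIR,7.0,validation
S0010,56,5.05,0,0,0,VHR,8.0,validation
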