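id,urine_creatinine
S0001,1.5507138382807355
S0002,0.4582537817052798
S0003,0.49643622247528446
S0004,1.217636413556382
S0005,1.5852509849979144
S0006,1.028501639829986
S0007,1.9653208442638264
S0008,1.4369206927504825
S0009,1.5763995125113377
S0010,0.8564305789834751
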