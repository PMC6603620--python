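name,p_value
MQ-2,0.000000e+00
MQ-3,0.000000e+00
MQ-4,0.000000e+00
MQ-5,0.000000e+00
MQ-6,0.000000e+00
MQ-7,0.000000e+00
MQ-8,0.000000e+00
MQ-9,0.000000e+00
MQ-135,3.725089e-01
TGS822,9.494413e-02
TGS2600,0.000000e+00
TGS2602,0.000000e+00
TGS2603,0.000000e+00
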