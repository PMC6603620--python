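name,sensitive_gases,load_resistance_ohm,alpha0,alpha1,beta0,beta1,delta,xi,fit_r2
MQ-2,H2;LPG;CH4;CO;ethanol;propane;butane;methane,10000,-0.0266,0.0003,-0.0023,0.0000,0.0000,1.4700,0.9989
MQ-3,ethanol;benzene;CH4;hexane;LPG;CO,10000,-0.0229,0.0002,-0.0036,0.0000,0.0000,1.4640,0.9960
MQ-4,LPG;CH4;H2;CO;ethanol,10000,-0.0103,0.0001,-0.0033,0.0000,0.0000,1.2760,0.9970
MQ-5,H2;LPG;CH4;CO;ethanol;isobutane;propane,10000,-0.0145,0.0001,-0.0040,0.0000,0.0000,1.3350,0.9881
MQ-6,LPG;H2;CH4;CO;ethanol;isobutane;propane,10000,-0.0126,0.0001,-0.0034,0.0000,0.0000,1.2920,0.9941
MQ-7,CO;H2;LPG;CH4;ethanol,10000,-0.0157,0.0001,-0.0036,0.0000,0.0000,1.3580,0.9876
MQ-8,H2;LPG;CH4;CO;ethanol,10000,-0.0106,0.0001,-0.0012,0.0000,0.0000,1.0880,0.9962
MQ-9,CO;CH4;LPG,10000,-0.0158,0.0001,-0.0037,0.0000,0.0000,1.3590,0.9875
MQ-135,NH3;benzene;ethanol;CO2;CO;NH4,10000,-0.0258,0.0003,-0.0023,0.0000,0.0000,1.4660,0.9978
TGS822,acetone;n-hexane;benzene;ethanol;isobutane;CO;methane,10000,-0.0576,0.0005,-0.0179,0.0001,0.0001,2.7390,0.9910
TGS2600,H2;CO;methane;isobutane;ethanol,10000,-0.0825,0.0008,-0.0187,0.0000,0.0003,3.1140,0.9907
TGS2602,H2;NH3;ethanol;H2S;toluene,10000,-0.0566,0.0004,-0.0070,0.0000,0.0001,2.2480,0.9944
TGS2603,H2;H2S;ethanol;methyl mercaptan;trimethylamine,10000,-0.0400,0.0002,0.0000,0.0000,0.0000,1.7310,0.9980
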