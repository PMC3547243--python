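model_id,target,variant,intercept,terms,coefficients,r2
SS2,SS,two_variable,61.55,Temp_6;Hum_10,-1.34;0.59,0.620
SS1,SS,one_variable,102.94,Temp_6,-1.51,0.412
SE2,SE,two_variable,168.86,Temp_M23;Rain_12,-7.27;3.35,0.649
SE1,SE,one_variable,184.12,Temp_M23,-8.23,0.462
PC2,PC,two_variable,-1337.96,Cloud_6;Hum_4,-26.45;48.02,0.485
PC1,PC,one_variable,2414.9,Cloud_6,-24.95,0.279
PD2,PD,two_variable,121.85,Temp_9;Temp_6,-2.16;-0.97,0.524
PD1,PD,one_variable,119.65,Temp_9,-1.96,0.325
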