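model_id,target,variant,r2,year,observed,expected,difference
SS2,SS,two_variable,0.620,2009,97,98,-1
SS2,SS,two_variable,0.620,2010,94,99,-5
SS1,SS,one_variable,0.412,2009,97,104,-7
SS1,SS,one_variable,0.412,2010,94,97,-3
SE2,SE,two_variable,0.649,2009,128,129,-1
SE2,SE,two_variable,0.649,2010,120,126,-6
SE1,SE,one_variable,0.462,2009,128,121,7
SE1,SE,one_variable,0.462,2010,120,128,-8
PC2,PC,two_variable,0.485,2009,173,831,-658
PC2,PC,two_variable,0.485,2010,1200,641,559
PC1,PC,one_variable,0.279,2009,173,502,-329
PC1,PC,one_variable,0.279,2010,1200,866,334
PD2,PD,two_variable,0.524,2009,107,113,-6
PD2,PD,two_variable,0.524,2010,106,97,9
PD1,PD,one_variable,0.325,2009,107,111,-4
PD1,PD,one_variable,0.325,2010,106,100,6
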