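variable,mean,sd,n
protein,3.54,0.15,15
fat,3.95,0.24,15
ts,13.24,0.51,15
snf,9.33,0.35,15
lactose,5.06,0.21,15
density,1032,1,15
fpd,0.543,0.022,15
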