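provenance,bound,protein,fat,ts,snf,lactose,density,fpd
measured,lower,3.33,3.60,12.57,8.94,4.80,1031,0.516
measured,upper,3.73,4.42,14.03,9.85,5.39,1035,0.576
variance_adjusted,lower,3.13,3.26,11.90,8.55,4.54,1030,0.489
variance_adjusted,upper,3.93,4.90,14.82,10.37,5.72,1038,0.608
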