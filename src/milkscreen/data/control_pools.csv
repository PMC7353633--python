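pool_id,quality,region,protein,fat,ts,snf,lactose,density,fpd
A,premium,North,3.69,4.05,13.72,9.73,5.30,1034,0.567
B,normal,North,3.44,3.75,12.79,9.05,4.88,1031,0.524
C,normal,South,3.47,3.83,13.04,9.24,5.04,1032,0.544
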