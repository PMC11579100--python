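ID,TIME,AMT,RATE,EVID,DV,CMT,DOSE_NR
1,0,1,-2,1,0,1,1
1,12,1,-2,1,0,1,1
1,6,0,0,2,0,1,0
1,24,0,0,0,0,1,0
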