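ID,TIME,AMT,RATE,EVID,DV,CMT,DOSE_NR
1,12,1,0,1,0,1,1
1,13,1,0,1,0,1,1
1,14,1,0,1,0,1,1
1,15,1,0,1,0,1,1
1,16,1,0,1,0,1,2
1,17,1,0,1,0,1,2
1,18,1,0,1,0,1,2
1,19,1,0,1,0,1,2
1,20,1,0,1,0,1,3
1,21,1,0,1,0,1,3
1,22,1,0,1,0,1,3
1,23,1,0,1,0,1,3
1,24,1,0,1,0,1,4
1,25,1,0,1,0,1,4
1,26,1,0,1,0,1,4
1,27,1,0,1,0,1,4
1,32,0,0,0,0,1,0
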