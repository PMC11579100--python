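ID,TIME,AMT,RATE,EVID,DV,CMT,DOSE_NR
1,0,1,0,1,0,1,1
1,1,1,0,1,0,1,1
1,2,1,0,1,0,1,1
1,3,1,0,1,0,1,1
1,4,1,0,1,0,1,1
1,5,1,0,1,0,1,1
1,6,1,0,1,0,1,1
1,7,1,0,1,0,1,2
1,8,1,0,1,0,1,2
1,9,1,0,1,0,1,2
1,10,1,0,1,0,1,2
1,11,1,0,1,0,1,2
1,12,1,0,1,0,1,2
1,13,1,0,1,0,1,2
1,14,1,0,1,0,1,3
1,15,1,0,1,0,1,3
1,16,1,0,1,0,1,3
1,17,1,0,1,0,1,3
1,18,1,0,1,0,1,3
1,19,1,0,1,0,1,3
1,20,1,0,1,0,1,3
1,21,1,0,1,0,1,4
1,22,1,0,1,0,1,4
1,23,1,0,1,0,1,4
1,24,1,0,1,0,1,4
1,25,1,0,1,0,1,4
1,26,1,0,1,0,1,4
1,27,1,0,1,0,1,4
1,28,1,0,1,0,1,5
1,29,1,0,1,0,1,5
1,30,1,0,1,0,1,5
1,31,1,0,1,0,1,5
1,32,1,0,1,0,1,5
1,33,1,0,1,0,1,5
1,34,1,0,1,0,1,5
1,35,1,0,1,0,1,6
1,36,1,0,1,0,1,6
1,37,1,0,1,0,1,6
1,38,1,0,1,0,1,6
1,39,1,0,1,0,1,6
1,40,1,0,1,0,1,6
1,41,1,0,1,0,1,6
1,14,0,0,2,0,1,0
1,42,0,0,0,0,1,0
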