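patient_no,pre_hours,pre_postures,post_hours,post_postures
1,14.5,17,3,2
2,16,1,14.5,1
5,9.3,3,23,8
6,9.5,3,9,4
7,15,7,15.8,2
8,20.4,6,22,12
9,23.4,9,22.5,22
10,9,5,25,10
11,51,31,23,1
12,45,5,27.5,15
13,34.5,5,24,14
15,19,5,22.5,2
16,45.3,37,40.8,8
17,22,6,34.5,13
18,35,9,11.7,1
19,13.5,6,17.3,11
22,14.5,15,15.3,5
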