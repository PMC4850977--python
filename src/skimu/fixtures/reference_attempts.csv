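attempt,trial,self_assessment,total_duration_s
1,1,2.5,13.85
2,,3.5,
3,2,3.5,10.71
4,3,4.5,11.42
5,4,5,11.23
6,5,5,10.48
7,6,5,11.13
8,7,5,10.71
9,8,6,10.80
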