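weight,interpretation,n_districts
N/A,Insufficient data for analysis,4
0,No loss in health,0
1,One indicator is worse than predicted; impact minimal,3
2,Two indicators worse than predicted; impact minimal,8
3,Three indicators worse than predicted; impact noticeable,7
4,All indicators worse than predicted; impact high,3
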