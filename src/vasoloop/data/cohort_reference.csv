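animal,pct_lt60,pct_60_70,pct_70_80,pct_gt80
1,16.9,76.5,6.7,0.0
2,8.6,77.3,13.3,0.8
3,5.1,85.5,9.4,0.0
4,15.3,80.8,3.9,0.0
5,26.3,66.7,7.1,0.0
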