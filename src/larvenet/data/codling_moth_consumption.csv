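instar,duration_days,cumulative_mg
1,3.54,0.588
2,3.27,2.713
3,3.27,8.001
4,4.5,37.667
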