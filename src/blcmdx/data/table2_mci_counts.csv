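MoCA,MMSE,ADAS-cog,count
1,1,1,193
1,1,0,52
1,0,1,75
1,0,0,76
0,1,1,84
0,1,0,115
0,0,1,112
0,0,0,404
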