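MoCA,MMSE,ADAS-cog,count
1,1,1,185
1,1,0,40
1,0,1,32
1,0,0,82
0,1,1,32
0,1,0,72
0,0,1,44
0,0,0,802
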