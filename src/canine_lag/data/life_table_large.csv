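age,lx,mx,lxmx
2,0.9818,8.3,8.1358
3,0.9754,8.5,8.3137
4,0.9675,8.3,8.0173
5,0.9500,8.3,7.8723
6,0.9357,7.8,7.3107
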