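age,lx,mx,lxmx
2,0.9620,8.8,8.4272
3,0.9494,9.0,8.5416
4,0.9359,8.5,7.9770
5,0.8914,7.5,6.6480
6,0.8320,6.3,5.2201
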