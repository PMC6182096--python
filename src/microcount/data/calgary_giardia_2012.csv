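sample_id,count,volume_liters
1,1,64.4
2,0,50.2
3,0,50.0
4,0,53.2
5,0,50.2
6,0,50.4
7,0,50.4
8,2,50.7
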