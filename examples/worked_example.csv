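record_id,value
0,16
1,12
2,11
3,10
4,9
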