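category,percent
0,23.75
1,27.06
2,21.49
3,13.38
4+,14.33
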