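round,transition1_mm,transition2_mm,transition3_mm
1,1.32,1.69,2.08
2,0.85,1.36,1.70
3,1.22,1.57,1.89
4,0.93,1.48,1.77
5,1.04,1.19,1.58
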