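group,step_count_measured,step_count_calculated,stride_length_measured_m,stride_length_calculated_m,cadence_measured_spm,cadence_calculated_spm
1,16,16,1.13,1.02,98,100
2,15,16,1.20,1.31,105,103
3,18,18,1.00,1.09,99,101
4,16,16,1.13,1.08,102,105
5,15,14,1.20,1.28,101,103
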