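rat,fdg_pct,rbc_pct,ttc_pct
1,24.38,37.19,25.97
2,29.19,29.49,26.28
3,25.46,32.85,23.58
4,29.26,29.81,21.35
5,27.46,35.39,31.90
6,25.62,38.64,27.04
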