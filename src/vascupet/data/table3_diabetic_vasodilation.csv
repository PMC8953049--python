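rat,stress_activity,rest_activity,stress_rest_difference,increased_ratio
1,3386.60,3042.22,410.54,13.40
2,14225.28,14026.88,2195.59,15.56
3,18781.97,15579.75,3796.07,24.37
4,6124.33,5829.02,1084.05,18.59
5,7063.27,5778.81,1284.46,22.20
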