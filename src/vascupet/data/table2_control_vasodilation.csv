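rat,stress_activity,rest_activity,stress_rest_difference,increased_ratio
1,2496.72,2008.44,635.04,31.62
2,14927.50,9340.60,6061.95,32.49
3,12271.33,9568.55,3108.66,41.00
4,20315.93,14905.81,5483.70,36.79
5,46501.94,34927.14,11760.07,33.70
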