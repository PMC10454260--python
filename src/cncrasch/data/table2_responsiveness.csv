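version,n,mean_baseline,sd_baseline,mean_followup,sd_followup,sd_pooled,reliability,sem,effect_size,es_ci_lower,es_ci_upper,srm
8item,40,-0.80,1.4,-0.43,1.1,1.25,0.87,0.45,0.29,-0.03,0.61,0.29
10item,40,-0.72,1.2,-0.43,1.0,1.12,0.89,0.37,0.26,-0.12,-0.57,0.24
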