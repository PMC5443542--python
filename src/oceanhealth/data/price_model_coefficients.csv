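group,term,estimate,std_error
inuit,intercept,1262,423
inuit,rnfb,0.625,0.239
inuit,rnfb_dist,0.035,0.017
inuit,iccpi,-10.89,4.01
inuit,iccpi_dist,0.024,0.018
inuit,population,-0.007,0.004
inuit,adj_r2,0.49,
inuit,f_statistic,9.13,
first_nations,intercept,1606,413
first_nations,iccpi,-12.86,4.05
first_nations,iccpi_dist,0.048,0.011
first_nations,population,-0.006,0.004
first_nations,adj_r2,0.42,
first_nations,f_statistic,11.51,
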