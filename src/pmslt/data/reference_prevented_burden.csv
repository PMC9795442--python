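metric,scenario,men,men_lo,men_hi,women,women_lo,women_hi,total,total_lo,total_hi
cases,S1_half_rate,3800,1966,5491,3600,1606,5326,7400,3572,10817
cases,S2_freeze,7800,4039,11273,7400,3302,10949,15200,7341,22222
cases,S3_reduce_prevalence,14800,7565,21281,15000,6266,22164,29800,13831,43445
deaths,S1_half_rate,700,357,1079,500,204,739,1200,560,1818
deaths,S2_freeze,1500,731,2213,1000,418,1518,2500,1150,3731
deaths,S3_reduce_prevalence,2800,1378,4179,2100,846,3104,4900,2224,7283
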