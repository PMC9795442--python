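group,men,men_lo,men_hi,women,women_lo,women_hi,total,total_lo,total_hi
cardiovascular,229100,108276,341508,153200,54863,231693,382300,35147,145237
cancers,37500,16906,57904,32300,10411,53811,69800,27317,111715
diabetes,1234100,696247,1643196,1274500,590052,1736674,2508600,1286299,3376871
chronic_kidney_disease,650400,293578,1020088,847200,304568,1355780,1497600,598146,2375868
cirrhosis,80500,44227,112980,41100,18690,59470,121600,62917,172450
Total,2575800,1329367,3682811,2688300,1111856,3947112,5264100,2441223,7629923
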