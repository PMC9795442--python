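group,men,men_lo,men_hi,women,women_lo,women_hi,total,total_lo,total_hi
cardiovascular,271000,130317,405517,208300,46210,175634,479300,210400,720800
cancers,26300,11843,40381,17000,5765,28235,43300,17608,69067
diabetes,67600,37593,91355,74700,34526,101672,142300,72119,193026
chronic_kidney_disease,35000,15720,55314,30000,11043,48053,65000,26763,103367
cirrhosis,58000,29614,82080,20700,8494,30017,78700,38108,112097
Total,458000,225086,675098,350600,1393892,523261,808600,364978,1198360
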