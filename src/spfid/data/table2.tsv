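id	length_bp	total_reads	unique_reads
SPF1	606	219895	115913
SPF2	609	163836	79980
SPF3	609	163675	86470
SPF4	609	161093	161012
SPF5	609	143476	72954
SPF6	615	120335	120335
SPF7	609	75756	26748
SPF8	609	63077	25759
SPF9	609	33603	11438
SPF10	594	5147	3911
SPF11	594	2352	1719
SPF12	642	530	248
SPF13	642	494	234
SPF14	594	302	302
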