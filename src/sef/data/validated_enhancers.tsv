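ecr	zf_region	mm_region	shared_nmers
6	chr2:39,790,777-39,791,782	chr1:77,387,974-77,389,004	29
7	chr2:39,792,312-39,793,241	chr1:77,390,034-77,391,031	23
10	chr9:22,365,926-22,366,799	chr14:58,234,894-58,235,874	19
11	chr9:22,368,460-22,369,405	chr14:58,234,894-58,235,874	14
12	chr14:41,645,428-41,646,386	chrX:130,162,955-130,163,923	40
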