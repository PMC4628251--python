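ecr	species	construct	tissue	time_hpf
1	zf	zf1	spinal cord	48
2	zf	zf2	epidermis	24
2	zf	zf2	epidermis	48
3	zf	zf3	tail bud	24
3	zf	zf3	eye	48
3	zf	zf3	heart	48
4	zf	zf4	notochord	24
4	zf	zf4	notochord	48
5	zf	zf5	epidermis	24
5	zf	zf5	epidermis	48
6	zf	zf6	epidermis	24
6	zf	zf6	epidermis	48
6	zf	zf6	otic vesicle	24
6	zf	zf6	otic vesicle	48
6	zf	zf6	somitic muscle	24
6	zf	zf6	somitic muscle	48
6	mm	mm6	epidermis	24
6	mm	mm6	epidermis	48
6	mm	mm6	notochord	24
6	mm	mm6	olfactory epithelium	24
6	mm	mm6	olfactory epithelium	48
6	mm	mm6	spinal cord	24
6	mm	mm6	otic vesicle	48
6	mm	mm6	pectoral fin	48
7	zf	zf7	hindbrain	24
7	zf	zf7	hindbrain	48
7	zf	zf7	olfactory epithelium	24
7	zf	zf7	olfactory epithelium	48
7	mm	mm7	eye	24
7	mm	mm7	eye	48
7	mm	mm7	olfactory bulb	24
7	mm	mm7	olfactory bulb	48
7	mm	mm7	hindbrain	24
7	mm	mm7	hindbrain	48
8	zf	zf8	somitic muscle	24
8	zf	zf8	somitic muscle	48
8	zf	zf8	olfactory epithelium	48
8	zf	zf8	hindbrain	48
9	zf	zf9	spinal cord	24
9	zf	zf9	spinal cord	48
9	mm	mm9a	midbrain	24
9	mm	mm9a	yolk	24
9	mm	mm9b	somitic muscle	24
9	mm	mm9b	somitic muscle	48
9	mm	mm9b	skin under yolk	24
9	mm	mm9b	skin under yolk	48
9	mm	mm9b	pharyngeal arches	48
9	mm	mm9b	pectoral fin	48
10	zf	zf10	somitic muscle	24
10	zf	zf10	somitic muscle	48
10	zf	zf10	olfactory epithelium	48
10	mm	mm10_11	somitic muscle	24
10	mm	mm10_11	somitic muscle	48
10	mm	mm10_11	pericardium	24
10	mm	mm10_11	pericardium	48
11	zf	zf11	hindbrain	24
11	zf	zf11	somitic muscle	24
11	zf	zf11	somitic muscle	48
11	zf	zf11	heart	48
11	mm	mm10_11	somitic muscle	24
11	mm	mm10_11	somitic muscle	48
11	mm	mm10_11	pericardium	24
11	mm	mm10_11	pericardium	48
12	zf	zf12	epidermis	24
12	zf	zf12	epidermis	48
12	zf	zf12	otic vesicle	24
12	zf	zf12	otic vesicle	48
12	zf	zf12	yolk	24
12	zf	zf12	yolk	48
12	mm	mm12	epidermis	24
12	mm	mm12	olfactory epithelium	24
13	zf	zf13	hindbrain	24
13	zf	zf13	olfactory epithelium	24
13	zf	zf13	olfactory epithelium	48
13	zf	zf13	line under eye	24
13	zf	zf13	line under eye	48
13	zf	zf13	spinal cord	48
13	mm	mm13	spinal cord	24
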