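module_id	name	step_index	alternatives
M_HIS	histidine biosynthesis	0	K00765
M_HIS	histidine biosynthesis	1	K01496
M_HIS	histidine biosynthesis	2	K01814
M_HIS	histidine biosynthesis	3	K02500,K02501
M_HIS	histidine biosynthesis	4	K01693
M_HIS	histidine biosynthesis	5	K00817
M_HIS	histidine biosynthesis	6	K00013
M_THI	thiamine biosynthesis	0	K03147
M_THI	thiamine biosynthesis	1	K00788
M_THI	thiamine biosynthesis	2	K00941
M_THI	thiamine biosynthesis	3	K00878
M_THI	thiamine biosynthesis	4	K03149
M_BIO	biotin biosynthesis	0	K00652
M_BIO	biotin biosynthesis	1	K00833
M_BIO	biotin biosynthesis	2	K01935
M_BIO	biotin biosynthesis	3	K01012
M_NOS	nitrous oxide reduction	0	K00376
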