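subject	group	timepoint	vintage_months	weight_change_kg
hd01	hd	1	67.43	-2.279
hd02	hd	1	40.06	-1.165
hd03	hd	1	59.73	-1.709
hd04	hd	1	55.26	-0.97
hd05	hd	1	53.75	-1.547
hd06	hd	1	8.84	-2.152
hd07	hd	1	46.33	-1.958
hd08	hd	1	31.65	-1.698
hd09	hd	1	68.3	-2.548
hd10	hd	1	66.56	-0.535
control01	control	1		
control02	control	1		
control03	control	1		
control04	control	1		
control05	control	1		
control06	control	1		
control07	control	1		
control08	control	1		
control09	control	1		
control10	control	1		
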