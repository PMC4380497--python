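roi	tissue	effect	estimate	se	p	d	band	flagged	note	p_adjusted
parietal	wm	group	1.7245354999999984	0.44445211726550665	0.00010439726343512722	1.6892242060534606	large	False		0.0004175890537405089
parietal	wm	time	-0.11212379999999919	0.07998832471133256	0.16098929471314039			False		0.6439571788525615
parietal	wm	group:time	0.13933919999999783	0.11312057363826948	0.218032796351743			False		0.872131185406972
parietal	gm	group	1.8953165000000924	0.4017178950152649	2.3814107417576647e-06	2.0348456867471683	large	False		9.525642967030659e-06
parietal	gm	time	0.1705999000000005	0.09397821773546207	0.06947579024381471			False		0.27790316097525886
parietal	gm	group:time	-0.22278139999999944	0.13290527008914219	0.09369079424094262			False		0.3747631769637705
frontal	wm	group	1.9418759999999737	0.44030320428625025	1.0322016970561274e-05	1.8309440845170695	large	False		4.1288067882245095e-05
frontal	wm	time	-0.013280499999999062	0.08909401381197399	0.8815049928490006			False		1.0
frontal	wm	group:time	0.0034239999999982843	0.12599796265914945	0.9783201214907902			False		1.0
frontal	gm	group	1.9486531999999541	0.3924559514969293	6.860245934563535e-07	2.210592140395375	large	False		2.744098373825414e-06
frontal	gm	time	0.23399790000000298	0.0909977342573211	0.010126792922566786			False		0.040507171690267144
frontal	gm	group:time	-0.20256840000000145	0.12869022993192628	0.1154695253038946			False		0.4618781012155784
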