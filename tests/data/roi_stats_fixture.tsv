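subject	group	timepoint	roi	tissue	mean_water	sd_water	n_voxels
hd01	hd	1	parietal	wm	73.547411	1.513439	820
hd01	hd	1	parietal	gm	85.815373	1.862057	347
hd01	hd	1	frontal	wm	73.97614	1.627952	780
hd01	hd	1	frontal	gm	85.491993	1.796881	670
hd01	hd	2	parietal	wm	73.835754	1.662304	339
hd01	hd	2	parietal	gm	85.626262	1.241782	885
hd01	hd	2	frontal	wm	73.670835	1.680613	760
hd01	hd	2	frontal	gm	85.606717	1.532758	565
hd02	hd	1	parietal	wm	72.212126	1.554452	530
hd02	hd	1	parietal	gm	84.283082	1.544989	833
hd02	hd	1	frontal	wm	72.629914	1.367265	592
hd02	hd	1	frontal	gm	84.117646	1.308415	878
hd02	hd	2	parietal	wm	72.540616	1.412099	422
hd02	hd	2	parietal	gm	83.920431	1.080361	843
hd02	hd	2	frontal	wm	72.425237	1.266947	575
hd02	hd	2	frontal	gm	84.567802	1.47704	708
hd03	hd	1	parietal	wm	71.889539	1.767054	850
hd03	hd	1	parietal	gm	84.857355	1.32672	500
hd03	hd	1	frontal	wm	71.875311	1.620583	635
hd03	hd	1	frontal	gm	84.593356	1.346922	552
hd03	hd	2	parietal	wm	71.759645	1.365679	698
hd03	hd	2	parietal	gm	84.944495	1.339872	611
hd03	hd	2	frontal	wm	72.063427	1.583517	660
hd03	hd	2	frontal	gm	84.549879	1.408661	304
hd04	hd	1	parietal	wm	74.887328	1.452497	758
hd04	hd	1	parietal	gm	84.467332	1.447836	781
hd04	hd	1	frontal	wm	74.834335	1.537922	414
hd04	hd	1	frontal	gm	84.508256	1.745674	561
hd04	hd	2	parietal	wm	74.567674	1.404329	528
hd04	hd	2	parietal	gm	84.457972	1.572176	431
hd04	hd	2	frontal	wm	74.530402	1.504666	860
hd04	hd	2	frontal	gm	84.213767	1.361013	467
hd05	hd	1	parietal	wm	73.111714	1.578325	618
hd05	hd	1	parietal	gm	86.189141	1.433971	667
hd05	hd	1	frontal	wm	73.176874	1.964071	565
hd05	hd	1	frontal	gm	86.194591	1.513796	591
hd05	hd	2	parietal	wm	73.374222	1.17966	527
hd05	hd	2	parietal	gm	85.899957	1.474476	806
hd05	hd	2	frontal	wm	73.31994	1.532897	431
hd05	hd	2	frontal	gm	86.236235	1.535472	383
hd06	hd	1	parietal	wm	73.333676	1.317934	749
hd06	hd	1	parietal	gm	84.442851	1.490894	554
hd06	hd	1	frontal	wm	73.443323	1.602371	487
hd06	hd	1	frontal	gm	84.443031	0.928229	335
hd06	hd	2	parietal	wm	73.105081	1.470514	833
hd06	hd	2	parietal	gm	84.355692	1.550328	438
hd06	hd	2	frontal	wm	73.471552	1.580585	855
hd06	hd	2	frontal	gm	84.725772	1.173128	432
hd07	hd	1	parietal	wm	72.818633	1.649006	880
hd07	hd	1	parietal	gm	84.464131	1.370491	435
hd07	hd	1	frontal	wm	72.907814	1.612931	700
hd07	hd	1	frontal	gm	84.672731	1.678039	606
hd07	hd	2	parietal	wm	72.703019	1.549792	765
hd07	hd	2	parietal	gm	84.558485	1.689939	352
hd07	hd	2	frontal	wm	72.739598	1.612556	327
hd07	hd	2	frontal	gm	83.969899	1.677134	533
hd08	hd	1	parietal	wm	73.338435	1.845772	339
hd08	hd	1	parietal	gm	82.931268	1.629961	825
hd08	hd	1	frontal	wm	73.239673	1.151447	489
hd08	hd	1	frontal	gm	83.106649	1.575658	371
hd08	hd	2	parietal	wm	73.121622	1.619942	358
hd08	hd	2	parietal	gm	83.356255	1.640583	609
hd08	hd	2	frontal	wm	73.389076	1.289503	884
hd08	hd	2	frontal	gm	83.366021	1.104539	524
hd09	hd	1	parietal	wm	72.523993	1.272198	558
hd09	hd	1	parietal	gm	83.468162	1.53604	716
hd09	hd	1	frontal	wm	72.536895	1.161197	581
hd09	hd	1	frontal	gm	83.573583	1.639339	464
hd09	hd	2	parietal	wm	72.565895	1.45952	674
hd09	hd	2	parietal	gm	83.381207	1.477829	635
hd09	hd	2	frontal	wm	72.655914	1.208886	672
hd09	hd	2	frontal	gm	83.804569	1.946176	688
hd10	hd	1	parietal	wm	71.499619	1.561231	581
hd10	hd	1	parietal	gm	85.246122	1.738051	624
hd10	hd	1	frontal	wm	71.537405	1.542621	400
hd10	hd	1	frontal	gm	85.277557	1.36606	807
hd10	hd	2	parietal	wm	71.8611	1.595347	773
hd10	hd	2	parietal	gm	85.142246	1.638299	688
hd10	hd	2	frontal	wm	71.793138	1.245192	403
hd10	hd	2	frontal	gm	85.253027	1.325325	749
control01	control	1	parietal	wm	70.019992	1.42965	447
control01	control	1	parietal	gm	83.513379	1.819678	336
control01	control	1	frontal	wm	70.258994	1.509751	853
control01	control	1	frontal	gm	83.279292	1.472795	383
control01	control	2	parietal	wm	69.697853	1.378661	795
control01	control	2	parietal	gm	83.251254	1.404643	855
control01	control	2	frontal	wm	69.893133	1.849899	494
control01	control	2	frontal	gm	83.47228	1.535299	896
control02	control	1	parietal	wm	70.34638	1.623918	589
control02	control	1	parietal	gm	82.918756	1.763646	672
control02	control	1	frontal	wm	70.422471	1.517995	758
control02	control	1	frontal	gm	83.018039	1.518697	788
control02	control	2	parietal	wm	70.370957	1.436653	749
control02	control	2	parietal	gm	83.462772	1.458894	320
control02	control	2	frontal	wm	70.562057	1.515482	683
control02	control	2	frontal	gm	83.679568	1.500286	672
control03	control	1	parietal	wm	71.300487	1.385944	477
control03	control	1	parietal	gm	83.77485	1.569966	562
control03	control	1	frontal	wm	71.036194	1.656811	309
control03	control	1	frontal	gm	83.849651	1.523845	306
control03	control	2	parietal	wm	70.889262	1.632	631
control03	control	2	parietal	gm	84.063377	1.590463	841
control03	control	2	frontal	wm	70.919685	1.155386	328
control03	control	2	frontal	gm	84.169129	1.35126	438
control04	control	1	parietal	wm	72.294628	1.498682	469
control04	control	1	parietal	gm	82.997918	1.51042	556
control04	control	1	frontal	wm	72.349901	1.374748	838
control04	control	1	frontal	gm	82.907571	1.399063	836
control04	control	2	parietal	wm	72.32515	1.407347	669
control04	control	2	parietal	gm	82.918055	1.359374	429
control04	control	2	frontal	wm	72.334559	1.634371	578
control04	control	2	frontal	gm	82.888867	1.42723	415
control05	control	1	parietal	wm	71.9048	1.742509	713
control05	control	1	parietal	gm	81.160184	1.551421	410
control05	control	1	frontal	wm	71.362515	1.682935	428
control05	control	1	frontal	gm	81.312249	1.56922	518
control05	control	2	parietal	wm	71.446581	0.945084	763
control05	control	2	parietal	gm	81.683616	1.259612	518
control05	control	2	frontal	wm	71.511863	1.531334	383
control05	control	2	frontal	gm	81.843838	1.667863	376
control06	control	1	parietal	wm	71.391982	1.360159	619
control06	control	1	parietal	gm	82.405255	1.375116	487
control06	control	1	frontal	wm	70.865335	1.619948	827
control06	control	1	frontal	gm	82.071581	1.42325	403
control06	control	2	parietal	wm	71.081613	1.464538	327
control06	control	2	parietal	gm	82.011122	1.50477	326
control06	control	2	frontal	wm	71.111192	1.525204	318
control06	control	2	frontal	gm	82.477771	1.584357	849
control07	control	1	parietal	wm	69.13889	1.664045	346
control07	control	1	parietal	gm	81.907175	1.845701	715
control07	control	1	frontal	wm	68.609405	1.431904	634
control07	control	1	frontal	gm	81.981611	1.426481	426
control07	control	2	parietal	wm	69.25006	1.690655	538
control07	control	2	parietal	gm	82.424991	1.488553	746
control07	control	2	frontal	wm	69.173566	1.712297	847
control07	control	2	frontal	gm	82.02989	1.5825	373
control08	control	1	parietal	wm	71.073861	1.531462	694
control08	control	1	parietal	gm	83.922093	1.663356	741
control08	control	1	frontal	wm	71.266998	1.455775	331
control08	control	1	frontal	gm	83.845717	1.615789	721
control08	control	2	parietal	wm	71.299203	1.315404	649
control08	control	2	parietal	gm	84.288764	1.44593	476
control08	control	2	frontal	wm	71.359297	1.744309	396
control08	control	2	frontal	gm	83.976556	1.964717	545
control09	control	1	parietal	wm	72.493589	1.385027	781
control09	control	1	parietal	gm	82.48804	1.517557	315
control09	control	1	frontal	wm	72.2974	1.390324	799
control09	control	1	frontal	gm	82.217982	1.698416	844
control09	control	2	parietal	wm	72.396445	1.472389	517
control09	control	2	parietal	gm	82.336471	1.358267	667
control09	control	2	frontal	wm	72.106672	1.276153	434
control09	control	2	frontal	gm	82.252896	1.496292	880
control10	control	1	parietal	wm	71.95251	1.385053	634
control10	control	1	parietal	gm	82.124002	1.588956	425
control10	control	1	frontal	wm	72.269711	1.546789	856
control10	control	1	frontal	gm	82.009168	1.442068	602
control10	control	2	parietal	wm	72.038757	1.453396	579
control10	control	2	parietal	gm	82.477229	1.23412	834
control10	control	2	frontal	wm	71.634095	1.57658	416
control10	control	2	frontal	gm	82.042045	1.668372	884
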