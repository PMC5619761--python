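gene_name	gene_locus	chromosome	start	end	length_aa	mw_da	pi	subgroup
ZmGRAS1	AC198366.3	chr10	1890881	1892401	506	55337.9	7.3345	
ZmGRAS2	AC200124.3	chr6	62906676	62907011	111	12308.9	4.6744	
ZmGRAS3	AC204621.4	chr4	1274853	1275830	294	31370.6	9.6636	
ZmGRAS4	AC234164.1	chr9	24984785	24987244	630	66847	6.9353	
ZmGRAS5	GRMZM2G001426	chr3	69955114	69957195	475	50563	5.7858	
ZmGRAS6	GRMZM2G011947	chr6	55555919	55556867	304	32193.3	6.1322	
ZmGRAS7	GRMZM2G013016	chr3	166194240	166195917	538	57765.5	6.5057	
ZmGRAS8	GRMZM2G015080	chr2	150778730	150782551	678	72083.7	6.6531	
ZmGRAS9	GRMZM2G018254	chr4	513060	515231	648	71808	6.0844	
ZmGRAS10	GRMZM2G019060	chr2	209040871	209042963	586	63755.6	5.498	
ZmGRAS11	GRMZM2G023872	chr8	72494685	72496501	508	56088.1	6.3404	
ZmGRAS12	GRMZM2G024973	chr5	11793473	11795945	625	65742.6	5.0091	D9
ZmGRAS13	GRMZM2G028039	chr9	149430555	149437059	545	60793.6	6.2568	
ZmGRAS14	GRMZM2G028438	chr4	156049665	156051935	607	63032.1	8.5031	
ZmGRAS15	GRMZM2G028608	chr2	46590168	46592051	607	66678.5	6.4672	
ZmGRAS16	GRMZM2G037286	chr6	155175171	155176649	489	51240.9	6.1941	
ZmGRAS17	GRMZM2G037792	chr10	138720419	138723128	718	75350.4	6.094	
ZmGRAS18	GRMZM2G049159	chr1	40143545	40147542	734	82633.5	6.5233	
ZmGRAS19	GRMZM2G051785	chr9	27346189	27348215	507	53502	5.9579	
ZmGRAS20	GRMZM2G055263	chr1	37809278	37810975	564	59835.2	4.9556	
ZmGRAS21	GRMZM2G060265	chr1	1953455	1955531	481	51254.8	6.5752	
ZmGRAS22	GRMZM2G070371	chr2	231610740	231612552	599	67026.7	6.5602	
ZmGRAS23	GRMZM2G073779	chr4	836061	838338	686	76470.4	4.8064	
ZmGRAS24	GRMZM2G073805	chr4	832522	834779	666	73486.5	5.5435	
ZmGRAS25	GRMZM2G073823	chr4	829955	831938	642	71250.6	7.1461	
ZmGRAS26	GRMZM2G079470	chr1	88488422	88491040	645	67236.9	6.4735	
ZmGRAS27	GRMZM2G082387	chr3	150869807	150871966	447	48471	6.8274	
ZmGRAS28	GRMZM2G089636	chr6	38422200	38424095	626	71576.2	6.0342	
ZmGRAS29	GRMZM2G089662	chr6	38410832	38413066	726	82524.8	7.9209	
ZmGRAS30	GRMZM2G089782	chr3	124035075	124037072	345	37232.6	7.7965	
ZmGRAS31	GRMZM2G091656	chr4	213905717	213907179	473	51700.4	4.4973	
ZmGRAS32	GRMZM2G097456	chr7	162247332	162249303	456	49478.5	5.398	
ZmGRAS33	GRMZM2G098517	chr7	161325637	161329188	558	60991.6	6.037	
ZmGRAS34	GRMZM2G098784	chr9	140092351	140096097	734	82407.3	6.3035	
ZmGRAS35	GRMZM2G098800	chr4	153223584	153226721	479	51399.2	8.136	
ZmGRAS36	GRMZM2G104342	chr5	9827131	9829504	569	61233.7	4.8845	
ZmGRAS37	GRMZM2G106336	chr4	2654200	2655918	569	64161.6	5.6074	
ZmGRAS38	GRMZM2G106356	chr4	2656855	2659044	629	71509.2	6.1865	
ZmGRAS39	GRMZM2G106548	chr7	158406894	158408665	452	48411.2	6.4457	
ZmGRAS40	GRMZM2G109869	chr2	15351727	15354059	623	65571	6.5741	
ZmGRAS41	GRMZM2G110067	chr1	71030279	71032027	526	54677.3	7.1968	
ZmGRAS42	GRMZM2G110579	chr5	192899281	192902025	595	62880.7	5.9948	
ZmGRAS43	GRMZM2G114680	chr9	103353117	103362197	467	49942.9	9.5395	
ZmGRAS44	GRMZM2G116638	chr1	137434183	137440188	542	59914.4	6.1403	
ZmGRAS45	GRMZM2G117949	chr9	117530782	117531764	118	12754.8	7.2349	
ZmGRAS46	GRMZM2G125501	chr2	209545748	209547741	456	49134.1	5.2625	
ZmGRAS47	GRMZM2G129154	chr8	158560400	158562023	449	48889.6	6.7131	
ZmGRAS48	GRMZM2G131516	chr4	185481408	185484703	140	15229.2	5.6514	SCR
ZmGRAS49	GRMZM2G132794	chr1	77494290	77496510	630	67547.3	6.6294	
ZmGRAS50	GRMZM2G133169	chr1	270571160	270573052	551	59842.1	5.0325	
ZmGRAS51	GRMZM2G140085	chr4	187217605	187218942	369	39334.6	7.342	
ZmGRAS52	GRMZM2G140094	chr4	187219736	187222248	487	51456.3	6.6281	
ZmGRAS53	GRMZM2G143433	chr5	120520869	120522119	416	43484.9	5.5444	
ZmGRAS54	GRMZM2G144744	chr1	266160101	266163168	630	66028.9	4.7928	D8
ZmGRAS55	GRMZM2G146018	chr3	142759880	142761574	492	52614.5	4.9922	
ZmGRAS56	GRMZM2G153333	chr6	148102723	148106458	561	62826.6	4.6747	
ZmGRAS57	GRMZM2G157679	chr3	180798590	180801759	809	89139.9	6.4786	
ZmGRAS58	GRMZM2G159475	chr3	125733039	125735799	710	78391.5	5.1754	
ZmGRAS59	GRMZM2G163427	chr4	842617	845669	765	84654.3	5.1643	
ZmGRAS60	GRMZM2G169636	chr7	165196140	165197777	545	57959.5	7.0312	
ZmGRAS61	GRMZM2G172657	chr7	161941687	161944142	592	63904.6	5.9479	
ZmGRAS62	GRMZM2G173429	chr10	135825173	135827459	623	65303.7	6.7864	
ZmGRAS63	GRMZM2G176537	chr10	117338432	117340217	494	52101.9	5.5598	
ZmGRAS64	GRMZM2G179325	chr1	155690714	155694188	721	79879	4.8103	
ZmGRAS65	GRMZM2G313078	chr6	156946311	156947989	426	45514.7	6.5092	
ZmGRAS66	GRMZM2G317287	chr10	1886674	1888997	606	66692.2	8.0803	
ZmGRAS67	GRMZM2G335814	chr1	248734599	248737101	732	82795.3	6.547	
ZmGRAS68	GRMZM2G342217	chr4	21604764	21607924	771	82103.3	6.6613	
ZmGRAS69	GRMZM2G346706	chr8	133612993	133614885	627	70612.1	7.267	
ZmGRAS70	GRMZM2G348780	chr1	161047325	161049647	338	38237.4	9.306	
ZmGRAS71	GRMZM2G359304	chr9	123178843	123180450	535	55755.5	6.4503	
ZmGRAS72	GRMZM2G368909	chr1	293715271	293717691	645	72646.3	6.9815	
ZmGRAS73	GRMZM2G386362	chr2	4624290	4626096	354	36607.9	6.2392	
ZmGRAS74	GRMZM2G408012	chr5	181911451	181912595	251	28281.4	10.717	
ZmGRAS75	GRMZM2G418899	chr7	162852139	162862787	431	47773.6	5.7168	
ZmGRAS76	GRMZM2G420280	chr2	51272702	51274207	498	53733.3	8.6598	
ZmGRAS77	GRMZM2G425366	chr2	219524850	219526665	541	60489.3	5.2866	
ZmGRAS78	GRMZM2G431309	chr2	208500828	208504903	554	60835.6	6.23	
ZmGRAS79	GRMZM5G821439	chr2	204949825	204954417	570	64511.1	6.3587	
ZmGRAS80	GRMZM5G825321	chr2	19769962	19772850	485	52611.8	7.2682	
ZmGRAS81	GRMZM5G826526	chr3	214641511	214642665	384	40366.2	7.5029	
ZmGRAS82	GRMZM5G868355	chr4	839965	841260	381	42723.6	6.5888	
ZmGRAS83	GRMZM5G874545	chr3	232137122	232158937	342	37832.3	6.5808	
ZmGRAS84	GRMZM5G885274	chr5	205139992	205141687	545	60793.6	6.2568	
ZmGRAS85	GRMZM5G889326	chr6	137480065	137481525	486	52641.4	7.2535	
ZmGRAS86	GRMZM5G895672	chr4	827079	829016	645	72101.2	6.8419	
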