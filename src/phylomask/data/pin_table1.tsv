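terminal	protein_aa	n_tmds	type_label	score	geometry_score
Aco001931	654	9	Long	1	1
Aco007499	356	9	Short	2	2
Aco016169	620	9	Long	1	1
Aco018139	641	9	Long	1	1
Aco018694	612	5	Long	1	5
AtPIN1	622	9	Long	1	1
AtPIN2	647	9	Long	1	1
AtPIN3	640	9	Long	1	1
AtPIN4	616	10	Long	1	1
AtPIN5	351	9	Short	2	2
AtPIN6	570	9	Reduced	3	3
AtPIN7	619	9	Long	1	1
AtPIN8	367	8	Short	2	2
Csi_g006199	657	10	Long	1	1
Csi_g007420	604	8	Long	1	1
Csi_g007826	588	8	Long	1	1
Csi_g018360	357	8	Short	2	2
Csi_g019021	347	9	Short	2	2
Csi_g035534	291	5	N-terminal TMD only	5	5
Csi_g036474	646	9	Long	1	1
Csi_g041301	291	7	Short	2	2
Csi_g048649	256	5	N-terminal TMD only	5	5
EgrA02229_1	599	8	Long	1	1
EgrB00948_1	587	9	Long	1	1
EgrB01403_1	365	9	Short	2	2
EgrB01405_1	364	9	Short	2	2
EgrB01406_1	285	7	Short	2	2
EgrB02902_1	657	9	Long	1	1
EgrC00078_1	626	9	Long	1	1
EgrF04265_1	530	8	Reduced	3	3
EgrG02187_1	652	9	Long	1	1
EgrG02548_1	338	9	Short	2	2
EgrG02549_1	360	9	Short	2	2
EgrH01382_1	262	6	Short	2	2
EgrH01390_1	519	7	Long	1	1
EgrI01919_1	356	8	Short	2	2
EgrK02271_1	598	9	Long	1	1
Mes003367	646	9	Long	1	1
Mes003794	614	8	Long	1	1
Mes003807	614	8	Long	1	1
Mes006998	468	9	Long	1	1
Mes010607	357	9	Short	2	2
Mes010688	354	9	Short	2	2
Mes026579	598	7	Long	1	1
Mes029063	361	8	Short	2	2
Mes029078	626	9	Long	1	1
Mes030090	380	5	N-terminal TMD only	5	5
Mes033391	355	8	Short	2	2
Mtr2g043210	315	4	N-terminal TMD only	5	5
Mtr4g154810	524	8	Long	1	1
Mtr6g083450	659	10	Long	1	1
Mtr7g008720	357	8	Short	2	2
Mtr7g089430	363	9	Short	2	2
Mtr7g106430	591	8	Long	1	1
Mtr8g130020	625	9	Long	1	1
Mtr8g130040	568	10	Long	1	1
Mtr4g084870	659	10	Long	1	1
MtrAAT48627	527	9	Long	1	1
MtrAY115838	621	10	Long	1	1
OsPIN1a	595	10	Long	1	1
OsPIN1b	554	9	Reduced	3	3
OsPIN1c	592	10	Long	1	1
OsPIN1d	390	4	C-terminal TMD only	4	4
OsPIN2	630	9	Long	1	1
OsPIN3a	670	5	Long	1	5
OsPIN3b	591	10	Long	1	1
OsPIN5a	363	7	Short	2	2
OsPIN5b	398	7	Short	2	2
OsPIN5c	357	7	Short	2	2
OsPIN8	311	5	Short	2	2
OsPIN9	426	10	Reuced	3	3
PpPIN1A	713	9	Long	1	1
PpPIN1B	713	9	Long	1	1
PpPIN1C	698	9	Long	1	1
PaPIN1	699	10	Long	1	1
PaPIN2	426	3	C-terminal TMD only	4	4
PaPIN3	625	8	Long	1	1
PtoPIN1	619	7	Long	1	1
PttPIN1	614	9	Long	1	1
PttPIN2	640	9	Long	1	1
PttPIN3	588	9	Long	1	1
PtrPIN1	614	9	Long	1	1
PtrPIN2	588	8	Long	1	1
PtrPIN3	645	9	Long	1	1
PtrPIN4	534	9	Long	1	1
PtrPIN5	532	8	Long	1	1
PtrPIN6	649	9	Long	1	1
PtrPIN7	609	9	Long	1	1
PtrPIN8	587	9	Long	1	1
PtrPIN9	633	9	Long	1	1
PtrPIN10	547	10	Long	1	1
PtrPIN11	346	9	Short	2	2
PtrPIN12	346	10	Short	2	2
PtrPIN13	355	8	Short	2	2
PtrPIN14	358	8	Short	2	2
PtrPIN15	370	8	Short	2	2
PtrPIN16	304	6	Short	2	2
Ppe002528	662	10	Long	1	1
Ppe002944	619	9	Long	1	1
Ppe003159	597	8	Long	1	1
Ppe007621	361	9	Short	2	2
Ppe021573	357	7	Short	2	2
Ppe022797	550	9	Long	1	1
Ppe024134	649	9	Long	1	1
Ppe025174	602	8	Long	1	1
Rc27985	544	8	Long	1	1
Rc29662	635	8	Long	1	1
Rc29816	646	10	Long	1	1
Rc29822	313	7	Short	2	2
Rc30128	357	9	Short	2	2
Rc30180	613	8	Long	1	1
SmPIN1-1	625	9	Long	1	1
SmPIN1-2	617	9	Long	1	1
SmPIN2-1	602	9	Long	1	1
SmPIN2-2	716	9	Long	1	1
SmPIN3-1	669	9	Long	1	1
SmPIN3-2	672	9	Long	1	1
SmPIN4-1	687	9	Long	1	1
SmPIN5-1	636	9	Long	1	1
SmPIN5-2	625	9	Long	1	1
SbPIN1	371	9	Short	2	2
SbPIN2	653	8	Long	1	1
SbPIN3	362	7	Short	2	2
SbPIN4	444	10	Reduced	3	3
SbPIN5	336	7	Short	2	2
SbPIN6	605	10	Long	1	1
SbPIN7	583	9	Long	1	1
SbPIN8	402	9	Short	2	2
SbPIN9	600	10	Long	1	1
SbPIN10	606	9	Long	1	1
SbPIN11	626	9	Long	1	1
VvPIN1a	604	8	Long	1	1
VvPIN1b	591	8	Long	1	1
VvPIN2	630	10	Long	1	1
VvPIN5b	361	9	Short	2	2
VvPIN5a	356	9	Short	2	2
VvPIN6	532	9	Reduced	3	3
VvPIN8	357	8	Short	2	2
VvPIN9	463	8	Reuced	3	3
ZmPIN1a	601	9	Long	1	1
ZmPIN1b	595	8	Long	1	1
ZmPIN1c	597	8	Long	1	1
ZmPIN1d	580	8	Long	1	1
ZmPIN2	626	9	Long	1	1
ZmPIN5a	382	9	Short	2	2
ZmPIN5b	385	7	Short	2	2
ZmPIN5c	365	7	Short	2	2
ZmPIN8	359	7	Short	2	2
ZmPIN9	433	10	Short	2	2
ZmPIN10a	610	8	Long	1	1
ZmPIN10b	581	8	Long	1	1
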