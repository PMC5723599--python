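# Verification panel: 71 clitellate specimens (11 families, 47 genera) with
# amplification status for the whole-ITS pair (29F/1084R, column amplified_its)
# and the ITS2 pair (606F/1082R, column amplified_its2), plus partition-length
# strings using the ">" (incomplete) and "-" (absent) conventions.
specimen_id	family	species	accession	amplified_its	amplified_its2	its1_bp	r58s_bp	its2_bp
CE18252	Branchiobdellidae	Xironogiton victoriensis	KY982581	+	+	>1097	153	>810
CE14346	Capilloventridae	Capilloventer australis	KY982554	-	+	-	>92	747
CE13745	Enchytraeidae	Achaeta aberrans	KY982545	+	+	>439	153	330
CE11317	Enchytraeidae	Chamaedrilus sphagnetorum	KY982555	-	+	-	>70	248
CE19554	Enchytraeidae	Fridericia magna	KY982559	+	+	>436	153	287
CE19299	Enchytraeidae	Lumbricillus lineatus	KY982569	+	+	>464	153	289
CE5731	Haplotaxidae	Haplotaxis gordioides	KY982561	+	+	>472	153	302
CE18378	Hirudinidae	Haemopis sanguisuga	KY982560	+	+	>322	153	381
CE12000	Lumbricidae	Allolobophora caliginosa	KY982547	+	+	>503	153	416
CE16075	Lumbricidae	Aporrectodea caliginosa	KY982549	+	+	>389	153	416
CE10969	Lumbriculidae	Dorydrilus michaelseni		-	-	-	-	-
CE14379	Lumbriculidae	Kincaidiana hexatheca	KY982565	+	+	>546	153	313
CE19888	Lumbriculidae	Lumbriculus variegatus	KY982570	+	+	>638	153	312
CE17795	Lumbriculidae	Stylodrilus heringianus	KY982578	-	+	-	>107	321
CE2048	Megascolecidae	Dichogaster bolaui	KY982556	+/-	+	>93	153	338
CE713_1	Naididae	Branchiura sowerbyi		-	-	-	-	-
CE10030	Naididae	Adelodrilus pusillus	KY982546	+	+	>490	153	385
CE37	Naididae	Aktedrilus arcticus	KY637025	+	+	>459	153	258
CE1790	Naididae	Aulodrilus acutus	KY637027	+	+	>426	153	377
CE14362	Naididae	Aulodrilus japonicus	KY982550	+	+	>515	153	389
CE281	Naididae	Aulodrilus pluriseta	KY637028	-	+	-	>64	288
CE196_2	Naididae	Baltidrilus costatus	KY637029	+	+	>715	153	481
CE17439	Naididae	Bathydrilus formosus	KY982551	+	+	>591	153	357
CE17759	Naididae	Bothrioneurum vejdovskyanum	KY982552	+	+	351	153	251
CE2213	Naididae	Branchiodrilus hortensis		-	-	-	-	-
CE12487	Naididae	Branchiura sp	KY982553	+/-	+	>118	153	642
CE112	Naididae	Clitellio arenarius	KY637031	+	+	380	153	302
CE138	Naididae	Doliodrilus tener	KY637032	+	+	>669	153	282
CE14133	Naididae	Doliodrilus tener	KY982557	+	+	>573	153	256
CE754	Naididae	Epirodrilus pygmaeus	KY982558	-	+/-	-	>70	>84
CE236	Naididae	Heronidrilus fastigatus	KY637033	+	+	444	153	285
CE18212	Naididae	Heronidrilus gravidus	KY982562	+	+	>472	153	247
CE17490	Naididae	Heterodrilus ersei	KY982563	+	+	>377	153	296
CE18015	Naididae	Inanidrilus leukodermatus	KY982564	+	+	416	153	258
CE131	Naididae	Limnodriloides anxius	KY637034	+	+	>880	153	353
CE16954	Naididae	Limnodriloides australis	KY982566	+	+	>876	153	312
CE2730	Naididae	Limnodrilus cf. cervix	KY982567	+	+	>480	153	408
CE2128	Naididae	Limnodrilus claparedianus/cervix	KY369387	+	+	378	153	346
CE1785	Naididae	Limnodrilus grandisetosus	KY637016	+	+	471	153	515
CE1786	Naididae	Limnodrilus grandisetosus	KY637017	-	+	-	>107	359
CE1784	Naididae	Limnodrilus hoffmeisteri	KY369406	+	+	341	153	341
CE22814	Naididae	Limnodrilus hoffmeisteri II	KY652931	-	+	-	>70	342
CE2740	Naididae	Limnodrilus hoffmeisteri VIII	KY369440	+	+	349	153	328
CE1991	Naididae	Limnodrilus hoffmeisteri X	KY369446	+	+	338	153	340
CE10781	Naididae	Limnodrilus rubripenis	KY637018	+	+	547	153	422
CE10853	Naididae	Limnodrilus rubripenis	KY637020	+	+	550	153	432
CE10482	Naididae	Limnodrilus sulphurensis	KY637022	+	+	>589	153	383
CE1839	Naididae	Limnodrilus udekemianus	KY982568	+	+	>524	153	392
CE211	Naididae	Lophochaeta ignota	KY637036	+/-	+	>188	153	439
CE20081	Naididae	Monopylephorus irroratus	KY982571	+	+	>370	153	330
CE50	Naididae	Monopylephorus rubroniveus	KY637037	+	+	>435	153	370
CE19318	Naididae	Nais elinguis	KY982572	+	+	>421	153	292
CE16885	Naididae	Olavius albidus	KY982573	+	+	>400	153	274
CE17410	Naididae	Potamothrix bavaricus	KY982574	+	+	>479	153	383
CE283	Naididae	Potamothrix moldaviensis	KY637042	+	+	>466	153	396
CE2883	Naididae	Psammoryctides albicola	KY637043	+	+	>487	153	518
CE289	Naididae	Psammoryctides barbatus	KY637044	+	+	391	153	373
CE623	Naididae	Rhyacodrilus coccineus	KF267996	+	+	340	153	308
CE17550	Naididae	Smithsonidrilus hummelincki	KY982576	+/-	+	>69	153	697
CE1984	Naididae	Spirosperma ferox	KY982577	-	+	-	>69	>306
CE18140	Naididae	Thalassodrilides bruneti	KY982579	+	+	>514	153	281
CE2038	Naididae	Trieminentia corderoi	KY982580	-	+/-	-	>63	>161
CE2044	Naididae	Tubifex blanchardi	KY637046	+	+	>604	153	446
CE272	Naididae	Tubifex newaensis	KY637047	+	+	>490	153	336
CE212	Naididae	Tubifex smirnowi	KY637048	+	+	447	153	321
CE276	Naididae	Tubifex tubifex	KY637049	+	+	>515	153	393
CE186	Naididae	Tubificoides benedii	KY637050	+	+	>464	153	332
CE3600	Naididae	Varichaetadrilus cf. angustipenis		-	-	-	-	-
CE3621	Naididae	Varichaetadrilus sp	KY637051	+/-	+	-	>105	494
CE14357	Phreodrilidae	Antarctodrilus proboscidea	KY982548	-	+	-	>85	747
CE14476	Randiellidae	Randiella sp	KY982575	+	+	>548	153	319
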