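variant_id	chrom	pos	risk_allele	other_allele	odds_ratio	eaf
rs000001	22	26618285	G	T	1.1255086801547072	0.8038280450404985
rs000002	3	22446197	A	G	1.048551732065857	0.7931441133763255
rs000003	4	4866298	A	G	1.096111503679514	0.5987172470394501
rs000004	3	14922750	A	G	1.011788076334967	0.7630787849588082
rs000005	22	29989308	C	T	0.974083184125449	0.92445095550685
rs000006	20	41185869	G	A	0.9905973597984457	0.31496444392563533
rs000007	19	15297572	A	G	1.1679758872041228	0.47603792419684826
rs000008	10	46681936	T	C	1.1368580221437472	0.17112018445403304
rs000009	8	22356858	C	T	1.0552161261502184	0.8464817965196577
rs000010	14	15090861	T	G	1.1028563018162145	0.5660938364443739
rs000011	4	23286533	C	T	1.035708995608613	0.5068029951130681
rs000012	11	3343147	A	C	1.2471263179062648	0.8826789210892947
rs000013	8	5627580	T	C	0.829536295696858	0.8404120524933238
rs000014	4	49114764	T	C	1.0473333727682097	0.15487402079994086
rs000015	7	19772594	G	T	0.9452156531241749	0.3983334921246746
rs000016	15	25824678	T	C	0.8781164276042139	0.23016533756691115
rs000017	7	16549141	G	T	0.819128080925972	0.4953290848693227
rs000018	11	45986983	T	G	1.050421174127432	0.8841729449017608
rs000019	14	11538907	C	T	1.0276914531847476	0.38024758988379354
rs000020	18	39596224	T	C	0.9103242280056801	0.5922860901306013
rs000021	17	3966421	C	A	0.970626955193686	0.632755728251846
rs000022	4	7855890	C	A	1.099132419015253	0.7036034907669895
rs000023	22	25784205	G	A	0.8776839369337645	0.6838062672072545
rs000024	11	8712975	C	A	0.8585514659618233	0.867443060239813
rs000025	3	43438971	T	C	1.039179956069098	0.06311456205385914
rs000026	20	34547968	C	A	1.0654390903940876	0.6140807979587688
rs000027	3	3171757	G	T	0.9380822537080161	0.238435872943571
rs000028	19	41912692	C	A	0.8401457904188788	0.2321149222487573
rs000029	12	23629637	G	A	1.010189903873094	0.5199286207971638
rs000030	14	33600562	T	C	1.0518055041905041	0.4727635810971845
rs000031	5	32107262	G	A	0.8865173090008429	0.5131383809559332
rs000032	5	35344366	G	T	1.0164905539839988	0.1338105854000613
rs000033	11	3392028	A	C	0.93844779937729	0.17846637236123003
rs000034	10	20202047	G	T	0.9231847925718637	0.12609417365680364
rs000035	19	40568189	G	A	0.9552815633204265	0.07252213968423635
rs000036	3	1044699	T	C	0.9505715270327771	0.6025311002097922
rs000037	14	25034931	A	G	0.9306687209685552	0.7975023513202002
rs000038	12	34837230	T	G	0.9849611659574367	0.6938061734366268
rs000039	7	2270795	C	A	1.2221571978445072	0.2855329250859949
rs000040	11	48720392	T	C	1.1175487354706133	0.5787875814220091
rs000041	21	5146447	A	G	0.9981511895190956	0.9113317852196575
rs000042	7	19673832	C	A	1.0245321935182892	0.8627463036891899
rs000043	9	30491116	G	T	0.9812117446891073	0.8240748015910633
rs000044	7	28964034	A	C	1.0380694551300733	0.571992073538952
rs000045	5	30423799	T	G	1.0509954583420087	0.8320913130331584
rs000046	20	20428016	G	T	1.0467750347610432	0.21415949837014037
rs000047	9	5554203	A	G	1.0604349676429303	0.10964446418837609
rs000048	18	5756568	G	T	0.9041619083326798	0.3408687365320942
rs000049	5	7515370	G	A	1.0878487668823218	0.4012104093065499
rs000050	20	31494963	G	T	0.9834797005530402	0.35003779248451583
rs000051	11	27217932	A	C	0.9046029781922965	0.28928788675617284
rs000052	1	6578491	T	C	1.1700801035636923	0.617232790901387
rs000053	4	2875923	A	G	0.8671285477926362	0.5263561732800821
rs000054	10	10732863	A	C	1.1245845127187213	0.7335765601537295
rs000055	17	33436769	T	G	0.9981293742413453	0.19508773955716008
rs000056	21	12659311	C	A	1.1480160941662776	0.4597176173424637
rs000057	12	44780089	A	C	0.9783768735547385	0.2830964532218393
rs000058	16	4574458	G	A	1.0612809437911706	0.7066197924265356
rs000059	13	13245930	G	A	0.9924982687697183	0.3608095030753088
rs000060	16	45185992	G	A	1.1202421997663061	0.9007576171892588
rs000061	4	6372331	T	C	1.040686012741251	0.24901284859285888
rs000062	18	39344592	T	G	0.9880384003871153	0.7674525937998202
rs000063	18	18166709	C	T	1.0530185822825584	0.4903178324404581
rs000064	19	7722110	G	T	0.9839157958997223	0.615655007985155
rs000065	14	6868595	G	A	1.0291043695424043	0.6219510915667918
rs000066	1	45087523	T	G	0.9401803499397108	0.7845781034923728
rs000067	19	35799288	T	C	1.0998091073808391	0.5111867619149086
rs000068	21	7104162	T	G	0.908034801529653	0.9022809839708696
rs000069	3	281131	A	G	0.8954244757575748	0.42967621884166335
rs000070	2	29593562	G	A	1.0617367417056403	0.10496422074353412
rs000071	10	14375719	G	T	1.1895221979358124	0.44289749047065435
rs000072	7	49065888	T	C	1.020572383059666	0.29853000302761
rs000073	16	27366882	T	C	1.1564984663887148	0.9426922891984064
rs000074	8	3348084	C	T	0.9936269362777506	0.34020863825308667
rs000075	5	2272999	C	T	0.9459238730747254	0.39142277093066186
rs000076	8	37563579	C	A	1.1623344940176605	0.264447755239877
rs000077	22	35701427	T	G	0.8658907403762074	0.6107020344823919
rs000078	1	26484037	G	T	0.8489773386627191	0.12082706219222274
rs000079	9	38120273	C	A	1.061316750583379	0.08786300341457226
rs000080	16	17428127	C	T	1.0991544288539337	0.09702713089031861
rs000081	14	13504079	A	C	1.0529198035634186	0.9328900851612076
rs000082	9	29327154	T	C	1.096092438716931	0.08528418006887145
rs000083	8	45842197	C	T	0.8964700964234048	0.20324607720316762
rs000084	3	45298091	A	C	0.9854615396415165	0.3151630554338618
rs000085	13	40729387	T	G	0.9852054749806932	0.5368639906388711
rs000086	2	4346119	A	C	1.1028792739044344	0.841024656018869
rs000087	14	7136396	G	T	1.0877907092635088	0.9157500552883352
rs000088	13	3179357	G	A	0.909634450579082	0.9268674580673141
rs000089	16	84502	G	A	1.3072350411891867	0.20584700491955987
rs000090	12	18613827	T	C	0.9936236001249501	0.6469930785354249
rs000091	15	4399716	T	G	0.9080813001522444	0.8834350985985147
rs000092	19	7246084	A	C	1.056155046656984	0.5371451319688144
rs000093	13	5371329	G	A	1.1014197110069903	0.22311126864723135
rs000094	10	33637041	A	G	1.091903521188667	0.38885685808625897
rs000095	1	45022742	C	T	1.058340842899794	0.42640515550890257
rs000096	7	37218550	T	C	0.9779759180410906	0.19275213225601057
rs000097	13	7354113	C	T	1.134284524216328	0.5108461996457896
rs000098	22	49162382	A	G	1.0285876855596725	0.9284309747442383
rs000099	2	19987946	C	A	0.9599900947499327	0.7050894058708426
rs000100	11	29852417	G	A	0.8612185400769744	0.7136473427073755
rs000101	17	9565043	T	G	0.9897716679720707	0.14427538833487516
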