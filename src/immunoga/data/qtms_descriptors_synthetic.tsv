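# SYNTHETIC stand-in table: per-residue quantum topological molecular
# similarity (QTMS) descriptors.  The published 21 per-residue QTMS
# descriptors are not redistributed here; these values are a seeded
# synthetic reconstruction preserving shape and schema (20 residues x 21
# descriptors).  Replaceable via FeatureContext(qtms_table=...).
residue	q01	q02	q03	q04	q05	q06	q07	q08	q09	q10	q11	q12	q13	q14	q15	q16	q17	q18	q19	q20	q21
A	1.2259	0.7418	-0.6096	0.7774	-0.2679	-0.8627	-1.5529	0.1439	0.4747	-0.0568	-0.9487	1.0386	-0.8726	2.6191	0.2908	-0.6982	-1.5537	0.7517	0.0550	-0.1866	1.5744
C	0.3880	0.0527	-0.4089	1.2446	1.2755	-0.4465	0.7789	0.0515	-0.1429	0.7424	1.3538	2.2931	1.2452	0.5026	-0.5388	0.7353	-0.9868	1.3904	1.8157	-0.2978	0.6445
D	1.4963	-0.4560	0.8975	0.8226	-0.7417	-0.2852	-0.0586	0.5013	1.4551	-0.9322	-0.4639	0.3132	-0.3845	-0.2054	-0.1526	-0.1718	0.2545	-0.1131	-0.9920	-0.7436	-0.7818
E	-0.6633	0.4035	-1.0006	2.5288	-0.5454	0.2738	-1.5494	0.6515	0.1317	0.4629	0.4093	-0.7093	1.1874	-0.6306	-0.7408	0.2087	-1.3659	0.7738	0.0318	0.3191	-0.2841
F	1.0935	0.2236	-0.5716	0.3188	-0.8448	0.3925	-0.1930	0.6125	-0.9140	-0.0327	-0.0884	0.2562	1.6881	0.8019	-0.2602	-1.5622	0.0623	-0.3305	1.4684	1.1656	0.2249
G	0.6314	-0.7440	-0.2506	0.1888	0.1266	1.0602	-0.4806	-0.4168	-2.4924	0.3022	-0.0266	-0.2898	-1.2721	1.0595	-0.4935	0.5407	1.5418	0.1508	1.3835	1.8703	0.7842
H	0.2502	1.1335	-0.4887	-0.1171	-0.1601	-0.5596	0.8917	1.2152	-0.4433	-0.6707	1.7035	-0.1283	0.4354	2.1995	0.0539	1.8956	-1.4187	-0.0273	-1.0686	0.1767	-0.2771
I	0.4856	-0.2402	-1.6831	-0.2443	-0.2691	1.1138	-0.5420	0.4697	-1.3329	1.1087	-0.1172	-0.6154	0.5438	-0.7414	1.5269	-1.5665	-0.1746	1.3927	-0.8415	0.6689	-1.4287
K	-0.4243	-3.0474	-0.5438	-0.3856	1.5103	0.2070	-0.2821	-2.0346	0.3527	-0.0751	-1.0413	0.3525	0.8059	-0.0527	-0.1395	1.3266	0.6854	1.0530	-0.3408	-0.0424	-0.1326
L	-0.5655	-0.4350	-1.2347	1.8381	-0.0905	-2.1381	-0.4436	0.5538	1.0065	0.8696	-0.5168	-2.0773	1.5670	1.0678	0.1220	-0.9637	1.2370	0.9551	-0.5975	-1.2975	0.5136
M	0.0211	0.4028	-0.5018	-0.5927	-0.0193	0.7913	-0.6437	1.4286	-1.4725	-0.0209	-0.7915	-1.1243	-0.0235	-0.4115	0.3122	-0.8158	-0.8406	0.3402	0.7186	-1.8767	0.2261
N	0.1683	0.4828	1.0478	0.5294	1.3238	-0.4793	-0.4701	-1.4810	1.1985	1.8404	-1.3211	1.4807	-3.0690	-0.1206	-0.5710	-1.7550	0.4936	-0.3956	0.1277	-0.2769	-1.1614
P	0.0100	-0.2847	-1.7771	0.3183	-0.2594	0.3686	1.0905	0.2677	-0.7460	0.7791	0.2964	0.2839	1.5111	-0.0069	0.1099	0.7121	0.8612	0.7235	-0.9829	0.2827	0.0286
Q	-0.3416	2.4664	0.3092	0.1603	-0.8589	0.9546	-1.2878	0.5050	-0.4809	-2.1173	-0.6997	-0.1162	0.7752	1.8822	0.7785	0.3216	0.2179	1.1543	-0.6753	-1.4279	-1.6629
R	-0.1530	-0.5823	-0.2269	-1.2524	0.3135	1.0207	0.1625	-0.2572	0.0139	-0.3754	-0.1635	-1.1001	0.9478	-0.4250	0.0136	0.8598	0.7148	2.3475	0.8398	0.4581	0.8407
S	-0.1640	-0.4975	0.8984	-2.3982	-0.9250	1.2255	-0.4677	0.1194	0.0172	2.2067	0.4057	1.1934	-0.4674	-0.2998	1.7670	0.0189	0.3613	0.1322	2.4319	-0.7240	1.7265
T	-1.3819	0.5215	0.3726	-1.9415	0.0102	-1.3893	-0.4980	1.9773	0.9356	0.4062	0.0406	0.0123	-0.4986	0.9616	1.7695	-0.5385	0.3815	-1.2279	0.6824	0.7956	-0.6612
V	-0.9314	0.3383	-2.0759	0.4328	-0.7284	-0.4464	-0.1291	2.0047	-0.3707	1.4265	-0.7298	0.2734	0.5451	0.7457	-0.0428	-0.4710	-0.5111	-1.6787	-0.1153	2.0639	0.4031
W	-0.9367	-0.1209	-0.9466	0.4433	-0.7980	-2.5370	-1.1993	0.0934	0.7974	1.7514	1.9035	1.4622	-0.9417	0.5647	0.5598	-0.2293	-0.7681	1.7845	-0.5112	1.1288	-1.2686
Y	0.7056	2.0969	0.6634	0.5064	0.5233	-1.2890	-0.2996	-0.3548	-1.8918	1.6771	-0.4228	0.1526	1.0536	1.1518	0.5747	-0.6639	0.8544	1.3276	0.1492	0.3612	-0.9969
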