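# SYNTHETIC stand-in table: per-residue amino-acid pairwise contact
# potentials (AAPP).  The published 40 contact-potential scales are not
# redistributed here; these values are a seeded synthetic reconstruction
# preserving shape and schema (40 scales x 20 residues).  Replaceable via
# FeatureContext(contact_potentials=...).
table_id	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
cp01	-0.3109	-1.2294	0.2982	-1.4914	-0.2337	-0.0375	-1.3590	0.3256	0.5487	-2.7390	-1.9375	0.0745	0.3113	-0.0144	-0.4901	-1.0005	-0.7082	-2.2726	0.3686	-1.2691
cp02	0.4289	0.3485	-1.0454	0.1679	2.0033	0.5974	-0.2753	-0.5220	0.3406	-1.2769	-0.6882	-1.4382	-0.4769	-1.5497	-0.9297	0.4342	1.1951	1.3928	0.3960	1.4098
cp03	-0.6707	1.5308	-0.1851	-1.3471	-0.0738	-0.3490	-0.3249	0.2826	1.2257	0.4219	0.2029	-0.0271	-0.0530	-1.0601	1.2425	1.8329	1.6129	1.1753	0.1828	0.9551
cp04	-0.4348	0.2857	-0.3574	0.0306	0.4151	-0.9768	-0.0811	0.3969	-1.4074	0.7402	0.2086	-1.1231	2.2448	0.9218	-1.5892	1.6062	1.7368	0.8411	-0.2454	-1.3498
cp05	-0.5665	1.2853	0.2343	-0.5717	-0.7533	0.3223	0.0975	0.9594	-1.0875	0.1281	0.0607	-1.7628	-0.4291	0.2708	0.2443	-0.7457	0.3175	0.2074	0.8720	-0.9522
cp06	-0.2174	-1.4746	-0.0155	-2.1983	-0.6613	-0.6370	-0.2034	-1.3233	-0.4048	0.7679	-0.6693	1.3693	-1.4948	0.8277	-0.7297	0.4019	1.3501	1.4995	-2.2661	-1.2790
cp07	-0.2660	0.6054	0.2639	-1.1311	0.4395	-0.4811	-1.1118	-0.6815	0.4568	-0.5980	-0.8618	-1.0319	0.0090	0.5246	2.8427	0.5759	-1.3774	-0.2465	1.8273	-0.6483
cp08	-0.4781	-0.1393	-0.3919	-0.0537	1.3411	-0.3367	-0.5666	-1.2678	0.8037	0.4578	-0.5124	1.0746	-0.5550	0.2377	-0.6087	-1.0756	1.0673	0.7480	-0.2009	0.8693
cp09	2.5848	1.0054	1.7323	0.0931	0.5245	1.5515	1.5588	1.1189	0.8137	-0.2541	1.2238	1.0097	-1.0077	-0.5844	0.0058	1.5043	1.7246	-1.5596	-0.5806	-1.7056
cp10	0.4502	-0.2558	0.0691	0.5508	0.3294	1.1120	-0.6825	0.6861	1.2349	1.5286	1.2408	2.7022	0.5284	-2.0263	-1.6535	-0.5349	0.5281	0.1151	-0.2898	0.5152
cp11	-1.0045	0.1232	1.2428	-0.6097	-0.4448	-0.4899	0.5251	1.2365	0.0000	0.5276	-0.6142	-1.0485	-0.0556	-2.2808	-0.1815	1.0214	0.2328	0.4503	1.1118	0.6254
cp12	-1.7249	-0.9071	0.7810	-2.3523	-0.2833	-0.4721	-0.0267	0.5256	-0.2807	0.1734	0.2485	1.0241	0.9235	0.0943	-1.2263	-0.2732	-0.5329	-0.4373	-1.6896	0.4219
cp13	-0.4701	0.3415	-0.3226	-0.8372	-1.9122	-0.6528	0.1387	-1.0033	-0.8074	-1.3180	1.0665	1.6945	0.1060	-0.9522	-1.5158	1.8430	0.8845	0.2368	-0.9932	0.5593
cp14	1.1836	-1.0058	-0.0860	-1.1032	-0.3393	1.4542	1.1576	1.3763	0.6221	0.1234	-0.5658	-0.9064	-1.5234	0.6582	1.5431	0.1433	-0.7646	-0.2157	-0.3037	-1.1616
cp15	0.4727	0.0586	-1.5785	-0.6431	0.7707	-2.8172	0.7930	-0.1628	-1.1356	0.7855	1.3909	1.1933	1.5800	0.4000	0.8347	-0.6341	-0.3015	-0.4313	1.7680	-0.6282
cp16	-2.0757	-0.0228	-0.7751	-0.0823	0.3313	0.1997	-0.6839	1.1339	0.1379	-0.9670	-0.4829	-0.6744	0.3685	0.0978	0.4334	-1.8972	-0.3540	0.9644	0.8214	-0.3490
cp17	-0.9057	-0.7423	-2.4923	0.3864	1.1897	-0.9552	-0.5417	-1.1802	-1.5968	-0.1494	-0.7062	1.9790	0.7719	-0.4669	-0.1328	2.1718	1.0837	1.6958	0.3646	0.1772
cp18	-0.6206	0.7881	-1.0550	-0.9012	0.3316	-1.5558	0.4558	1.9597	-0.6085	1.2831	-0.2420	-1.0742	-0.9246	0.5637	0.1955	1.0383	-1.9234	-0.9808	-1.0081	-1.4379
cp19	-1.0996	-0.4666	0.0867	-1.4385	-1.2423	0.2534	-1.5742	-1.0395	-0.3423	-0.5858	-2.5233	-1.3109	0.9635	-1.0192	0.2840	0.1772	1.3672	0.5989	1.0838	0.4169
cp20	0.4090	-0.4617	0.9278	2.0749	0.9745	-1.4777	-0.7954	0.0694	0.3068	-0.9981	0.9516	-0.0281	0.0625	-1.6956	0.6761	-0.4683	0.1602	-0.9609	0.3007	0.4368
cp21	1.9207	0.4538	-0.2330	-1.1618	0.2593	0.2972	-2.1120	-2.2651	-0.7446	0.4176	-0.6802	-0.3071	-0.9025	-0.3848	-0.5002	1.5848	1.2007	-1.1682	-0.4528	0.6587
cp22	0.8565	-0.9286	0.4470	1.5483	0.1949	-1.8872	-0.6026	2.1171	-1.0635	0.7968	0.5175	0.8774	1.1849	-1.3597	-0.2325	1.1102	-0.9180	-0.2100	-0.8463	-1.3527
cp23	-1.0769	0.0364	-0.8425	0.1294	0.5192	0.0528	-1.9559	0.4108	0.7653	1.9239	1.3312	-2.6702	1.8688	0.7299	1.0348	-1.3476	-0.7811	-1.7663	0.6867	-0.8319
cp24	0.8538	2.5714	1.0551	0.6546	-0.7749	-1.0975	0.5181	1.5633	0.2832	0.4142	-0.2847	0.1793	-0.6699	-0.5952	-0.8565	-0.0800	-0.4151	-0.1290	-0.3765	-0.3710
cp25	1.5900	0.2352	-0.9295	0.8671	-0.6386	0.4589	-0.1414	1.0267	1.8745	-0.9404	0.2551	-0.6346	-1.6077	0.0006	-0.1808	-1.3769	0.4473	1.3056	-0.8948	-0.1685
cp26	-1.6515	0.4684	1.2127	0.8317	0.6925	0.4810	1.1685	-1.1399	-0.7414	-0.3416	0.7758	0.1195	0.2212	1.8491	0.7550	0.9355	1.2656	1.2241	0.1026	-1.4090
cp27	0.4889	-0.5626	-2.3347	-0.5878	0.4370	-1.1547	-0.5624	-0.6735	1.1114	-0.0516	-0.9278	0.5156	-1.1620	-0.3355	0.5093	0.1517	-3.3449	-0.5422	-0.9916	-0.2101
cp28	0.0646	0.6131	2.7763	0.0973	0.5229	0.3464	0.3328	-0.9322	-0.1781	0.2319	-0.7290	-0.0931	-0.5249	-0.0578	1.2799	-0.1661	-0.4315	-0.1947	-1.4982	0.2480
cp29	-0.4117	-2.3599	-1.7886	1.8110	1.6804	-0.9626	-0.5769	-0.1665	-0.8164	-0.2969	-1.2422	1.7126	1.0570	-0.6703	-0.3264	0.2437	0.2987	0.5185	0.8191	-0.5771
cp30	-0.7825	-0.2888	-0.2889	0.7609	0.3357	-1.5313	0.7431	-0.7534	0.3825	-0.7260	0.2191	0.6887	-0.6107	-0.2061	-2.2436	-1.6606	0.4844	-2.0908	0.0237	0.4114
cp31	-0.8832	0.6685	-0.9160	-1.3876	1.6620	0.1993	0.6629	1.3365	-0.6747	0.2520	1.6060	0.5860	-0.9081	-1.0216	-0.3111	-1.8427	-1.3416	-0.3466	1.8397	0.6650
cp32	-0.7688	0.6944	-0.2575	-1.2388	1.6874	0.6167	0.0889	-0.1518	0.7008	0.1696	-0.8527	-0.2918	0.6176	-0.0657	0.9504	-0.3198	-1.3587	0.0981	-0.4490	-0.9521
cp33	-2.6350	1.5530	0.0486	-1.1208	1.0742	1.1716	-0.5745	0.5345	-1.3108	0.4251	-0.8689	0.4517	-0.4533	1.3742	-0.5571	0.1684	-0.3476	1.1001	-0.1124	0.8005
cp34	0.0653	-1.0582	-0.7076	0.1146	0.0375	0.3801	2.2965	1.0622	0.2438	-0.1525	1.2724	-0.3818	0.8610	1.8505	0.9340	-0.1635	-0.2412	1.5934	-0.8276	0.2570
cp35	1.6650	0.2750	-0.0287	-0.5656	-0.5650	-0.6699	1.0875	0.4584	-3.6134	-0.3716	-1.3467	-0.6820	-0.0480	0.1999	0.1614	-0.0196	-0.5933	-1.6291	-1.5284	-0.1882
cp36	0.6077	-1.6425	-1.2722	-0.4734	0.6593	0.5220	-0.7488	-0.0858	0.6790	1.2523	0.2504	0.0098	0.3749	-0.4224	2.5120	1.2747	-0.3481	-0.1239	-0.3962	-0.1094
cp37	0.5518	1.3298	-0.0797	-0.8560	-0.4933	-0.4898	1.2145	1.4821	-1.2114	2.3119	0.0230	-0.3193	0.4109	1.0367	1.0808	-1.3599	0.2352	0.7713	-0.3242	1.0247
cp38	0.7363	-0.0684	-1.1211	1.8201	0.2934	-0.8764	-0.5825	0.6725	0.1329	0.0984	-2.0807	0.8614	0.3572	-0.4402	0.0871	-0.5718	1.1818	0.6293	0.0256	-1.2093
cp39	-0.4273	3.5440	1.2707	0.3079	1.4544	-0.1696	1.7733	0.6215	-1.0627	0.2654	0.8210	2.1332	-1.2698	-0.7926	-0.1322	-0.2340	0.4293	-1.8357	0.6001	0.0729
cp40	-0.4951	-0.9447	1.0122	1.2296	0.1256	0.2966	-0.2382	-0.1955	-0.5675	0.0283	0.5593	-0.9753	0.6628	-0.6424	-0.2643	-0.9268	-1.7190	-0.7273	-0.6835	-0.1441
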