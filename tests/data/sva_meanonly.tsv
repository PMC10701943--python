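	s0	s1	s2	s3	s4	s5	s6	s7	s8	s9
g0	 9.1316291350320444	 8.7820020030572650	 8.5221303040188232	 9.5055947566180148	 8.8092717654621069	 9.0847348403621417	 8.9438787019134445	 8.2602370556224471	 9.4653479635797222	 9.7453980547702486
g1	 4.8221373995956220	 6.1490358805184586	 4.0652588149081534	 5.4175720123932987	 5.7230911156301243	 5.7334053296069296	 5.8014787097630878	 5.4883706575236273	 5.2111222781305919	 4.6047046209367775
g2	10.6567730917246344	 9.9615227803246533	 8.9944911792447488	 9.4670208257684774	 9.1189962092199952	 9.8496232470311931	 9.5835844790293283	 9.7210020664854202	 9.4149541222344055	 9.3443738597790809
g3	 9.9146137866528328	 9.3336033457323087	 9.4807003494758479	 9.3953687492675311	10.4220299605342372	 9.9205067679462484	 9.3174660134782883	 9.8396274926434852	10.0616506576422982	 9.4995087100552542
g4	 3.7962425140637630	 3.7981171319077558	 3.8144654432234262	 3.5251076352847583	 3.8215664225398882	 3.8903218313823320	 2.7533271438101252	 3.4154126050682390	 3.8159727909317009	 3.7275111842426907
g5	 5.9013598473429525	 5.0174444063763080	 5.2288574750689927	 6.6857799750951399	 5.6899034139813587	 6.2576196308233056	 5.0743852622448165	 5.5788820381755153	 5.4189243794206137	 5.4821298944787200
g6	 9.7770975139152974	 8.0380349870847532	 9.2424427510406701	 9.6584191079768331	 8.4420924055201372	 7.4581860489033556	 8.4945978452031650	 7.6191003597430251	 8.8599945450469519	 7.9987066698989606
g7	 8.4047811047970029	 7.1550210878157321	 6.3992793108728598	 7.6120596661626641	 7.8418964997333678	 8.3797358503836250	 7.9952537597197733	 7.9691612434116719	 9.2174627136935516	 6.8829741329049350
g8	 7.2447112661239386	 7.0901893689605053	 7.2208187908305357	 6.9694471552876331	 7.8865804941484150	 6.9788015539789594	 6.0839031974247115	 6.1280787790132312	 7.6198925369262378	 7.4206445343796670
g9	 7.8027436179435936	 8.4880556275192536	 6.5088857254395629	 5.9376779597013520	 6.1028851059863385	 7.4946190511156807	 6.7185980585850933	 6.4597248771643763	 6.8478272582300779	 6.6472122213729357
g10	10.1266410617003881	 9.5429976981712272	 9.0432445641987265	 8.9291348471908467	 9.0547196194393198	 9.5367104358709156	 9.8157189204548665	10.3643915796489328	 9.8566020974400654	 9.8090394255293578
g11	 9.8101263126643552	 9.4026175411334858	 9.1726096902377474	10.0287875912700617	11.4801736036891313	 8.9334833004213507	10.0626787224133682	 8.7625401074040674	10.9260320464852398	 9.6561796355422000
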