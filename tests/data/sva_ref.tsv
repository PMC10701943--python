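	s0	s1	s2	s3	s4	s5	s6	s7	s8	s9
g0	 8.5783425938455800	 8.5116839935546036	 8.4621378281431916	 8.6496414794642842	 8.4091945918678448	 8.6846576667678796	 8.5438015283191824	 8.3945853065876328	 8.6223960494177572	 8.6753359231526161
g1	 6.2243901197338483	 6.2820491072016686	 6.1915007514388414	 6.2502641088677651	 6.2337848492702763	 6.2440990632470816	 6.3121724434032398	 6.2731862668751450	 6.2466906750376419	 6.1887376050747518
g2	 9.2473809935136941	 9.1030198616428510	 8.9022263140561400	 9.0003419329867302	 8.6532615124480863	 9.3838885502592841	 9.1178497822574194	 9.1324956332107590	 9.0325860690408071	 9.0095450932937897
g3	10.1128880477745060	 9.9850355137911553	10.0174045098459832	 9.9986271169678069	10.5611504050592320	10.0596272124712431	 9.4565864580032830	10.0409555059268367	10.1135113042987488	 9.9298067894759914
g4	 3.0429030906138612	 3.0433168080552901	 3.0469247869032849	 2.9830651728803845	 3.3480838612068582	 3.4168392700493020	 2.2798445824770952	 2.9469857392408847	 3.0784763435979552	 3.0494373363864389
g5	 5.4784398851603520	 5.2885565565205575	 5.3339724586994128	 5.6469495615460810	 5.4421291880783542	 6.0098454049203012	 4.8266110363418120	 5.4577539837164695	 5.4050967685689333	 5.4259036897931638
g6	 7.0508079607639011	 6.6790588219667777	 6.9365179656740406	 7.0254387779307539	 7.2045349385788313	 6.2206285819620497	 7.2570403782618591	 6.7347936698874493	 7.1294886480743642	 6.8555362006213780
g7	 8.4025494875929905	 8.1628064430954463	 8.0178315423173707	 8.2504807315483522	 7.9842247344776887	 8.5220640851279459	 8.1375819944640941	 8.2119686380144579	 8.4970159807321224	 7.9639398109121311
g8	 6.5277298270509423	 6.4936087525835227	 6.5224539603701510	 6.4669468092620814	 7.3892263370220475	 6.4814473968525919	 5.5865490402983440	 6.1987375944851610	 6.6784730611044125	 6.6143991557877362
g9	 6.1941015890877651	 6.3384409957120402	 5.9215911444279614	 5.8012842056704130	 5.3746387384172802	 6.7663726835466225	 5.9903516910160350	 5.9897286220660186	 6.1172552461414815	 6.0513351187799467
g10	 9.1849958569029173	 9.0604417778164414	 8.9537905327887675	 8.9294386226928602	 8.6121112844690941	 9.0941021009006899	 9.3731105854846408	 9.1598497658804785	 8.9959122121307793	 8.9805568171176269
g11	10.3676313712275494	10.2777489252749046	10.2270170891253258	10.4158605430374749	11.6324871100500644	 9.0857968067822839	10.2149922287743014	 9.9850140399659253	10.6824402443337760	10.2730888938279392
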