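	s0	s1	s2	s3	s4	s5	s6	s7	s8	s9
g0	9.044850572194159	8.6952234402193795	8.4353517411809378	9.4188161937801294	8.4091945918678448	8.6846576667678796	8.5438015283191824	8.7463615954952552	9.9514725034525302	10.231522594643057
g1	4.3965015065325161	5.7233999874553527	3.6396229218450484	4.9919361193301928	6.2337848492702763	6.2440990632470816	6.3121724434032398	5.580570162864956	5.3033217834719206	4.6969041262781062
g2	10.926884115759677	10.231633804359696	9.2646022032797912	9.7371318498035198	8.6532615124480863	9.3838885502592841	9.1178497822574194	9.8578335827075598	9.5517856384565452	9.4812053760012205
g3	9.5388311952553888	8.9578207543348647	9.104917758078404	9.0195861578700871	10.561150405059232	10.059627212471243	9.456586458003283	10.176872274714775	10.398895439713588	9.8367534921265438
g4	3.9712141520196007	3.9730887698635935	3.9894370811792639	3.700079273240596	3.3480838612068582	3.416839270049302	2.2798445824770952	3.6557252111844183	4.0562853970478798	3.96782379035887
g5	6.000695555758953	5.1167801147923084	5.3281931834849932	6.7851156835111404	5.4421291880783542	6.0098454049203012	4.826611036341812	5.7269838141637441	5.5670261554088425	5.6302316704669488
g6	10.906765847301619	9.1677033204710732	10.37211108442699	10.788087441363155	7.2045349385788313	6.2206285819620497	7.2570403782618591	7.4595932171128556	8.7004874024167833	7.8391995272687911
g7	7.6222217706223363	6.3724617536410655	5.6167199766981941	6.8295003319879974	7.9842247344776887	8.5220640851279459	8.1375819944640941	8.8044353642909403	10.052736834572819	7.7182482537842034
g8	7.3420973598981059	7.1875754627346726	7.318204884604703	7.0668332490618004	7.3892263370220475	6.4814473968525919	5.586549040298344	6.4999048439738205	7.9917186018868271	7.7924705993402563
g9	8.2836576141204787	8.9689696236961396	6.989799721616448	6.4185919558782372	5.3746387384172802	6.7663726835466225	5.990351691016035	6.6108381749974523	6.9989405560631539	6.7983255192060117
g10	9.7683569301047992	9.1847135665756383	8.6849604326031375	8.5708507155952578	8.6121112844690941	9.0941021009006899	9.3731105854846408	11.191389671613662	10.683600189404794	10.636037517494087
g11	9.3268359895865753	8.9193272180557059	8.6893193671599676	9.5454972681922818	11.632487110050064	9.0857968067822839	10.214992228774301	9.2550318602486339	11.418523799329808	10.148671388386767
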