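	s0	s1	s2	s3	s4	s5	s6	s7	s8	s9
g0	 9.1532950383750169	 8.8481219630279941	 8.5929815063571073	 9.5090941814692336	 8.5836992300766006	 8.8290107325003344	 8.6948638514510748	 8.5906011872329771	 9.6477919890467021	 9.7632656099415271
g1	 5.0452257352526289	 6.0605220461261089	 4.4234157559765350	 5.5552241158148323	 5.0425988672716731	 5.0450210539263640	 5.1109120501557559	 6.0071354294501100	 5.6537183911814273	 5.0445416358755093
g2	10.3298836716070852	 9.8120017536311828	 9.1080213027565993	 9.4351260005126996	 9.2622243816345886	 9.9503927222729835	 9.7015401887843105	 9.8418587344027504	 9.4767661178325149	 9.3487067238644279
g3	 9.9833878305575343	 9.5142667330823691	 9.6001589373843661	 9.5922051143893512	 9.9572032491930500	 9.5114069107359800	 9.0328971391132349	10.0521371047512478	10.2209667730795388	 9.6284678901413052
g4	 3.7279105050232801	 3.7314821524095945	 3.7360486703001099	 3.4954118950370523	 3.7179650738872643	 3.7324994101522275	 2.9218497140503530	 3.4801029354782611	 3.9324186914739752	 3.8806740882005886
g5	 5.8290646622141091	 5.1409896465616258	 5.2692526488294220	 6.4833817826178111	 5.4358957253657456	 5.8874959804064071	 4.8756608059527782	 5.9751338022109222	 5.6798678027156155	 5.8562058265692345
g6	 9.2453650232230817	 7.9700208534569255	 8.7760531561648687	 9.2443830407099661	 8.3262705836047797	 7.4033791078475657	 8.3215730567213004	 8.2986598559627005	 9.6669753773342464	 8.7879658824283453
g7	 8.4955390510740223	 7.5137531892176623	 6.7987986230336457	 7.9665984226500886	 6.9694382786497338	 7.3506007669382303	 7.0092039332413654	 8.4675394503318895	 9.7151903353143965	 7.3173572434839169
g8	 7.2079996896310865	 7.0807094570128735	 7.1513494559254687	 7.0096340831009556	 7.3614346484728603	 6.5356806100309859	 5.7958481685852075	 6.6019201204017399	 8.0624954767359220	 7.8338242155435509
g9	 7.4714294715050347	 7.9781316309364101	 6.5296461738304243	 6.0436094983402935	 6.3870664406337125	 7.6814918083095041	 6.9677990725905410	 6.4695993671241245	 7.0564440036764076	 6.7106755089605805
g10	10.0665162211244059	 9.6164272653350391	 9.2778351471453551	 9.1190852789425918	 9.3493616315434238	 9.8134581521233137	10.0751032993799452	 9.9064094156882074	 9.3847600505218161	 9.2896811753728201
g11	 9.9915314298908466	 9.6475312532755257	 9.3527778822138821	10.2745536380800182	10.0332106538478243	 7.8859909031755455	 8.7053425219588902	 9.7099806049312125	11.9035853467147241	10.6859655912204463
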