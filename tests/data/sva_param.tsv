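	s0	s1	s2	s3	s4	s5	s6	s7	s8	s9
g0	 9.1378260012452692	 8.8205237269249004	 8.5846785261515670	 9.4772165444695275	 8.8455097081782217	 9.1294593414003469	 8.9842636600404866	 8.3949097207139296	 9.3304635027132026	 9.5478724733171152
g1	 5.0120450016645748	 6.0087567084834799	 4.4435088575325405	 5.4593110568701491	 5.4701341206482867	 5.4806459492451491	 5.5500235776150637	 5.6170514404442873	 5.3294949392237383	 4.7005306143004519
g2	10.3555206840399254	 9.8269075777626060	 9.0916535690504983	 9.4509275746299490	 9.1964470529626574	 9.8893658381067748	 9.6370575462081582	 9.8233549742509947	 9.4766897374703980	 9.3967423832870818
g3	10.0060423266488350	 9.4633151139401583	 9.6007197821128063	 9.5210107471707559	10.2006074556844499	 9.8274275627551422	 9.3787091634662012	 9.7926324294461935	10.0210463474792739	 9.4427236092200033
g4	 3.7315239177340764	 3.7334141306282072	 3.7498984444552454	 3.4581334528140073	 3.7865437277021514	 3.8340297840133273	 3.0487622004362218	 3.3844802273497416	 3.8211355395582522	 3.7247025143837957
g5	 5.8210984935547545	 5.1252552488362548	 5.2916855982530873	 6.4386162125807536	 5.6717926624722024	 6.1698781185820923	 5.1317682096618915	 5.6801907115235029	 5.4927626179036642	 5.5668227741088323
g6	 9.3003621246927466	 7.9109266295609615	 8.8731961696346726	 9.2055432282054053	 8.6550672289339392	 7.7743906155733358	 8.7020638892279720	 7.8680200643642610	 9.0526188041676381	 8.2304048365372342
g7	 8.4953197916454073	 7.4222671504037505	 6.7733820053948559	 7.8146836519566696	 7.6625027218557422	 8.2097590043487152	 7.8185450863499000	 7.8550478973081601	 8.8817861956877699	 6.9616500025578469
g8	 7.2041889186105879	 7.0445113996131781	 7.1794992710745991	 6.9197406229694787	 7.7290955980080041	 7.0205035168967242	 6.3219657333087209	 6.2506353897536604	 7.5529446912522467	 7.3790070762885529
g9	 7.4990511948994047	 8.0220503150737734	 6.5116373892822068	 6.0757174655925139	 6.2333991981133288	 7.5210760804743080	 6.8030765692849826	 6.5832556687167081	 7.0332965482748806	 6.8006647169733894
g10	10.0834434087293445	 9.6186850973421532	 9.2207290214757798	 9.1298628475356338	 9.1516065277623415	 9.5903930972767402	 9.8443920774282159	10.1326243537540961	 9.6313812114325561	 9.5844317097965117
g11	 9.9572430916066779	 9.5489361381339766	 9.3184777739587936	10.1763326591135179	11.0197191232626448	 9.0423299977932547	 9.9190988554402750	 8.8893165924860167	10.8285144528712944	 9.6903104994275644
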