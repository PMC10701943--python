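	s0	s1	s2	s3	s4	s5	s6	s7	s8	s9
g0	 9.0965735068451092	 8.8716040203792179	 8.7043881571552095	 9.3372037272999755	 8.9322243684481730	 9.1882152146288316	 9.0573160656800749	 8.5189278520741070	 9.3372364716391107	 9.5273993869508846
g1	 5.1233430422975692	 6.0999939727387229	 4.5662498022390743	 5.5616069916249309	 5.6069287189993915	 5.6129717883065835	 5.6528557925732805	 5.4771167770575948	 5.2419422130970368	 4.7275514403871819
g2	10.2554233612581882	 9.8158500199896803	 9.2044424376716343	 9.5032002119078065	 9.2560434907653484	 9.8563401571243965	 9.6377577925403806	 9.8842401350690707	 9.5258596545092473	 9.4432105504981738
g3	 9.9239809507941334	 9.4965432463540687	 9.6047595557039216	 9.5419828123953963	10.1755849648890262	 9.8653224880571280	 9.4922571525413026	 9.8224967862704720	 9.9805763739537703	 9.5803336006624242
g4	 3.7257636426773315	 3.7269791118191193	 3.7375790684920003	 3.5499645700960909	 3.7039852164808087	 3.7530098783303796	 2.9422986772564661	 3.4208397038546443	 3.7263989774306259	 3.6589178217061979
g5	 5.7187770736258550	 5.1444858021938282	 5.2818436018087915	 6.2284249557932121	 5.7676509089691175	 6.1584091192242125	 5.3439906994897459	 5.9334667698284376	 5.5710858010560589	 5.7142766676691394
g6	 9.6568005517272386	 8.5919941974435101	 9.3294380905887504	 9.5841352399228086	 8.3628963773781759	 7.8135563225014097	 8.3922115057161832	 7.5321443946543365	 8.5857654942919677	 7.8544613356737027
g7	 8.4536921715368791	 7.4952871444614209	 6.9157305029051388	 7.8457768905753626	 7.7859103899466815	 8.1267825735671497	 7.8831052568198778	 7.9586435939842239	 8.7925654162534315	 7.2330214938079216
g8	 7.1266472736878228	 6.9796506873458863	 7.1039183765421017	 6.8647886932654707	 7.7458520926627061	 7.0606441123889176	 6.3851586298435699	 6.2961031840605166	 7.3329784778672105	 7.1944924704249065
g9	 7.4659481672806578	 7.8962896791516712	 6.6534704143354064	 6.2947806349859228	 6.3542751264196786	 7.5067761797588739	 6.8641497536126677	 6.3870963905105231	 7.0548164225486349	 6.7096634799932504
g10	10.0920402314778741	 9.6639035731242213	 9.2973053212620442	 9.2135991472895995	 9.1536540973058482	 9.5525191239446912	 9.7834088480683778	10.1931882036727934	 9.9004420649955680	 9.8730216692708215
g11	10.0422798007354963	 9.7098845479175555	 9.5222725918328059	10.2206366265544766	10.8022032508632329	 9.2602605647169778	 9.9439536780634512	 8.9059532951960829	10.4243092931478483	 9.5331166846430406
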