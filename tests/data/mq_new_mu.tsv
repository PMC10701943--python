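	V1	V2	V3	V4	V5	V6
1	20.2765762957278639	 8.5094664280768484	25.9271637082565576	53.7548018817324191	44.1459127247799188	22.4880026443861425
2	16.6984735580626875	23.4518120426218957	54.2494984297081828	32.6836717152036726	26.3897804904263467	48.0568235344253480
3	20.6634764536283910	44.8049270641058683	40.4373669601045549	53.2381648663431406	10.5480219400487840	19.7129514045082033
4	54.2301756620872766	23.5688433423638344	45.7593256793916225	15.4056492343079299	56.0016148723661900	17.0254906686022878
5	29.5429427828639746	39.6727767365518957	38.2916895591188222	46.6956678812857717	20.5777875171042979	33.4238260018173605
6	47.8991689381655306	51.2338004703633487	54.6694886323530227	44.8474390967749059	37.4815237347502261	19.7922825615387410
7	53.4340469178277999	52.0872415590565652	21.1551585304550827	56.9048650062177330	11.0698332719039172	14.9642580037470907
8	27.7218315226491541	26.5247604565229267	15.5193060438614339	35.1205622858833522	51.2278867664281279	33.5216875618789345
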