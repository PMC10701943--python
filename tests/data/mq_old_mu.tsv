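	V1	V2	V3	V4	V5	V6
1	58.6893882206641138	29.5456391735933721	33.1143381074070930	56.0738359799142927	18.1377772765699774	38.8054734421893954
2	45.2485881536267698	40.2055574825499207	16.4149812306277454	37.8950832295231521	19.1991259669885039	35.6437746365554631
3	24.6199801645707339	59.5511241024360061	17.5761978502850980	35.8495411404874176	45.1120292849373072	23.0827525479253381
4	28.7310529802925885	32.2576467820908874	37.7641597972251475	33.9315248152706772	29.8913957271724939	29.9222294997889549
5	13.1516358372755349	31.6392238403204829	36.6179709054995328	59.1802373132668436	14.6319722628686577	32.5242534943390638
6	 5.7192666514310986	14.5393284177407622	 9.2385409155394882	32.9203002282883972	46.0684048291295767	14.9476498621515930
7	44.3561336351558566	46.5151519479695708	 6.9547318771947175	42.5533443270251155	10.7743202219717205	34.1296831541694701
8	10.6751329661346972	29.9642519070766866	40.3537520708050579	38.0847669707145542	52.5499721965752542	 9.1401660139672458
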