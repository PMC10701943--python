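	old_phi	new_phi
1	0.58464378900825975	0.82770295396912841
2	0.17269901174586266	0.34287771417293694
3	0.29354922381462528	0.66710048747481776
4	0.73203851218568161	0.95568767855875192
5	0.96333943960489710	0.95604601752711460
6	0.14513380423886701	0.37298024324700235
7	0.77506155503215268	0.29935040461132301
8	0.95056803693296388	0.20718123652040960
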