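	V1	V2	V3	V4	V5	V6
1	8	8	26	20	67	11
2	13	21	124	20	57	44
3	34	16	97	34	7	26
4	59	18	39	12	52	20
5	47	36	32	26	39	33
6	32	112	127	35	21	41
7	49	43	62	42	26	14
8	54	32	17	38	42	75
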