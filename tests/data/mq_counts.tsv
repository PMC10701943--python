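	V1	V2	V3	V4	V5	V6
1	26	28	34	26	27	21
2	37	38	33	27	36	34
3	36	32	35	28	34	29
4	32	26	34	27	29	34
5	21	28	30	32	28	32
6	32	27	19	29	33	26
7	34	29	32	22	33	25
8	33	35	35	35	26	37
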