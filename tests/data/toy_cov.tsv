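	x
s0	-0.15663789765809041
s1	-0.040762526135434025
s2	-0.65478769542939042
s3	0.44607220148208054
s4	-0.45498348034078001
s5	-1.2256057637672482
s6	-1.2779375743196193
s7	0.17258791772211948
s8	1.5790912564104349
s9	0.15999161357343825
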