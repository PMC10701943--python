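sample	batch
s0	A
s1	A
s2	A
s3	A
s4	B
s5	B
s6	B
s7	C
s8	C
s9	C
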