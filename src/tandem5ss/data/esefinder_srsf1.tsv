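pos	A	C	G	T
1	-1.14	1.37	-0.21	-1.58
2	0.62	-1.10	0.17	-1.58
3	-1.58	0.73	0.48	-1.58
4	1.32	0.33	-1.58	-1.13
5	-1.58	0.94	0.33	-1.58
6	-1.58	-1.58	0.99	-1.13
7	0.62	-1.58	-0.11	0.27
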