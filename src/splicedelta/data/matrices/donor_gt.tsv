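#name=donor_GT
#site_kind=donor
#core=1,2
offset	A	C	G	T
-3	0.33	0.37	0.18	0.12
-2	0.61	0.13	0.12	0.14
-1	0.10	0.04	0.78	0.08
1	0.00	0.00	1.00	0.00
2	0.00	0.00	0.00	1.00
3	0.53	0.03	0.42	0.02
4	0.71	0.08	0.12	0.09
5	0.07	0.06	0.84	0.03
6	0.16	0.16	0.22	0.46
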