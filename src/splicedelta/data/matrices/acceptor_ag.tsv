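#name=acceptor_AG
#site_kind=acceptor
#core=-2,-1
offset	A	C	G	T
-14	0.10	0.31	0.15	0.44
-13	0.09	0.33	0.13	0.45
-12	0.07	0.31	0.11	0.51
-11	0.07	0.35	0.07	0.51
-10	0.09	0.37	0.09	0.45
-9	0.10	0.38	0.09	0.43
-8	0.09	0.39	0.12	0.40
-7	0.09	0.41	0.09	0.41
-6	0.09	0.41	0.08	0.42
-5	0.09	0.40	0.08	0.43
-4	0.23	0.28	0.26	0.23
-3	0.04	0.74	0.01	0.21
-2	1.00	0.00	0.00	0.00
-1	0.00	0.00	1.00	0.00
1	0.25	0.13	0.49	0.13
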