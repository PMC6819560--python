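# Demonstration minor-allele-frequency snapshot (position, ref, alt, maf).
# SYNTHETIC data shaped like a MITOMAP-style frequency export: entries cover
# the packaged haplogroup tree's defining variants, a panel of common
# polymorphisms, the two planted pathogenic mutations and a few notable
# rare variants. source_size mirrors the nominal number of sequences a
# frequency snapshot of this kind would be based on.
position	ref	alt	maf	source_size
73	A	G	0.55	30589
204	T	C	0.05	30589
295	C	T	0.07	30589
462	C	T	0.04	30589
489	T	C	0.07	30589
709	G	A	0.10	30589
980	T	C	0.55	30589
1243	T	C	0.04	30589
1555	A	G	0.0033	30589
2220	A	G	0.60	30589
2702	G	A	0.02	30589
2831	G	A	0.15	30589
3010	G	A	0.12	30589
3243	A	G	0.0014	30589
3308	T	C	0.002	30589
3480	A	G	0.05	30589
4216	T	C	0.11	30589
4580	G	A	0.06	30589
4917	A	G	0.09	30589
5319	A	T	0.0005	30589
5600	T	C	0.15	30589
6221	T	C	0.02	30589
6261	G	A	0.012	30589
7028	C	T	0.55	30589
7476	C	T	0.02	30589
8584	G	A	0.15	30589
8701	A	G	0.08	30589
8860	A	G	0.10	30589
9055	G	A	0.05	30589
9822	C	T	0.0005	30589
9966	G	A	0.004	30589
10034	T	C	0.03	30589
10238	T	C	0.02	30589
10398	A	G	0.20	30589
10463	T	C	0.09	30589
11299	T	C	0.05	30589
11467	A	G	0.18	30589
11719	G	A	0.50	30589
11812	A	G	0.04	30589
12280	A	G	0.10	30589
12308	A	G	0.18	30589
12372	G	A	0.18	30589
12612	A	G	0.07	30589
12940	G	A	0.0005	30589
13368	G	A	0.09	30589
13708	G	A	0.08	30589
13928	G	C	0.12	30589
14233	A	G	0.04	30589
14470	T	C	0.02	30589
14766	C	T	0.09	30589
14798	T	C	0.07	30589
15257	G	A	0.02	30589
15326	A	G	0.08	30589
15452	C	A	0.08	30589
15904	C	T	0.06	30589
16069	C	T	0.07	30589
16126	T	C	0.11	30589
16129	G	A	0.06	30589
16182	A	C	0.03	30589
16183	A	C	0.05	30589
16311	T	C	0.18	30589
16519	T	C	0.60	30589
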