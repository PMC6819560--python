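# Demonstration pathogenicity-probability table (position, ref, alt,
# probability) for nonsynonymous variants, shaped like an APOGEE-style
# meta-predictor export. SYNTHETIC data: probabilities are illustrative.
# The five variants connecting L3 and the reference node carry no entry on
# purpose (no probabilities are estimated for them; they are also on the
# load exclusion list).
position	ref	alt	probability
3308	T	C	0.45
4216	T	C	0.35
4917	A	G	0.25
5319	A	T	0.42
6261	G	A	0.40
8584	G	A	0.15
9055	G	A	0.45
9822	C	T	0.47
9966	G	A	0.38
12940	G	A	0.43
13708	G	A	0.28
13928	G	C	0.35
14798	T	C	0.25
15257	G	A	0.55
15452	C	A	0.30
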