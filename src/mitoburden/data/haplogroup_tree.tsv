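# Reduced haplogroup tree for the European mtDNA haplogroups handled by the
# pipeline. SYNTHETIC curated data: topology and the rCRS-relative
# defining-variant sets are loosely modelled on well-known diagnostic
# positions but are NOT transcribed PhyloTree rows; a user-supplied tree
# file can override this one everywhere. The root is the L3 outgroup; the
# reference haplotype's own node is H, reached from the root with no added
# variants (profiles are stored as differences from rCRS).
# columns: label, parent (- for root), defining variants (comma-separated, - for none)
L3	-	-
H	L3	-
V	L3	m.4580G>A,m.15904C>T
U	L3	m.11467A>G,m.12308A>G,m.12372G>A
K	U	m.3480A>G,m.9055G>A,m.11299T>C
JT	L3	m.4216T>C,m.16126T>C
J	JT	m.295C>T,m.489T>C,m.10398A>G,m.12612A>G,m.13708G>A,m.16069C>T
J1	J	m.462C>T,m.3010G>A
J2	J	m.7476C>T,m.15257G>A
T	JT	m.709G>A,m.4917A>G,m.10463T>C,m.13368G>A
T2	T	m.11812A>G,m.14233A>G
T2c	T2	m.6261G>A
W	L3	m.204T>C,m.1243T>C
N1	L3	m.2702G>A,m.10238T>C
I	N1	m.10034T>C,m.16129G>A
X	L3	m.6221T>C,m.14470T>C
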