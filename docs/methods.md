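# Methods

`mitoburden` implements a cohort analysis of functional variation in human
mitochondrial DNA: variants called against the rCRS coordinate system are
classified by functional category and population rarity, subjects are
stratified by haplogroup, and the groups are contrasted with pooled
rare-vs-common burden statistics, mutational-load sums and binomial
carrier probabilities. This note records the models, the defaults and the
design decisions.

## Coordinate system and reference

All positions are 1-based rCRS coordinates (`m.<pos><ref>><alt>`
notation); there is no internal 0-based representation. The historical
placeholder at position 3107 is kept as `N` so positions match published
numbering, and it never produces a variant call.

The packaged default genome is a **synthetic stand-in** for the rCRS,
built deterministically by `mitoburden.synthref`. It reproduces the real
NC_012920 gene coordinates, valid open reading frames under the
vertebrate mitochondrial code (including both frames of the ATP8/ATP6 and
ND4L/ND4 overlaps and the polyadenylation-completed stop codons), and the
real reference alleles and codon consequences at every position the
pipeline's rules, packaged tree and demo tables reference. Everything
else is pseudo-random sequence. Analyses of real data must supply the
real rCRS FASTA via `load_reference(fasta_path=...)` or the
`--reference-fasta` CLI flag; the synthetic genome exists so the package,
its tests and its simulations are self-contained.

The packaged gene map regularises the source annotation slightly: the
1-bp MT-ATP6/MT-CO3 junction overlap and the MT-TI/MT-TQ and MT-TC/MT-TY
tRNA overlaps are trimmed, so exactly two (protein) overlaps remain.
Reading-frame phases are unchanged; no documented codon consequence is
affected.

## Translation and codon context

Translation uses the vertebrate mitochondrial code (table 2): `ATA` →
Met, `TGA` → Trp, `AGA`/`AGG` → stop. The light-strand gene (MT-ND6) is
reverse-complemented and read in its own 5'→3' orientation before codon
arithmetic. Genes whose mRNA stop codon is completed by polyadenylation
have their terminal partial codon completed with `A` bases; variants in
such partial codons are evaluated after completion.

## Functional categories

A substitution is **nonsynonymous** if it changes the encoded amino acid
in *any* overlapping reading frame (all per-gene consequences are kept);
otherwise it is **tRNA**, **rRNA**, **synonymous** or **noncoding** by
feature. Indels are carried through I/O and filtering but are never
functional. Functional = nonsynonymous ∪ tRNA ∪ rRNA, restricted to
substitutions. The category precedence for multi-feature hits is
nonsynonymous > tRNA > rRNA > synonymous > noncoding (only defensive:
the gene map contains no protein/tRNA overlaps).

## Rarity

A functional variant is **rare** when its minor allele frequency in the
frequency table is < 1% and **common** when MAF ≥ 1% (boundary inclusive
on the common side); the threshold is a parameter (`--rare-maf-threshold`,
default 0.01). Variants absent from the table default to MAF 0 and hence
rare — unseen in the frequency source means below any threshold; a
`missing_policy="unclassified"` mode exists for sensitivity analyses.
Frequencies are file inputs (a MITOMAP-style snapshot); the packaged
`demo_frequencies.tsv` is synthetic demonstration data.

## Exclusion lists

* **Hotspots** (removed before haplogroup assignment): m.523_524delAC,
  m.16182A>C, m.16183A>C, m.16519T>C, and C-insertions at 309, 315 and
  16193. All are noncoding or indels, so functional counts are unchanged.
* **Back-mutation-prone variants** (removed from all counting): m.9966G>A
  and m.2702G>A in subclade N1, m.6261G>A in subclade T2c, m.10398A>G in
  haplogroup J. By default removal is conditional on the subject's
  haplogroup equalling or descending from the named clade; a `strict`
  mode removes them unconditionally for replication robustness.
* **Load exclusions** (mutational load only): the five variants that
  connect the L3 outgroup with the reference haplotype, written here in
  rCRS-relative orientation — m.10398A>G, m.8701A>G, m.14766C>T,
  m.15326A>G, m.8860A>G.

All three lists are configuration (JSON override via `--exclusions`).

## Haplogroup assignment

The packaged tree is a **synthetic reduced tree** of 16 European-style
nodes (L3 outgroup root; H, V, U, K, JT, J, J1, J2, T, T2, T2c, W, N1,
I, X) with rCRS-relative defining variants loosely modelled on well-known
diagnostic positions — it is deliberately not a PhyloTree transcription,
and a user tree file overrides it. The reference haplotype's own node (H)
is reached from the root with no added variants, so an empty profile maps
to H.

Scoring: for each node, score = |observed ∩ root-path defining variants|
/ |root-path defining variants| (1.0 on an empty path). The winning node
is the one that *explains* the most observed path variants, with ties
broken by score, then depth, then lexicographically smallest label. The
explained-count ranking is required for consistency: the reference node's
empty path matches any profile vacuously with score 1.0, so a score-only
ranking could never assign an imperfect real lineage. Private variants
never penalise a call; heteroplasmy fractions are ignored. A metadata
haplogroup, when present, overrides the computed call, which is kept with
a QC flag. The J/K stratum is tree-descent from J or K (so J1, J2, K are
members; the JT ancestor is not), with a guarded prefix fallback for
labels outside the reduced tree ("J1c2" matches, "JT" does not).

## Statistics

* **Burden test**: Pearson chi-square without continuity correction on
  the groups × {rare, common} table of *pooled* functional-variant
  counts, df = groups − 1. Pooling matches the whole-cohort framing of
  the summary tables. Pooled counting treats variant occurrences as
  independent draws; because per-subject common counts are partly
  determined by the haplogroup backbone, a subject-label permutation
  variant of the same statistic (`mode="permutation"`) is provided as a
  robustness option. Under the generator's default conditions the
  per-subject count dispersion is close to Poisson and the pooled test is
  empirically well calibrated (checked over 1,000 null cohorts).
* **Ratio of ratios**: (rare/common in stratum A) / (rare/common in
  stratum B); scale-invariant; undefined (error) on zero denominators.
* **Mutational load**: per subject, the sum of pathogenicity
  probabilities over nonsynonymous variants, split by rarity, after the
  load exclusions. The default sums *all* nonsynonymous probabilities;
  `mode="nonneutral"` sums only those > 0.5 — both are provided because
  either reading of "the sum of these probabilities" is defensible.
  Variants without a table entry contribute 0 and are reported.
* **Carrier probability**: binomial pmf, P(K=k) = C(n,k)·f^k·(1−f)^(n−k).
* **Rank tests**: Mann–Whitney U (two groups; exact for small untied
  samples, tie-corrected normal approximation otherwise) or
  Kruskal–Wallis (more groups); all-identical input yields p = 1 with a
  flag.
* Sample SD uses the n − 1 denominator; single-subject groups report
  SD 0 with a flag. Reported p-values are raw (no multiple-testing
  correction). Summary tables print category × rarity means ± SD with a
  totals row per rarity that equals the sum of the category means.

## Synthetic cohorts

The generator emulates the study structure: default group sizes 52
(endurance), 89 (sprint), 77 (control); a haplogroup drawn per subject
from a frequency vector (defaults place ~10% of subjects in the J/K
stratum); the node's root-path variants as backbone; common polymorphisms
drawn per site as Bernoulli(MAF) from the frequency table's ≥ 1% entries
(excluding tree-defining sites — lineage markers enter only via the
backbone); private rare variants per category as Poisson draws with
group-specific rates (defaults are the published per-subject rare means:
endurance 0.83/0.19/0.37, sprint 0.63/0.10/0.36, control 0.61/0.14/0.19
for nonsynonymous/tRNA/rRNA); and pathogenic variants planted by
Bernoulli draws at their population frequencies (m.3243A>G at 0.14%,
heteroplasmy 0.43; m.1555A>G at 0.33%, homoplasmic). Private positions
avoid every frequency-table and exclusion-list site, so they are rare by
construction and untouched by filters; requested nonsynonymous
consequences are enforced by rejection sampling through the annotation
module. Per-subject substreams derive from (seed, group, subject index),
so resizing one group never reshuffles another subject.

What the generator does **not** emulate: phylogenetic realism beyond the
reduced tree (no coalescent structure, no recurrent mutation except the
independent re-draws of common sites), sequencing error, indel
polymorphism beyond what tests construct explicitly, and real
linkage between control-region motifs and coding variants. Passing tests
therefore demonstrate the correctness and calibration of the analysis
machinery under the assumed generative structure, not the biological
claims themselves.

## Numerical choices and problem sizes

* Chi-square oracle equivalence is checked exhaustively on every 2×2
  integer table with cells ≤ 20 and on a seeded sample of 20,000 3×2
  tables (the full 3×2 grid has ~8.6×10⁷ tables; a sample is the
  package's chosen problem size).
* Annotation/oracle equivalence is checked at 1,000 sampled
  protein-coding positions × all three alternate bases.
* Null calibration uses 1,000 simulated cohorts at default sizes with
  equal rates across groups and a 99% binomial acceptance interval
  around α = 0.05.
* The reconstruction consistency check rebuilds the pooled rare/common
  table from the published per-subject means × group sizes
  (72/153, 97/282, 72/250) and recovers a chi-square p that rounds to the
  printed 0.04; the published stratum means likewise give the printed
  0.42 ratio of ratios. These are rounding-limited consistency checks of
  the statistics layer, not replications from raw data.
* Full-cohort replication (the deposited GenBank sequences, the exact
  MITOMAP snapshot) is out of desk scope: sequence-level results here use
  the synthetic reference, and the published cohort totals are
  version-sensitive to the frequency snapshot. The sequence → counts
  path itself is exercised end to end on constructed full-length
  sequences.

## Known limitations

* The default reference is synthetic; real-data runs must supply the real
  rCRS FASTA and a real frequency/pathogenicity snapshot.
* The reduced tree supports stratification, not fine haplotyping; there
  is no back-mutation path logic (`@`-style) beyond the exclusion lists.
* Heteroplasmic variants count as present regardless of fraction (the
  fraction is recorded); IUPAC-derived calls carry an unknown fraction.
* Insertions/deletions are parsed, filtered and reported but never enter
  functional counts or loads.
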