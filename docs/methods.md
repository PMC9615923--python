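# Methods

This note documents the statistical procedures, the synthetic-data model,
and the numerical and design choices behind `virotax`.

## Data model

A *record* is one deposited nucleotide sequence (a genome or one segment),
stored upper-case with U normalized to T so that a single A/C/G/T k-mer
alphabet serves RNA and DNA deposits. Records are grouped into per-species
*assemblies* using the species string as the grouping key: species is the
only ICTV rank shared by all segments of one virus, and deposits do not
otherwise link segments to each other. Segment order within an assembly is
lexicographic by (segment label, accession). The genome-scale length of an
assembly is the sum of its segment lengths ("multiple-segments" length);
for a non-segmented virus it is the single record's length.

Host categories form a closed vocabulary (fungi, plants,
plants+invertebrates, invertebrates, invertebrates+vertebrates,
vertebrates, unknown). Unrecognized host strings are mapped to `unknown`
with a warning rather than rejected, so a single bad row does not abort an
ingest; `unknown` is retained in the data model but always excluded from
host contrasts.

## Composition

GC content is (G+C) / denominator. The default denominator is the full
residue count — ambiguity codes and N dilute GC — matching how standard
sequence-statistics tools report GC on deposited genomes; an `acgt_only`
flag restricts the denominator to unambiguous calls. Per-virus GC is the
length-weighted mean over segments, i.e. total GC count over total length.

## ORF calling

The caller is a fully specified six-frame scanner rather than a heuristic
gene finder, so its output is deterministic and auditable. In each of the
six reading frames it reports, per stop codon, at most one ORF: the one
opening at the earliest in-frame start codon after the previous stop
("longest per stop"). ORFs truncated by sequence ends are not reported.
Defaults: minimum length 90 nt (stop included), ATG-only starts, standard
genetic code; all three are configurable. Coordinates are reported on the
forward strand, 1-based inclusive, GFF3-compatible.

Absolute counts from this caller will not equal those of a trained gene
finder; the analysis target is the *scaling* of ORF count with genome
length, which is robust to the caller's conventions. Both Pearson and
Spearman statistics are reported because the relationship is expected to be
monotone but not necessarily linear.

## Genus genome deviation

For genome *i* in genus *g*: `d_i = (L_i − mean_g(L)) / mean_g(L)`, with
the mean taken over the genus's complete genomes, focal genome included.
Multi-segment viruses enter via their total length. Within a genus the
signed deviations sum to zero identically; the test suite requires this to
1e−12 relative tolerance. Genera with fewer than `min_members` (default 2)
complete genomes are skipped and listed: a single-member genus would
contribute a deviation of exactly 0 by construction and inflate the
consistency fraction. The headline screen reports the share of genomes with
`|d_i| < τ` (default τ = 0.20), counting the boundary `|d_i| = τ` as
exceeding.

## Host contrasts

Only complete genomes enter host contrasts, and only host groups with
strictly more than `min_host_n` (default 40) of them survive the screen.
Pairwise contrasts use the two-sided Wilcoxon rank-sum (Mann-Whitney) test:
exact null enumeration when the pooled sample is tie-free with at most 16
observations, otherwise the normal approximation with tie and continuity
correction (scipy's implementation; the test suite checks the exact branch
against full permutation enumeration for all group sizes up to 7).
Significance codes are **** p ≤ 1e−4, *** p ≤ 1e−3, ** p ≤ 0.01,
* p ≤ 0.1, ns otherwise; the outer two follow the convention of the
analysis this package operationalizes, the inner two are the usual fill-in
and configurable. Raw p-values are always reported alongside the codes; no
multiple-testing correction is applied.

## Segment classes

Three length populations are compared: each individual segment length of
segmented viruses ("single-segment"), per-virus totals of segmented viruses
("multiple-segments"), and totals of non-segmented viruses. Densities are
Gaussian KDEs with Silverman bandwidth evaluated on one shared grid; the
grid is padded by three bandwidths past the pooled data range so each
density integrates to ≈1 over the grid even for classes concentrated at an
edge. Mode extraction takes local maxima of the evaluated density, tallest
first, discarding peaks below 5% of the tallest. Per-genus architecture
tables rank segments within each virus by descending length and average
per rank over the members having the genus's modal segment count (ties in
the mode broken toward fewer segments).

## Similarity

**Nucleotide.** Distinct k-mer sets (default k = 10; windows containing
non-ACGT characters are skipped) compared with the Dice coefficient
`2|A∩B| / (|A|+|B|)`, defined as 0 when both sets are empty. Set semantics
(distinct k-mers) is the documented default reading of "number of shared
segments over the sum of segments"; k-mers are not canonicalized across
strands — deposits are compared as given. Multi-segment genomes contribute
the union of their segments' sets; windows never span segment junctions.

**Protein.** Each genome is translated in all six frames (ambiguous codons
→ X), translations are split at stop codons, and fragments of at least
`min_fragment_aa` (default 20) residues are kept. Every cross-genome
fragment pair is aligned locally with BLOSUM62, gap open 11, extend 1 —
BLAST's default protein scoring — and identity is matches over aligned
columns (gaps included) of the pair's best-scoring alignment. Alignments
spanning fewer than 20 columns are ignored. The genome-pair similarity is
the maximum identity over all fragment pairs, in percent; genomes with no
qualifying fragments give 0 with a warning. E-value statistics, seeding
heuristics and X-drop are out of scope: this is a transparent analog of a
translated-vs-translated search, not an emulation of one.

All-pairs fragment alignment is the pipeline's cost hotspot (quadratic in
both genomes and fragments). The orchestration layer therefore keeps only
the longest 20 fragments per genome by default (configurable, including
off) and refuses cohorts above 500 viruses without an explicit override.

**Clustering contrast.** For a labeled similarity matrix and a grouping
(typically genus), the contrast is mean within-group minus mean
between-group off-diagonal similarity, computed after rescaling percent
matrices to [0, 1] so protein and nucleotide contrasts are comparable
rather than trivially ordered by their units. Significance is a label
permutation test (default 999 permutations, seeded; the observed labeling
is included in the null count, so the smallest attainable p is
1/(N+1)).

## Synthetic cohorts

The generator draws, per genus: a host category (categorical), a mean
genome length (log-normal, median 6,000 nt, log-sd 0.5), and with
probability `segmented_fraction` (default 0.3) a segment architecture from
a menu that by default contains a bipartite (7,500, 3,700) nt layout and a
tripartite (3,500, 2,800, 2,800) nt layout — the two characteristic
segmented-genus architectures the analysis is designed to resolve. For a
segmented genus the mean total length is anchored to the architecture sum
rather than drawn from the log-normal: segmented genera have fixed
characteristic architectures, and this anchoring is what makes the
single-segment length density reproducibly bimodal near the layout's
segment sizes.

Per member, total length is `mean × (1 + Normal(0, sigma_rel))` truncated
positive (default `sigma_rel` = 0.08), split across segments proportionally
to the architecture. The relative deviation of a member from its genus mean
is therefore ≈ Normal(0, σ_rel), giving the closed-form expectation
`P(|d| < τ) = 2Φ(τ/σ_rel) − 1` used by the acceptance checks
(≈ 0.9876 at τ = 0.20, σ_rel = 0.08; using the realized genus mean rather
than the true mean shifts this by well under the 3-binomial-SE band at 20
members per genus).

Sequences are background bases drawn at the host's target GC (defaults:
fungi 0.55, plants 0.44, plants+invertebrates 0.46, invertebrates 0.48,
invertebrates+vertebrates 0.47, vertebrates 0.50 — fungi high and plants
low, the qualitative ordering the host-contrast stage is meant to detect)
with `round(orf_density × kb)` embedded non-overlapping complete ORFs
(default 1 per kb, lengths uniform in 90–300 nt in codons). Each embedded
ORF is preceded by an in-frame guard stop codon so its six-frame
translation fragment is exactly the encoded peptide; embedded ORF codons
are drawn at the background GC with stop codons repaired, so realized GC
stays within ±0.02 of target. Infeasible configurations (ORF footprint
exceeding the sequence) are rejected before any output. All randomness
flows from the single config seed; identical configs are byte-identical.

Synonymous recoding replaces every codon of each ORF by a uniform draw from
its amino acid's codon set (stops from the stop set) and resamples non-ORF
bases at the realized non-ORF GC. This forces protein identity 100 while
destroying nucleotide k-mer similarity (typically < 0.05 at k = 10 for
1 kb coding records). `recoded_family_cohort` extends this to whole
families: each genus descends from one ancestral peptide, members carry it
with a small per-site amino-acid drift (default 5%) re-encoded with random
synonymous codons — high within-genus protein identity, low within-genus
nucleotide similarity, which is exactly the structure under which protein
matrices cluster by taxon and nucleotide matrices do not.

What the generator does **not** emulate: real codon-usage bias, RdRp or
capsid motifs, secondary structure, phylogenetic signal within genera,
database artifacts (vector contamination, mis-annotation), or the real,
uneven taxon sampling of curated databases. Passing tests on synthetic
cohorts therefore demonstrate that the statistics measure what they claim
under the stated model, not that any particular real cohort shows these
regularities to the same degree.

## Problem sizes and numerics

Test and acceptance cohorts are sized so each property is measured with
adequate power at desk scale: 100 genera × 20 members for the
genus-deviation screen (binomial SE ≈ 0.25% on the fraction), n = 200 for
the ORF-length correlation, 200 random pairs ≤ 2 kb for the k-mer oracle
comparison, 30 genomes (6 genera × 5) for the protein/nucleotide clustering
contrast, and ~40 genera for the segment-density shape. Exact Wilcoxon
enumeration is checked for all group sizes up to 7. Floating-point
conservation of the deviation statistic is asserted at 1e−12 relative
tolerance; KDE mode locations are asserted within ±10% of the architecture
lengths.

## Known limitations

- The six-frame caller reports complete start-to-stop ORFs only; genes
  truncated by segment ends, leaky starts, or frameshifted genes are
  invisible to it.
- Protein similarity depends on the fragment floor and alignment-length
  floor; very short conserved peptides (< 20 aa) do not register.
- The permutation p-value of the clustering contrast has resolution
  1/(N+1); with the default 999 permutations, p-values below 0.001 are
  reported as 0.001.
- Host-contrast results depend on the `> 40` group-size screen; on small
  cohorts the screen must be lowered explicitly, which changes the test's
  power.
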