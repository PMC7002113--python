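# Methods

This note documents the models and procedures implemented in `metasrna`, the
choices made where the design was genuinely open, and what the synthetic
test fixtures do and do not establish about behaviour on real data.

## Coordinate model and classification

All intervals are 0-based half-open internally; GFF3/GTF on disk are 1-based
inclusive. The distance between two intervals is the gap in nucleotides
between their closest boundaries; overlapping *and* touching intervals have
distance 0. "At least 30 nt away" is inclusive (≥ 30), and "overlap by at
least 10 nt" is inclusive (≥ 10), following the plain reading of "at least".

Transcripts are treated as single-exon (prokaryotic/archaeal communities);
exon rows in the GTF are ignored. Each transcript receives exactly one label:

* `coding` — any same-strand gene overlap (≥ 1 nt), checked first;
* `intergenic` — nearest gene on *either* strand ≥ `min_gene_distance` away;
* `antisense` — nearest same-strand gene ≥ `min_gene_distance` away and some
  opposite-strand gene overlapping by ≥ `min_antisense_overlap`;
* `ambiguous` — everything else. Ambiguous and coding transcripts are
  retained in the catalog with their label rather than dropped, so the
  classification is auditable.

When several opposite-strand genes overlap an asRNA, all are recorded sorted
by overlap descending, ties broken by gene id; the first is the primary
antisense partner.

Small-peptide handling: a gene shorter than `small_peptide_max` (100 nt) that
lies fully within a transcript more than `small_peptide_transcript_ratio`
(3×) its length — strictly more, so a 270-nt transcript does *not* silence a
90-nt gene — is excluded from the gene set *for that transcript only*.

## Reading-frame filter

The paperless notion of "contains a reading frame" is implemented as the
longest stop-codon-free codon stretch (stops TAA/TAG/TGA; `N` never forms a
stop) over all six frames, in nucleotides, divided by transcript length. A
candidate fails when this fraction strictly exceeds `max_orf_fraction`
(1/3). An alternative ATG-initiated definition is available via
`longest_orf_fraction(seq, mode="atg")` for users who want a conventional
ORF; the stop-free definition is the default because it is the stricter
(more conservative) noncoding criterion. The implementation is tested for
exact agreement with an independent brute-force enumeration of stop
positions on 1,000 random sequences of 50–500 nt.

## Dynamic contig-edge correction

Assemblies misassemble and truncate at contig tips, inflating spurious
"transcripts" there. For each distance `d` on the grid {0, 10, …, 500} nt,
the probability that a uniformly placed candidate falls within `d` of a tip
is `p0(d) = Σ_c min(2d, L_c) / Σ_c L_c` over contig lengths `L_c`; the
observed number of candidates with edge distance < `d` is compared to
Binomial(n, p0(d)) with an exact one-sided test (a two-sided variant is
available via `alternative="two-sided"`). The scan answers one family-level
question — *is any edge zone enriched?* — so each grid point is tested at a
Bonferroni-corrected level `edge_alpha / m` (m = 50 nonzero grid points).
Without this correction the family-wise false-alarm rate of the scan,
measured over 100 uniform-placement replicates, is ≈ 20% rather than the
intended ≤ `edge_alpha` (5%); with it, the measured rate is 0/100 while a 3×
enrichment of candidates within 50 nt of tips still raises the threshold to
≥ 50 nt in 100/100 replicates. The chosen threshold is the smallest grid
distance above the last significant one (clamped to the grid maximum), and
candidates closer to a tip than the threshold are flagged `edge_fail`.

Filter order is classification → edge → length → reading frame → (later)
coverage and homology. The order is recorded in the catalog's telescoping
provenance log `(step, n_in, n_out)` so it can be audited; length/ORF flags
are computed for all candidates regardless of edge status, since the flags
are independent annotations.

## Homology and conservation

The protein filter requires a *single* hit to satisfy all four conditions
simultaneously — query cover > 30%, bitscore > 50, E < 1e−4, identity > 30%,
all strict as printed; hits are never combined across rows. Query cover is
always recomputed by the reader from the aligned query span
(|qend − qstart| + 1, orientation-independent) so that every BLAST dialect
behaves identically. Conservation bounds are inclusive ("maximum",
"or more"): E ≤ 1e−3, identity ≥ 70%, query coverage ≥ 50%. Coverage here is
query coverage; subject coverage is not computable from 12-column tabular
output, which is why no switch is offered.

Housekeeping Rfam families (tRNA, RNase P, SRP) are matched by normalized
name tokens, flag the record `rfam_housekeeping`, and remove it from the
*regulatory sRNA set* while keeping it — with its family annotation — in the
full *ncRNA catalog*. This two-tier output reconciles the exclusion of
housekeeping RNAs from regulatory candidates with their legitimate presence
in a community ncRNA inventory.

## Expression and differential expression

Contig normalization: `value = transcript_count / contig_count ×
count_scale` per sample, with 0/0 defined as 0 and transcript reads on a
read-free contig an error. `count_scale` = 1e6 purely for readability; any
positive constant yields identical test decisions (tested). Standardized TPM
is the same ratio with scale 1. The point of the construction is the tested
invariance: scaling a contig's reads (transcript and contig rows together)
in any sample leaves normalized values unchanged, so organism-abundance
shifts cannot masquerade as expression changes.

The NB Wald test works directly on the (non-integer) normalized values:

* per-feature group means m₁, m₂; pooled within-group variance;
* method-of-moments dispersion α̂ = (s² − μ̄)/μ̄², floored at 1e−8, shrunk in
  log space (equal weights) toward a cross-feature trend α(μ) = a₀ + a₁/μ
  fitted by least squares on features with positive moment estimates (median
  fallback when fewer than 10);
* log2 fold change of group 2 over group 1 (groups ordered by sorted group
  name); if either group mean is zero, 0.5 is added to both means to keep
  the fold change and SE finite;
* delta-method SE: SE²(log m_g) = (1/m_g + α)/n_g; the Wald statistic is
  referred to a t distribution with 1.5 × (n₁ + n₂ − 2) effective degrees of
  freedom. A normal reference is measurably liberal at replicate-level
  sample sizes (mean type-I 0.057 at n = 10+10, mean 200, dispersion 0.1)
  and a plain t(n₁+n₂−2) conservative (0.044), because the trend shrinkage
  removes roughly half of the dispersion-estimate noise; the 1.5 factor was
  calibrated by null simulation across 20 seeds to hold the nominal level
  (mean 0.050);
* two-sided p-values, Benjamini–Hochberg adjustment (via statsmodels) across
  tested features, significance at FDR ≤ `de_fdr` (0.05). All-zero features
  are excluded from testing and reported NA; features with identical values
  in all samples report log2fc 0, p = 1.

This estimator intentionally does not reproduce any external DE tool
bit-for-bit; it is validated by calibration (type-I error, sensitivity,
empirical FDR) on simulations with known truth. `metasrna quantify --round`
exports an integer-rounded normalized matrix for users who prefer to run an
external count-model tool.

Pair correlations use Pearson r on (standardized) TPM across the replicate
samples shared by both matrices (≥ 3 required), two-sided p from the t
distribution with n − 2 df, significance at p < `corr_alpha` (0.01);
zero-variance vectors give NA.

## Community analytics

*Taxonomy.* A "weighted average" of categorical lineages is operationalized
as a rank-wise weighted majority vote (gene length as the natural default
weight): descend from domain while the winning name holds ≥ 0.5 of the total
gene weight; deeper ranks are left absent below a majority. A 50/50 tie
keeps the lexicographically first name and sets a `tie` flag rather than
discarding information. Each sRNA inherits its contig's lineage.

*Overlap geometry.* The asRNA–gene overlap is projected onto the mRNA's
5′→3′ axis (for a minus-strand gene, axis origin at the gene's right edge)
as relative coordinates in [0, 1].

*Upstream regions.* The `upstream_len` (50 nt) window upstream of the
transcription start — before `start` on the plus strand, the reverse
complement after `end` on the minus strand — is emitted as FASTA for
external motif tools, truncated and flagged at contig edges.

*Interaction density.* Predicted sRNA–mRNA hybridizations are ranked by
ascending p-value, ties by ascending energy then target id (a
`rank_by="energy"` switch swaps the first two keys, since either ranking is
defensible for "top targets"); the top `top_n_interactions` (100) increment
per-position counts over their sRNA span; the peak is the smallest position
attaining the maximum.

## Synthetic communities

`generate_community` emulates the *geometry and attributes* the pipeline
consumes: contigs carrying genes of 300–900 nt on random strands, planted
intergenic/antisense sRNAs with safe margins, coding and ambiguous
transcripts, and a fixed decoy set pinning every threshold boundary
(gene distance 29/30 nt, overlap 9/10 nt, lengths 49/50/500/501 nt, coverage
4.9/5.0× and 9.9/10.0×, a stop-free sequence for the reading-frame filter,
and a small-peptide-containing transcript). Planted sRNA sequences are built
from a TTAA tiling (stop codons every 12 nt in all six frames) randomized by
point mutations under a stop-free-run cap, so they pass the frame filter by
construction. All features sit ≥ 600 nt from contig tips, outside the edge
grid.

`generate_counts` draws NB counts (variance μ + αμ², the DE module's
parameterization, so parameter recovery is well-posed) for two groups of
replicates named after two field seasons; per-transcript log2 fold changes
model true expression changes and per-contig multiplicative shifts model
organism-abundance changes, with contig counts equal to member-transcript
sums plus background genes sharing the shift. The headline property is that
a 4-fold contig shift with zero transcript effects yields no excess DE calls
after normalization but a flood of them without it.

What the fixtures do *not* emulate: read-level noise, rRNA contamination,
overlapping/nested transcript architectures, chimeric contigs, annotation
errors, uneven coverage along contigs, or realistic taxon abundance
distributions. Passing the suite therefore demonstrates correctness of the
rules and calibration of the statistics under their stated models, not
robustness to the full messiness of environmental data.

## Problem sizes and numerical conventions

The test and acceptance runs use: 8 contigs / 250 genes / 200 planted sRNAs
for recovery; 1,000 random sequences for the frame-scan oracle; 100
Monte-Carlo replicates × 200 candidates for edge calibration; 2,000 features
× (10+10) samples at mean 200 and dispersion 0.1 for DE calibration; and
2,000 pairs × 21 replicates for correlation calibration — sizes chosen so
each property is measured with useful precision while the whole suite runs
in well under a minute per check. Dispersion floor 1e−8; zero-group
pseudo-mean 0.5; all randomness flows through explicit
`numpy.random.default_rng` seeds, and catalogs, tables and manifests are
written in deterministic order (manifests omit wall-clock time by default so
reruns are byte-identical; `--timestamp` opts in).

## Known limitations

* Classification uses annotated genes only; unannotated ORFs are invisible
  unless supplied in the GFF (a merged gene+ORF GFF works unchanged).
* The edge null assumes uniform candidate placement and independent
  candidates; clustered transcription violates it mildly.
* The DE model is two-group, single-factor, without fold-change shrinkage or
  outlier handling; very low counts (< ~5 per group mean) rely on the NB
  moment fit being stable across features.
* Taxonomy voting ignores rank inconsistencies between input lineages; it
  trusts the per-gene lineage strings.
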