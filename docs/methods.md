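# Methods

`mirpair` infers candidate miRNA→mRNA repressive regulation from a two-channel
expression study over six ordered cellular states (receptor-negative cells,
receptor-positive cells, and four hormone-exposure time points), each profiled
in triplicate. This note records the model, the numerical choices, and what
the synthetic benchmark does and does not establish.

## Summarization and differential calling

Intensities are non-negative per-sample values on a microarray-like scale.
Because the emulated platform's own normalization is proprietary, the package
ships a documented stand-in, `normalize_pm_only`: each sample is rescaled so
that its two-sided trimmed mean (default trim 0.02 per tail) equals a common
target (default 100). This is a pure per-sample scaling — within-sample
intensity ratios are preserved exactly — and it can be switched off for data
already on one coherent scale. It makes no claim to reproduce any vendor
algorithm.

Transcripts whose maximum intensity over all 18 samples is *strictly* below a
threshold (default 10) are removed; a maximum exactly at the threshold is
retained. Each surviving transcript is summarized into six per-condition
geometric means of the triplicates. Zeros are clipped to a floor (default 0.5)
before the log; the floor only matters for cells at or near zero and keeps
profiles strictly positive.

Differential expression is called per contrast — receptor-positive vs
receptor-negative at baseline, then each time point against the
receptor-positive state — as a signed fold change on the condition geometric
means (strictly greater than 1.5 in magnitude) gated by an adjusted p-value
(Benjamini–Hochberg by default, at most 0.05). Two tests are computed per
contrast: one-way ANOVA on the replicates and an exact two-sided Mann–Whitney
test that enumerates all C(6,3) = 20 labelings of the pooled midranks, which
stays valid under ties. **Which p-value gates the call is a real design
choice**: the exact Mann–Whitney two-sided p on 3-vs-3 replicates can never go
below 2/20 = 0.1, so demanding that *both* tests clear α = 0.05 rejects every
transcript at this replicate depth by construction. The default gate is
therefore `either` (the smaller of the two raw p-values feeds adjustment);
`both`, `anova` and `mw` remain available for sensitivity analyses. The
`both` mode is only meaningful with more replicates or with the
normal-approximation Mann–Whitney.

"Treatment-responsive" means differential in at least one of the four
time-point contrasts; the differential set used downstream is the union over
all five contrasts.

## Rank correlation over six states

For a miRNA profile X and an mRNA profile Y (the six condition geometric
means), expression is converted to ranks (midranks under ties) and Spearman's
rho is computed: the classical `1 − 6·Σd²/(n(n²−1))` when ranks are tie-free,
and equivalently the Pearson correlation of the rank vectors when ties occur.
A constant profile has undefined rho and is reported as sign class "none"
with p = 1 and a flag.

With n = 6 the null distribution of rho under independence is discrete: there
are 720 equally likely rank permutations and the attainable two-tailed
p-values form the grid m/720. The default test therefore *enumerates* all
permutations and counts those with |rho| at least the observed value
(tolerance 1e-12 on the comparison, guarding against float-boundary
undercounting on the grid); an asymptotic t-approximation
(t = rho·√((n−2)/(1−rho²)) on n−2 df) is provided for longer profiles and
falls back to enumeration at |rho| = 1. Consequences worth noting at n = 6:

* the smallest attainable p is 2/720 ≈ 0.00278 (identity and full reversal);
* the pair filter |rho| > 0.8 (strict) with p ≤ 0.05 effectively requires
  Σd² ≤ 4, i.e. rho ≥ 1 − 24/210 ≈ 0.886, because rho = 1 − 36/210 ≈ 0.829
  already carries p = 42/720 ≈ 0.058;
* rho exactly 0.8 is unattainable on tie-free ranks (it would need Σd² = 7,
  and Σd² is always even for permutations).

Pair screening (`correlate_all`) considers every differential miRNA against a
configurable mRNA universe (all filtered mRNAs, or the differential subset —
the default), keeps pairs with |rho| strictly above the cutoff and p ≤ α, and
partitions them by sign. Negative pairs are the repression candidates;
positive pairs typically reflect co-transcription or shared regulation.

## Target prediction and integration

The internal predictor is a canonical seed matcher: the reverse complement of
miRNA nucleotides 2–7 is scanned against each 3′UTR; a hit is upgraded to
7mer-m8 by a 5′-flank base pairing miRNA position 8, to 7mer-A1 by an
adenosine on the 3′ flank, and to 8mer by both. No free-energy, conservation
or context scoring is attempted — those belong to dedicated tools whose
output can be *imported* as (miRNA, gene) tables and combined across sources
by intersection (default) or union. Experimentally validated interactions are
ingested the same way and carried as a flag.

Integration assigns tiers over the union of passing correlations and
predicted pairs: **high-confidence** requires prediction (either route),
negative correlation beyond the cutoffs, and a differentially expressed mRNA;
passing correlations that miss a requirement are **correlated-only**;
predictions with no passing correlation are **predicted-only**. The
high-confidence requirement reads the negative correlation per pair (the
specific miRNA against its own predicted target), not against any
differential miRNA.

## Genomic context

miRNA loci are intersected with gene models (GFF3; BED6 accepted for loci).
Precedence is exon > intron: any exon overlap makes the locus exonic; a
gene-body overlap without exon overlap is intronic; otherwise intergenic. The
host gene is the gene with the longest overlap; orientation is sense iff the
strands agree. Internally all intervals are 0-based half-open; GFF3
conversion is exact and round-trips.

Clusters chain loci whose inter-locus gap (next start minus current rightmost
end) is at most 10 kb, with single-linkage transitivity, strand ignored —
10,000 bp clusters, 10,001 bp does not. Host-gene concordance uses the same
Spearman machinery; the category boundaries (correlated at rho ≥ 0.5,
negative at rho ≤ −0.3, poor between) are package defaults — the literature
names the categories but no thresholds — and are echoed in the output so
reruns are comparable.

## Enrichment

Each miRNA's high-confidence target set is tested for over-representation in
GMT gene sets with the upper-tail hypergeometric probability P(X ≥ k) for N
universe genes, K in the term, n targets. The universe defaults to the
*expressed* genes (those surviving the intensity filter) rather than all
annotated genes, avoiding expression-bias inflation; BH adjustment is applied
across terms within each miRNA, matching the per-miRNA reporting style.

## Synthetic benchmark

The generator emulates the 6 × 3 design end to end and writes every input
dialect the pipeline reads, plus a truth ledger. Defaults: 20 strong
repressive pairs, 5 weak pairs, 10 co-transcribed intronic miRNA/host pairs,
50 null mRNAs and 10 null miRNAs, 10% of each channel pushed below the
intensity threshold, log-normal replicate noise with sd 0.1, baselines
drawn from 50–400 with a 1.6-fold ladder step. These sizes keep a full run
around a second while leaving every code path exercised; the ladder step is
chosen so planted transcripts clear the 1.5-fold threshold in at least one
contrast with margin.

Planted structure: repressor miRNAs follow a strictly monotone ladder over
the six states and their targets the reversed ladder (population rho = −1),
with a seed site of a declared type (cycling 8mer/7mer-m8/7mer-A1/6mer)
embedded in the target UTR; weak pairs swap one adjacent state pair in the
target, sitting at rho ≈ −0.943 — above the 0.8 cutoff and significant
(p = 12/720), so they probe the cutoff's discrete behavior; co-transcribed
pairs share a template (rho = +1) and the miRNA sits in its host's intron;
nulls carry independently permuted ladders. Decoy predictions point at null
genes re-sampled until |population rho| ≤ 0.6, decoy validated entries and
random GMT terms complete the branch coverage. UTRs are actively scrubbed of
stray seed matches (and miRNA seeds are drawn to avoid one-base shift
collisions between match patterns, which would make a planted site's fixed
flanks unscrubable).

What the benchmark does *not* emulate: probe-level array physics,
cross-hybridization, batch effects, correlated noise between transcripts,
many-to-many regulation, or partial repression strengths. Passing it shows
the inference machinery is correct and the thresholds behave as specified —
not that real arrays at this design size would yield comparable precision;
on real data the planted rho = ±1 extremes are replaced by a continuum and
the 0.8/0.05 filter is genuinely selective.

Determinism: one seeded generator drives every draw, so a (config, seed)
pair reproduces all outputs byte-identically; the pipeline itself is a pure
function of its inputs and parameters, with checksums recorded in the run
manifest.

## Known limitations

* The per-sample trimmed-mean normalization is a stand-in; counts derived
  from any specific vendor pipeline are not reproducible with it.
* Exact enumeration is limited to n ≤ 8 profile length (n! growth); longer
  designs switch to the t-approximation.
* The exact Mann–Whitney test is intentionally powerless at 3-vs-3 under a
  0.05 threshold (floor 0.1); it contributes only through the configurable
  gate.
* Gene-level collapsing of predictions is by any-transcript-hit; isoform-
  specific 3′UTR usage is not modelled.
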