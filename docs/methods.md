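# Methods

## Problem and model

A xenograft RNA-seq library mixes reads from two species: the grafted tumor
cells and the host-derived microenvironment (stroma, vasculature, immune
cells). `xenosort` treats deconvolution as a deterministic k-mer
classification problem followed by a conventional cross-species expression
analysis on one-to-one orthologues. No probabilistic read model is fitted;
every decision rule below is exact and auditable.

## Read classification

All k-mers of both reference transcriptomes are canonicalized (lexicographic
minimum of the k-mer and its reverse complement) and partitioned into three
disjoint sets: host-only, graft-only, shared. For a read pair, k-mer hits
are summed over both mates — a pair has a single biological origin, so
per-mate classification with a reconciliation policy would only add an
arbitrary layer. With nH / nG / nB hits in the host-only / graft-only /
shared sets, the class is: `host` (nH>0, nG=0), `graft` (nG>0, nH=0),
`ambiguous` (nH>0 and nG>0), `both` (only shared hits), `neither` (no
hits). Specific evidence thus takes priority over shared evidence, direct
conflict is surrendered as ambiguous, and reads shorter than k default to
`neither`. This five-way truth table is this package's fixed contract; the
class *names* follow the established xenograft-separation convention, but
other tools do not publish their exact both/ambiguous split, so byte-level
agreement with them is not claimed.

Parameters: `k` (odd, 11–31, default 25 — the conventional read-scale k
balancing specificity against error tolerance; even k is rejected because a
palindromic k-mer equals its own reverse complement and has no unique
canonical form). Canonical (strand-agnostic) matching is used even for
stranded libraries: strand carries no species information. The index is
built from transcriptomes, not genomes, because downstream quantification is
transcript-level; intronic or intergenic reads therefore fall into
`neither`.

The per-sample summary table reports percentages at mixed precision — one
decimal for the three major classes (host, graft, ambiguous), two decimals
for the two minor ones (both, neither) — matching the reporting convention
of desk summaries of such runs.

## Quantification

Classified reads are assigned within their species by k-mer voting: each
pair's matching k-mers are tallied per gene (one transcript per gene; the
transcript→gene map collapses votes first), the gene(s) with the maximal
tally receive the pair, and exact ties split the unit count equally. Pairs
matching no k-mer are dropped and reported. "Tied" is pinned to
*maximal-tally* genes: it reduces to the natural rule (all matching k-mers
point to one gene → that gene gets count 1) and degrades gracefully when a
read spans a shared and a unique region. No EM over multi-mapping reads is
performed — with one transcript per gene and divergent references, ties are
rare, and an iterative reassignment would be unauditable at this scale.

TPM uses effective length `max(L − ℓ + 1, 1)` for read length ℓ — the count
of distinct start positions — and rescales length-corrected counts to 10⁶
per sample. All-zero columns stay zero rather than NaN.

## Orthologue harmonization and fold change

Only strict one-to-one orthologue pairs are kept: rows not labelled
one-to-one are dropped, and any gene still appearing in more than one row
disqualifies all of its rows. Pairs with TPM = 0 in every sample of both
species are removed ("expressed in ≥ 1 sample", with expressed meaning
strictly positive TPM); the joint matrix holds `log2(TPM + 0.01)`. The
pseudocount 0.01 keeps zeros finite at ≈ −6.64 while leaving values ≥ 1 TPM
essentially untouched.

The cross-species statistic is
`log2FC = log2((mean host TPM + c) / (mean graft TPM + c))` with c = 0.01 by
default, means taken over each species' own samples on the raw TPM scale.
Placing the same pseudocount inside the ratio is this package's resolution
of the zero-denominator case; `fc_pseudocount=0` recovers the bare ratio
where it is defined. DEG calling uses the inclusive threshold
`|log2FC| ≥ 2.2`; positive fold changes are labelled `tme_up` (host side),
negative `tumor_up` (graft side). When a PCA-selected gene list is supplied,
the restriction is applied *before* thresholding — the pipeline order is:
one-to-one filter → expressed filter → PCA → contribution selection →
fold-change threshold → enrichment.

## PCA contributions

Samples are observations, orthologue pairs variables; variables are
mean-centered and, by default, not scaled to unit variance (the common
default of the PCA routine this analysis style is built around; `scale=True`
is exposed for sensitivity checks). The decomposition is a full SVD of the
centered matrix; the sign of each component is fixed by making its
largest-magnitude loading positive, which removes SVD sign ambiguity from
all outputs. A gene's contribution to a component is
`100 · loading² / Σ loading²` — the squared-cosine convention for variables
under orthonormal components — and selection keeps genes **strictly** above
the expected average contribution `100/p`. Whether the expectation should be
evaluated per component or jointly over two components is ambiguous in this
analysis style; per component is used. Hierarchical heatmap ordering uses
distance `1 − Pearson r` with average linkage; constant rows get maximal
distance (2.0) with a warning, and the gene dendrogram is skipped above
5,000 genes to keep desk-scale runtime.

## Enrichment

Right-tailed Fisher exact p = P(X ≥ a) with X hypergeometric(N, K, n),
where the universe N is the set of orthologues that survived the expressed
filter — the enrichment background must match the tested pool, not a whole
genome. Benjamini–Hochberg runs across all sets of one DEG list (PC1 and
PC2 lists are corrected as separate families). The activation z-score is the
unit-weight direction-agreement statistic `Σ d_g · sign(log2FC_g) / √m` over
set members that carry a direction annotation and a DEG-level fold change;
with none, the z-score is reported as undetermined. This is a deliberate
simplification of proprietary weighted z-scores, whose edge weights and
"Ratio" denominators are not public; `ratio` here is a/K within the tested
universe.

## Synthetic data generator

The generator emulates a three-sample xenograft design: per sample, a host
fraction drawn from {0.40, 0.52, 0.65} (the observed range of host read
proportions in such experiments), 2×100 bp pairs. References are one
transcript per gene; orthologous graft transcripts are host sequences with
independent per-base substitutions at the divergence rate (default 0.2),
while non-orthologous genes get independent random sequences — guaranteeing
species-specific k-mers exist. Baseline mean expression is log-normal
(σ = 0.6 in natural log space), shared between orthologous partners so that
non-planted pairs have true log2FC = 0; planted pairs receive exactly
±effect/2 on each side (default effect 3.0 on 10% of pairs, half up in each
species, odd remainder to the host), and per-species means are renormalized
to 10⁶. Renormalization shifts all realized fold changes by a common
log-ratio of the two normalization constants (≈ ±0.15 at default scale),
which is part of what the pipeline must tolerate.

Read geometry is deliberately minimal: fragment length equals read length
(mates fully overlap, R2 = reverse complement of R1), substitution errors
only (default 0.005/base), constant Q40 qualities. The generator does *not*
emulate indels, PCR duplicates, quality-dependent errors, intronic reads,
adapter contamination, isoform structure, or overdispersed biological
replication — so green tests demonstrate correctness of the pipeline's
decision rules and statistics under a clean mixture model, not robustness
to every artifact of real libraries.

Default scale: 80 + 80 genes, 60 orthologue pairs, 6 planted DEGs, 32,000
pairs per sample (≈ 200 pairs per gene on average), transcript lengths
300–500 bp. These sizes were chosen as the smallest design at which every
gene is sequenced deeply enough for fold-change estimates to be stable,
which keeps a full pipeline run in the tens of seconds on one core.
All randomness flows from a single integer seed; identical arguments give
byte-identical FASTQ and truth files.

## Numerical choices and degenerate inputs

- Empty classified FASTQ → zero counts, zero TPM, percentages reported as 0
  with a warning.
- Mismatched R1/R2 record counts or unpaired titles → error naming the
  offending record index.
- PCA rejects a single sample or an all-constant matrix; zero-variance genes
  within a varying matrix are retained with zero loadings.
- BH q-values come from the standard step-up with cap at 1; p-values must
  lie in (0, 1].
- Fisher p-values are computed by the hypergeometric survival function and
  are verified in the test suite against exact rational enumeration of all
  2×2 tables with margins N ≤ 60 at 1e-12 relative tolerance.
- Ties in enrichment ordering are broken by set name for reproducibility.

## Known limitations

- The equal-split vote has no EM refinement; paralogous gene families with
  near-identical transcripts would be systematically split.
- The fold-change rule is threshold-only by design — no dispersion model and
  no per-gene p-values — so it inherits the usual caveat that a fixed
  threshold conflates effect size with depth at very low expression.
- The classifier is transcriptome-based; genomic contamination reads are
  invisible to it beyond landing in `neither`.
- The activation z-score treats all annotated members with unit weight and
  is not comparable to knowledge-base-weighted scores.
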