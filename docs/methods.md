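# Methods

This note documents the models and procedures implemented in
`thermomics`, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the numerical decisions a
maintainer would want written down.

## Coordinate model

All internal coordinates are 1-based, inclusive on both ends
(GFF3-native); bedGraph's 0-based half-open intervals are converted only
at the I/O boundary (bedGraph position *p* → internal *p* + 1). Signed
offsets are defined in transcript orientation: offset 0 is the anchor
(TSS or 3′ end), positive runs downstream, and minus-strand windows are
extracted reverse-complemented. This makes the motif windows (−50..+10,
−42..−19, −35..+2) read identically on both strands, and strand-mirror
symmetry of all sequence-based calls is asserted in the test suite.

## Term-seq 3′-end consensus

Tracks carry per-position counts of read 3′ ends, one pair of strand
tracks per replicate. CPM normalization divides by the replicate's total
end count across both strands, so the two strand tracks of a replicate
jointly sum to 10⁶ (relative tolerance 10⁻⁶, asserted).

The peak caller takes maximal runs of positions that are nonzero in any
replicate, bridging gaps up to `merge_window` (default 3 nt). Within a
peak, each replicate's maximum position is found; ties are broken toward
the most gene-proximal position (lowest coordinate on +, highest on −),
then lowest coordinate — deterministic and conservative. A consensus end
is emitted only when the *identical* position is the per-replicate
maximum in ≥ `min_replicates` (default 3) replicates and the mean CPM
over the supporting replicates is ≥ `min_cpm` (default 5). Positional
tolerance is deliberately zero; the jitter in real data is expected to
be absorbed by the within-peak argmax, not by fuzzy matching. The mean
(rather than min or max) is used for the CPM filter as the least
seed-sensitive aggregation. Both choices are configurable.

Classification assigns each consensus end to a gene: ends inside a gene
body are internal (the 3′ boundary itself counts as body, making the
downstream window half-open and preventing double counting); ends within
(0, 300] nt downstream in transcript orientation are candidates, with an
end falling in two genes' windows going to the nearer gene; per gene,
the highest-CPM candidate is primary (ties toward the gene) and the rest
secondary. Unassignable ends are orphans. 3′-UTR length is the offset of
the primary end from the stop codon.

Transcriptional-unit calling replaces a by-eye decision with an explicit
rule: an adjacent same-strand gene pair is co-transcribed when ≥ 5 reads
each cover ≥ 50% of both genes.

## Promoter / terminator sequence features

Motif discovery is not needed because the motif consensus is known;
instead a PWM is seeded from the degenerate consensus
(BRE + 2-nt spacer + TATA = `SWAAANNTTTWWW`): probability `match_prob`
(0.9) is split uniformly over allowed bases per position, the remainder
over disallowed ones, scored as log2 odds against the background.
Site *p*-values are exact: per-position score distributions under the
background model are convolved by dynamic programming on a discretized
score grid (step ε = 10⁻³); enumeration for PWM length ≤ 5 agrees to
machine precision. A gene is +promoter when the best window of −50..+10
around its TSS has p ≤ α (default 10⁻³); promoter strength is the
best-window p restricted to −42..−19 (smaller = stronger). Windows
containing N are skipped and reported.

Poly(U) terminator classification is a windowed count rule: +polyU when
any 8-nt subwindow of the sense-strand −35..+2 sequence holds ≥ 6 T.
This is a deterministic stand-in for a discovered U-rich motif — the
discriminating signal is a long (~16 nt) U stretch, which this rule
captures; both parameters are exposed.

Nucleotide enrichment at position *i* for base *b* is
log2((f_group(i,b) + 10⁻⁴) / (f_bg(b) + 10⁻⁴)), with the background
frequency from 100,000 positions sampled uniformly (with replacement,
width-weighted) from intergenic intervals under a caller-supplied seed.

Leaderless (5′ UTR = 0) versus leadered proportions are compared to the
control set by Pearson chi-square on the 2×2 table without continuity
correction — group sizes in this design are large; rows with an expected
cell < 1 are flagged low-count rather than corrected.

CAI follows Sharp–Li: relative adaptiveness w = f/f_max per synonymous
family from the reference set (pseudocount 0.5 on codon counts; the
intended reference is the top 5% most abundant proteins in the control
condition), and CAI is the geometric mean of w over a gene's codons,
excluding stop codons and single-codon amino acids (Met, Trp). CAI is
invariant under synonymous codon-order permutation and equals 1 exactly
on reference-preferred-codon genes (asserted).

The palindromic regulon scan evaluates both strands of −100..−1
(relative to the TSS, else the start codon) with the same exact
*p*-values; palindrome symmetry makes the two strand scans agree, which
is asserted rather than assumed (non-palindromic input warns).

## Differential expression

These are deliberately simplified stand-ins for DESeq2/limma — the
downstream analyses consume only the regulation grouping, so the tests
are judged on grouping fidelity against planted truth, not on
bit-parity with those tools.

*RNA.* Counts are scaled by median-of-ratios size factors (geometric
mean 1, computed over all-positive genes). log2FC =
log2((mean₁+c₀)/(mean₂+c₀)) with c₀ = 0.5 so zero-count genes stay
bounded. Per-gene NB dispersion comes from the method of moments pooled
across the two conditions, truncated at 0, and then moderated toward the
across-gene median with prior weight d₀ = 20 pseudo-degrees of freedom:
α̃ = (d₀·ᾱ + d·α̂)/(d₀ + d). Purely per-gene dispersions with ~6
residual df make a normal-referenced Wald statistic behave like a t₆
(≈ 9% type-I at nominal 5%); moderation toward a central value — the
same idea as the dispersion shrinkage in standard RNA-seq tools —
restores calibration (measured type-I ≈ 0.065 at 4+4 replicates) while
keeping the per-gene signal. The Wald statistic uses the delta-method
standard error of the log2 fold change with model variance
(m + α̃m²)/n per group; p is two-sided normal.

*Protein.* Intensities are log2-transformed; upper-quartile
normalization shifts each sample so its 75th percentile of observed
values matches the across-sample mean (the simplest reading of "quartile
normalization"; full-quantile is not implemented). The per-gene pooled
two-sample variance is squeezed limma-style: the prior (d₀, s₀²) is
moment-matched on log s² via digamma/trigamma identities (d₀ = ∞ when
the observed spread does not exceed the sampling spread), the posterior
variance is (d₀s₀² + ds²)/(d₀+d), and the t statistic has d₀+d df.
Genes observed in < 2 samples per group are omitted; measured type-I
error ≈ 0.049.

Regulation groups: RNA strong_up (padj < 0.05, log2FC ≥ 1), up
(0 < log2FC < 1), strong_down (≤ −1), down (−1 < log2FC < 0), else ns;
boundaries ±1 belong to the strong groups. Protein uses sign only, with
no magnitude threshold. BH adjustment is step-up with monotonicity,
applied within each contrast.

Replicate outlier flags are advisory: samples are scored on the first
two PCs of log2(x+1); within a condition of ≥ 3 replicates, a replicate
is flagged when its distance to the condition centroid exceeds the
median distance by more than c × MAD (c = 3.5). The deviation-from-
median form is used because the raw distance-vs-MAD comparison
degenerates when a single extreme replicate drags the centroid.

## Length-aware enrichment

The probability weighting function is fitted by binning genes into 20
length quantiles, taking per-bin DE fractions, enforcing monotone
nondecreasing by pool-adjacent-violators (weighted by bin size), and
interpolating per gene; weights are rescaled to mean 1 and floored at
10⁻⁶. PAVA replaces a smoothing spline deliberately: it carries the
same monotone-bias-correction contract with no smoothing parameter and
full determinism.

Per category, odds = mean weight inside / mean weight outside, and the
p-value is the upper tail of the Wallenius noncentral hypergeometric
distribution — the law of drawing n_DE balls sequentially without
replacement where category balls have weight `odds`. The distribution is
computed by the exact recursion over draws (O(n_DE·n_cat) flops), which
agrees with the central hypergeometric at odds 1 and with an independent
reference implementation to ~10⁻¹¹. Directions are tested separately on
up (strong_up + up) and down sets against the background of all detected
genes; raw p is thresholded at 0.05 with no cross-category correction
(a BH option exists but is off by default, matching how such category
scans are usually reported in this setting).

## Fold-change integration and clustering

Genes × (condition, layer) log2FC matrices are z-scored per gene within
each layer; zero-variance rows are dropped and reported. Genes missing
more than 50% of features are removed; remaining missing entries are
zero-imputed *after* z-scoring (zero is the row mean, so imputation is
neutral) and counted. PCA is computed by SVD; `n_pcs="auto"` keeps the
fewest components explaining ≥ 90% variance (the retained dimensionality
is not prescribed anywhere, so it is exposed). Ward linkage on the PC
scores follows the ward.D2 criterion (Lance–Williams on squared
Euclidean distances, heights square-rooted); merge heights are checked
nondecreasing on every run. The number of clusters is the k in the
candidate range maximizing the second difference of the within-cluster
sum of squares (the usual operationalization of the elbow); the full
WSS curve is returned and k can be overridden, since in practice k is
also sanity-checked against category enrichments of the clusters.
Cluster profiles are per-cluster, per-condition, per-layer medians and
IQRs of the z-scores.

Pairwise correlations are Pearson on pairwise-complete rows, with the
pair count reported and cells under 3 complete pairs returned missing.

## Synthetic data generator

The generator emulates the statistical structure of the study design:
one contig (~0.4 Mb at 200 genes, GC 0.41), non-overlapping genes on
both strands with ≥ 400 nt spacing; 5′-UTR length 0 with probability
0.15 (leaderless), else 1 + geometric (mean 30 nt); BRE/TATA instances
written at −38..−26 for 60% of genes; a 16-nt stretch with 13 T written
immediately upstream of the primary 3′ end for 40% of genes; primary 3′
ends at 20–150 nt past the stop, secondary ends (30% of genes, 0.3× the
primary height) and internal ends (20%, 0.2×). Planted end heights are
lognormal, rescaled so that total planted+background mass is one million
CPM and floored at 20 CPM. Term-seq reads are NB around the height
(dispersion 0.1) at a nominal depth of 2×10⁶ with replicate size factors
log-uniform in [0.5, 2] (so normalization genuinely matters), each read
jittered by a rounded Gaussian (σ = 1 nt); background single-read
positions arrive uniformly at 5×10⁻⁴ per nt per strand.

Expression: per-gene lognormal baselines (log-mean log 200, log-sd 1);
a gene is differentially expressed with probability 0.3, in which case
it takes one of four condition-profile templates (heat-transient,
cold-gradual, general-down, heat-spike) scaled by an amplitude ~
N(2, 0.5); genes in the planted enriched category are 3× as likely to be
DE. Protein-layer effects equal ρ·(RNA effect) plus orthogonal noise
scaled so the planted effect correlation is ρ = 0.69 among DE genes
(genes without an RNA effect have none at the protein layer). RNA counts
are NB (dispersion 0.05) around baseline × 2^lfc × size factor; protein
intensities are lognormal (σ = 0.3) around 100·baseline^0.8 × 2^lfc with
5% missing at random. For cluster-recovery studies a separate profile
generator plants k templates as a randomly rotated regular simplex whose
pairwise distances equal `separation` × the noise magnitude of one full
profile (per-feature σ × √n_features) — separation is measured on the
profile-vector scale, since that is the scale on which clustering
operates.

What the generator does **not** emulate: sequencing error, rRNA
contamination, positional coverage bias, intensity-dependent protein
missingness (missingness is MCAR), batch effects, operonic correlation
of expression, and overlapping genes. Tests passing on this data show
the algorithms implement their rules correctly and are calibrated under
the assumed noise laws; they do not certify performance under real-data
pathologies outside those laws.

## Problem sizes and determinism

All simulation-backed checks run at deliberately modest sizes chosen to
make the full suite complete in well under a minute of compute per
module: 200-gene genomes for end calling, 2,000 genes × 8 samples for
DE and enrichment calibration (10–20 seeds), 300 genes for cluster
recovery, 500 random tracks and 100 random PWMs for the oracle
equivalences. Every stochastic component takes an explicit seed;
identical configuration and seed reproduce byte-identical outputs, which
the pipeline manifest verifies by SHA-256 checksum.

## Known limitations

- The RNA Wald test is anticonservative by design margin (~0.065 at
  nominal 0.05 with 4+4 replicates); downstream grouping uses BH-adjusted
  p-values, which absorbs most of this in practice.
- The poly(U) rule and the PWM promoter call are threshold classifiers,
  not probabilistic motif models; their agreement with an EM-based motif
  assignment on real data is approximate.
- Condition-dependent 3′-end calling is not implemented (ends are called
  in one condition, as in the emulated design).
- The elbow criterion needs the WSS curve at k−1 and k+1, so the extreme
  ends of the candidate range are only selectable via `k_override`.
- Upper-quartile (not full-quantile) normalization is the only protein
  normalization implemented.
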