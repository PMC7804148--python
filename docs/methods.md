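# Methods

This note documents the models implemented in `netmodmut`, the parameters
that matter, the design choices made where the design was genuinely open,
and what the synthetic experiments do and do not demonstrate.

## Mutation matrix construction

Input segments carry one of five discrete somatic states; HOMD and HETD are
collapsed to loss (−1), GAIN and AMP to gain (+1), NEUT to neutral (0).
The quality filter *retains* segments of at least `min_length_bp` (default
5,000 bp) supported by at least `min_probes` (default 10) probes, and drops
neutral segments, which carry no mutation.

Coordinates are 1-based and inclusive on both ends internally; segment
length is `end − start + 1`. The BED reader converts from BED's 0-based
half-open convention, and chromosome names are compared after stripping an
optional `chr` prefix. A gene is called mutated in a sample when any
retained segment overlaps it by at least one base. When segments of
opposite sign hit the same gene in the same sample, the segment covering
more bases of the gene wins; an exact tie resolves deterministically to
loss and is logged. These conflict rules are interpretations — segment
calls rarely overlap within one sample — and both thresholds and the
strictness of endpoint handling are exposed as arguments.

## Frequencies, heat and similarity

Gene i's gain and loss frequencies are f_ig = n_g/N_s and f_il = n_l/N_s;
its heat is f_i = f_ig + f_il. Because each sample contributes one state
per gene, f_i ≤ 1.

The pairwise mutation similarity is, by default, the standard cosine

    sim(i, j) = (f_ig f_jg + f_il f_jl)
                / (sqrt(f_ig² + f_il²) · sqrt(f_jg² + f_jl²)),

bounded in [0, 1] for non-negative frequencies, symmetric, and invariant to
scaling either frequency vector. An `as_printed` variant with unrooted sums
in the denominator is provided for comparison; it is not a cosine (it can
exceed 1) and is not used by default. A gene with zero frequencies gets
similarity 0 to everything rather than NaN: an unmutated gene should not
bind a mutated module.

## Hot subnetworks (insulated heat diffusion)

The diffusion stage consumes the *unweighted* interaction graph (the
similarity weights feed only the clustering stage). The walk matrix W is
column-stochastic degree normalization; isolated nodes are removed first
(they cannot exchange heat). The influence matrix has the closed form
F = β(I − (1−β)W)⁻¹, computed by dense inversion — exact, and cheap at the
network sizes this package targets (hundreds to a few thousand genes).
Since 1ᵀW = 1ᵀ, every column of F sums to 1, so the exchanged heat
E = F·diag(h) redistributes exactly each source's heat: Σ_i E_ij = h_j.
This conservation is asserted in the tests to 1e−9.

β (default 0.4, configurable) is the fraction of heat a node retains per
step; β→1 degenerates to no diffusion (F→I). The edge threshold δ is
selected on heat-permuted data: heats are reassigned to nodes uniformly at
random (network fixed), and the per-permutation δ is the smallest
threshold at which the largest strongly connected component of the
permuted exchanged-heat graph falls below `l_max` genes (default 10),
found by binary search over the sorted distinct edge values — valid
because raising δ never merges components. The working δ is the median
across permutations. Components of at least `k_min` genes (default 3) are
reported.

Significance is per component size s: p(s) compares the observed count of
components of ≥ s genes with the same count under the heat-permutation
null, p(s) = (1 + #{perm: count ≥ observed}) / (n_perm + 1), and
FDR(s) = mean permuted count / observed count, capped at 1 and defined as
1 when nothing of size s was observed. Whether the false-discovery
estimate should be per-size or global was open; per-size with the cap is
implemented because the count statistic is itself per-size.

## Cohesive clusters (overlapping greedy clustering)

Cohesiveness of a gene set P is C(P) = w_in/(w_in + w_bound + p·|P|), with
w_in the total weight of edges inside P, w_bound the weight crossing its
boundary, and a penalty proportional to the group size modelling
unobserved interactions. The penalty was open between a constant and a
per-vertex form; the per-vertex form `penalty_rate·|P|` is implemented
(default rate 2, following the reference algorithm's published default),
and `penalty_rate=0` recovers the constant-free reading.

Growth is a strict hill-climb from a seed: every single-gene addition
(boundary neighbours) and removal (members, the seed included) is
evaluated, the move with the largest strict cohesiveness increase is
applied, and ties break to the lexicographically smallest gene id, making
the procedure deterministic. A seed ejected from its own group is flagged
an outlier; it remains eligible as a member of later groups but never
seeds again. Seeds are processed in decreasing weighted-degree order,
skipping genes already covered by an accepted group.

Merging builds an overlap graph with edges where ω(X,Y) = |X∩Y|²/(|X||Y|)
≥ 0.8 (the displayed inequality is taken as authoritative over the
"larger than" phrasing) and unions each connected component, so chains of
pairwise-overlapping groups merge transitively; the operation is
idempotent. Groups below weighted density w_in/C(|P|,2) of 0.3 are then
discarded.

Cluster significance is a one-sided Mann–Whitney U test that members'
in-weights exceed their out-weights: exact enumeration over all rank
splits (midranks for ties) when both sides have ≤ 8 values, otherwise the
normal approximation with tie correction and no continuity correction —
so equal in- and out-weights give p = 0.5 exactly. p-values are BH-adjusted
across clusters; the reporting convention keeps adjusted p < 0.1 with more
than two genes, both configurable.

Known small-graph limitation: on small, densely weighted graphs (tens of
nodes at mean degree ≳ 5 with uniformly high similarity weights) the
whole connected component can dominate cohesiveness and greedy growth from
any seed converges to it, after which the density filter removes it and no
module-scale cluster is reported. At the package's target scale (hundreds
of genes, sparse background) the planted module is a stable local optimum
and recovery is reliable.

## Two-cohort validation

The overlap rate |A∩B| / min(|A|, |B|) equals 1 exactly when one module
contains the other. Matching is one-directional: each discovery module is
paired with the validation module maximizing the rate (ties: more shared
genes, then smaller index), and pairs at ≥ 50% are reported. A validation
module may partner several discovery modules.

## Survival association

The sample-specific mutation score for a module is p_j = Σ_i f_i·|v_ji|:
a gain and a loss count equally, weighted by the gene's overall mutation
frequency. Kaplan–Meier estimation and the two-group log-rank test are
implemented directly (product-limit and the standard U²/V chi-square with
hypergeometric variances; no events or a degenerate arm give statistic 0,
p 1 by convention) and are verified against lifelines in the test suite;
the in-package log-rank is vectorized over candidate cut-points because the
min-p scan runs inside permutation loops.

Dichotomization scans every distinct score value whose rank fraction lies
in the central quantile window (default 10–90%; prevents degenerate
1-vs-(n−1) splits) and takes the cut minimizing the log-rank p, ties to the
smaller cut; the high-risk arm is *strictly above* the cut. The minimum p
is reported uncorrected, and module-level significance is calibrated by
permutation: each of n_perm (default 1000) draws a uniformly random gene
set of the module's size, recomputes scores, cut-point and log-rank p, and

    p_perm = (1 + #{permuted p < real p}) / (n_perm + 1),

with strict inequality exactly as the formula reads, hence
p_perm ∈ [1/(n_perm+1), 1]. Random same-size gene sets are the default
permutation unit (equivalent to permuting gene-row labels of the CNA
matrix); `mode="shuffle_values"` instead shuffles each module gene's values
across samples, preserving the module's own score distribution. The two
nulls answer different questions: gene-set permutation asks whether *this
module* beats random modules, and is sensitive to the fact that a
high-frequency module's score has many more admissible cut-points (hence a
more optimistic minimum p) than typical low-frequency gene sets; value
shuffling holds the multiplicity of the scan fixed and tests only the
score–survival association. The gene-set unit is the default; its
anti-conservativeness for modules whose mutation burden far exceeds the
genome background is a property of the published procedure, not of this
implementation, and is quantified in the test suite.

Expression risk scores RS_j = Σ_i coeff_i·E_ij use Cox proportional-hazards
coefficients fitted by lifelines (Breslow ties, tolerance 1e−8, ≤ 100
iterations; joint fit over the module's genes by default, univariate
optional). Constant expression rows get coefficient 0 with a warning.
Downstream dichotomization and testing reuse the mutation-score flow.
Survival time units are caller-supplied and opaque to all of the above.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
copy-number biology. Genes are laid out per chromosome as non-overlapping
fixed-length intervals. Each gene, per sample, is independently gained,
lost or neutral; contiguous same-state genes are emitted as one segment
that passes the quality filter (gain runs are randomly labelled GAIN/AMP,
loss runs HETD/HOMD, neutral runs are emitted as NEUT), plus per-sample
decoy segments that fail the filter on length or probe count. This
gene-level construction guarantees that the filtered, reconstructed
mutation matrix equals the generating state matrix exactly, which the
tests assert — the acceptance surface is module recovery, not breakpoint
realism.

Default study conditions: two cohorts of n = 300 samples over 200 genes;
an 8-gene planted module mutated at total rate 0.45 (gain 0.30, loss 0.15)
against a background of mean total rate 0.08. Background rates are
heterogeneous per gene — total rate uniform on 0.08·(1 ± 0.8), gain share
Beta(0.3, 0.3), fixed per gene and shared by both cohorts — because real
gene-level CNA frequencies vary in magnitude and in gain/loss composition
(genes sit in recurrent amplicons *or* deleted regions); with identical
background rates every frequency vector would point the same way and the
cosine edge weights would degenerate to ≈ 1, leaving the similarity
weighting uninformative by construction. Under the default profile the
network's edge-weight bins (≥ 0.9 / 0.5–0.9 / < 0.5) come out near
43/21/34%, a mix comparable to what weighted CNA-similarity networks show
in practice.

The interaction network is a G(n, m) random background (600 edges, mean
degree 6 — sparse, scaled to the 200-gene universe; a small-world model is
available) with the module wired as a clique. Survival is exponential with
hazard `baseline_hazard · exp(effect · (score_j − mean score))`
(baseline 0.05, effect 1 per score unit by default; the centring makes the
baseline describe an average sample without changing the log-hazard ratio),
with independent uniform censoring on [0, 40]. Expression, when needed, is
a linear signal in the standardized module score plus Gaussian noise.
Everything derives from one integer seed; identical configurations write
byte-identical files.

What passing the synthetic experiments shows: that each stage implements
its formula exactly (oracle tests), that the pipeline end-to-end recovers
a planted module whose burden and connectivity stand out at realistic
effect sizes, and that the survival calibration behaves as analysed above.
What it does not show: performance under breakpoint-level noise,
inter-gene correlation within CNA events, network mis-annotation, or
cohort-level confounding — none of which the generator models.

## Problem sizes used by the default test run

The acceptance-style tests run the full pipeline at the generator's
default scale (two cohorts × 300 samples × 200 genes, 30 permutations for
δ selection and significance), the survival calibration at n = 200–400
with 200–1000 score permutations, and the oracle equivalences on
enumerable fixtures (all connected graphs of ≤ 6 nodes; 50 random ≤ 8-node
weighted graphs). The whole suite completes in well under two minutes on
one CPU.
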