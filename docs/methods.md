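# Methods

## Network model

The core object is a typed undirected graph over three node classes —
disease genes, miRNAs, drugs — in which an edge may only join a gene to a
miRNA (regulation) or a gene to a drug (binding). Gene nodes are exactly
the catalog's disease genes that carry at least one interaction; genes with
a risk score but no edges never enter the network, since every downstream
analysis is edge-driven. A miRNA–gene–drug triplet (MGDT) is any pair of
edges (m, g) and (d, g) sharing the gene, so the triplet count is
Σ_g deg_miRNA(g) · deg_drug(g). Triplets are always emitted in
lexicographic (miRNA, gene, drug) order, which fixes tie-breaking and makes
every output table reproducible byte for byte.

Topology diagnostics follow the conventions of interactive network-analysis
tools: the degree-distribution fit is an ordinary least-squares regression
of log10(count) on log10(degree) over the raw integer-degree frequencies
(logarithmic binning available but off by default, since binning choices
change R² and the default should be the most transparent one), and the
topological coefficient of a node n with degree k_n ≥ 2 is the mean of
J(n, m)/k_n over all nodes m sharing at least one neighbour with n, where
J(n, m) counts shared neighbours plus one if n and m are directly linked.
Nodes with k_n < 2 or no such partner get 0.

## Dysregulation scores

Each triplet is scored on three channels:

- **S_risk**: the gene's disease-association confidence from the catalog.
  It is a gene property, so triplets sharing a gene share it; it carries
  prior evidence, not expression signal, and is invariant under label
  permutation.
- **S_P = P_mRNA · P_miRNA**: the product of two two-sided two-sample
  Student *t*-test P values (pooled variance, df = n₁ + n₂ − 2; Welch
  available behind a flag). The product is small when *both* features are
  differentially expressed, but note it is also small when one P value is
  tiny and the other moderate — the product does not distinguish these
  cases, which matters for interpreting backgrounds with many perturbed
  features (see Limitations).
- **S_pcc = |D_pcc − C_pcc|**: Pearson correlation of the (gene, miRNA)
  expression pair computed separately over disease and control samples,
  then differenced. This is the differential-correlation channel: it is
  the only one that distinguishes a genuinely co-dysregulated pair from a
  coincidence of two independently perturbed features.

No per-feature differential-expression gate is applied before scoring: the
rank aggregation is designed to weigh weak and strong channels jointly, and
a hard P < 0.05 pre-filter would silently drop triplets whose evidence is
concentrated in the correlation channel.

Numerical conventions for degenerate inputs, applied identically in the
observed and permuted computations: a zero-variance feature with equal
group means gets P = 1 (no evidence), with unequal means P = 0 (the most
extreme evidence a t-statistic can give); a constant vector makes Pearson r
undefined and is reported as 0 with a warning. Group-size minima are 2 per
group for the t-test and 3 for correlations; by default a study violating
them is rejected. With `allow_degenerate_groups=True` an undefined group
correlation is set to 0 with a warning — this exists for 4-vs-1 style
designs, where the one-sample group's correlation simply does not exist; we
deliberately do not invent a value beyond the neutral 0, and results under
this flag should be read as using the difference-from-zero of the other
group's correlation.

## Rank aggregation

The three channels live on incomparable scales, so triplets are ranked per
channel — S_risk descending, S_P ascending, S_pcc descending, average ranks
on ties — and each rank r over N triplets is mapped to (N − r + 1)/N, a
fixed (0, 1] scale independent of N and stable across permutations. The
final score is the unweighted mean of the three mapped values; higher =
more dysregulated. Equal weighting is a modelling commitment, not an
estimate: no channel is privileged, and the mapping keeps the weak
monotonicity property that improving any single channel can never lower a
triplet's final score.

## Permutation null

Each permutation redraws the disease/control label assignment uniformly at
random with the group sizes preserved (assignments are sampled with
replacement across permutations; a warning is emitted if fewer distinct
assignments exist than permutations requested), applies it identically to
the mRNA and miRNA matrices, recomputes S_P and S_pcc (S_risk is
label-invariant), re-runs the full rank aggregation, and records every
triplet's permuted final score. The per-triplet P value uses the add-one
estimator (1 + #{permuted ≥ observed})/(1 + N_perm), which is never 0 and
is conservative (super-uniform) under exchangeability. All randomness flows
from one `numpy.random.default_rng(seed)` stream consumed as exactly one
full label permutation per iteration, so results are bit-reproducible per
seed.

Two null granularities are provided. The default compares each triplet with
its own permuted scores (per-triplet null): this respects per-triplet
structure such as the invariant risk rank. `pooled=True` compares each
observed score against the pooled permuted scores of all triplets; because
final scores are rank-derived, the pooled null is close to a fixed
Bates-like reference and effectively thresholds the observed score itself.
The per-triplet null is the default because it conditions on what
permutations cannot change.

Multiple testing is not corrected by default (selection is raw P < α with a
strict inequality); Benjamini–Hochberg adjustment is available as an option.

## Downstream constructions

Significant triplet sets are compared between diseases on whole-triplet
identity (a "common" triplet has the same miRNA, gene and drug in both
diseases); component-level overlap is reported separately as a descriptive
extra. The significant network is the union of each triplet's two edges;
drug participation counts triplets per drug (descending, lexicographic
tie-break); the gene-centered subnetwork is the star of edges incident to
one gene. Score-profile summaries tabulate location/spread statistics and a
deterministic 30-bin histogram per score channel.

Pathway enrichment replaces web-service annotation with the explicit
statistic underlying such tools: the upper-tail hypergeometric test
P(X ≥ k) of a query gene set against each GMT set, both restricted to a
background universe. The default universe is the intersection of the GMT
union with the miRNA-target catalog — enrichment of a miRNA's targets
should be judged against what targets could have been drawn, not the whole
genome; the GMT-union and explicit-list policies are selectable and the
universe used is logged. Per-miRNA profiles are the enriched pathways
(P < α) of each miRNA's own target set; "common pathways" are those
enriched in at least ceil(min_fraction · n) of the profiles, with
min_fraction = 1 (strict intersection) as the default. The drug–pathway
network joins one drug–gene pair, the profiled miRNAs, and the common
pathways through drug–gene, miRNA–gene and miRNA–pathway edges.

## Synthetic benchmarks

The generator emulates the pipeline's three input families. Interaction
catalogs are sparse Bernoulli bipartite tables (each miRNA–gene pair
present with density 0.06, each drug–gene pair with 0.04 by default) with
risk scores drawn from Beta(2, 5) — right-skewed on [0, 1], mimicking
curated disease-gene catalogs where most associations have modest
confidence. Expression studies have i.i.d. Normal(0, σ) background in both
groups; each planted triplet's (gene, miRNA) pair is bivariate normal
(Cholesky construction) with correlation ρ_disease = 0.8 in disease and
ρ_control = −0.5 in control samples and a mean shift of δ·σ = 2σ in the
disease group for both features. The default design — 50 genes, 80 miRNAs,
120 drugs, 10 vs 10 samples, 20 planted triplets — yields ~1200 triplets
and runs the full 500-permutation analysis in about a second, sized so the
entire test battery stays at desk scale.

Planted signal is a property of the (gene, miRNA) expression pair: the drug
never enters the generative model. Planted pairs are therefore drawn
uniformly from the eligible miRNA-target pairs (gene must be a disease gene
with a drug partner), with pairwise-distinct genes and miRNAs so each pair
carries exactly its designed parameters, and a uniformly drawn drug partner
names the representative planted triplet. Every same-pair/different-drug
triplet is score-identical to its representative and is counted as signal-
carrying (`GroundTruth.carries_signal`), not background. Planted genes'
risk scores are redrawn from the top quartile of the Beta law so all three
channels carry signal (toggleable, to study partial-signal behaviour).

What the generator does *not* emulate: probe-level noise, batch effects,
heteroscedasticity, correlated background features, library-size artefacts,
or realistic degree distributions of curated databases (Bernoulli edges
give binomial, not heavy-tailed, degrees). Passing benchmarks therefore
demonstrates the statistical machinery — calibration of the null,
recovery of exactly the planted signal structure — not robustness to real
microarray pathology.

## Calibration and power at the default conditions

On pure-null benchmarks the per-triplet permutation P values are mildly
super-uniform (the add-one estimator plus ties in the discrete rank-derived
final scores), and triplet P values are positively dependent because all
triplets share one ranking and one permutation stream; across generator
seeds the significant fraction at α = 0.05 centers near 0.045. Calibration
checks retain a seeded uniform subsample of triplets rather than a
lexicographic prefix, since a prefix clusters on few miRNAs and inflates
the dependence.

Recovery of planted triplets at the default design is power-limited, at
roughly 85% sensitivity on average (α = 0.05, 500 permutations): with 20
of 50 genes perturbed, any triplet containing one planted feature has a
near-planted S_P; sample correlations at n = 10 are noisy (SD ≈ 0.3); and
near-original label splits give planted triplets a heavy permuted-score
tail. Planted triplets nonetheless separate clearly in the final score
(median far above the background 95th percentile). Larger group sizes or
sparser planting push sensitivity toward 1.

## Limitations

- The S_P product conflates "both features moderately significant" with
  "one extremely significant"; interpretation should always consult the
  two P values kept in the output table.
- The per-triplet permutation null conditions on the observed ranking
  structure; with few samples (≤ 6 per group) the attainable P values are
  coarse and near-original permutations bound power.
- Correlation differences at small n are noisy; the package refuses groups
  below 3 samples rather than report undefined correlations.
- Identifiers are treated verbatim; alias/probe mapping is out of scope and
  must happen upstream.
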