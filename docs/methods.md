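# Methods

This note documents the models, statistical conventions and numerical
choices behind `phylosym`, in the order data flow through the pipeline.

## Synthetic holobiont model

The generator emulates a multi-population host survey: `n_populations`
host populations (default 9) with `n_individuals_per_population` sampled
individuals each (default 6), a subset of populations carrying a dominant
intracellular endosymbiont (default: the first six, giving 36 infected vs
18 uninfected samples).

**Host tree.** A uniform random rooted bifurcating labeled topology is
drawn by sequential insertion: leaf *k*+1 attaches uniformly to one of the
2*k*−1 possible positions (any edge, or above the root). This scheme is a
bijection onto insertion histories and yields the uniform distribution
over the (2*n*−3)!! labeled topologies — deliberately shape-unbiased,
because the same sampler provides the null for the congruence test.
Branch lengths are i.i.d. exponential(1) by default (arbitrary positive
units; their magnitude is absorbed by `sigma_phylo`). A `"coalescent"`
mode draws a Kingman coalescent tree instead, which is ultrametric; see
*Limits of UPGMA recovery* below for when that matters.

**Communities.** Each of K background OTUs gets a root log-abundance
drawn N(0, 1). Log-abundances evolve along the host tree as Brownian
motion with variance `sigma_phylo² · branch_length`, producing one
population-level log-profile per leaf. Each individual adds i.i.d.
N(0, `sigma_ind`²) noise per OTU. Relative abundances are the softmax of
the log-profile — the simplest compositional link with separately tunable
between-population and within-individual variance. Reads are multinomial
at fixed depth D, so every sample's counts sum to D exactly.

**Endosymbiont spike-in.** For each infected population a load *w* is
drawn once, uniformly from `endo_prop_range` (default 0.203–0.964, the
relative-abundance range dominant *Wolbachia* infections reach in insect
hosts); infection is a population-level trait, so all individuals of the
population share *w*. The endosymbiont OTU takes fraction *w* of the
composition and background OTUs are rescaled by 1−*w*. The spike-in is
how the generator reproduces the diversity-dilution phenomenon: a taxon
occupying 20–96% of reads mechanically depresses Shannon and Simpson
indices, giving a strongly negative Spearman correlation between load and
diversity.

**Defaults.** `n_otus=200` and `depth=20000` are desk-scale choices large
enough that multinomial noise is small relative to the community signal;
`sigma_phylo=1.0`, `sigma_ind=0.3` give a clear but not saturated
phylosymbiosis signal (at `sigma_phylo` ≳ 3 the softmax saturates: a few
OTUs dominate every population and Bray–Curtis loses its gradient). All
randomness flows from a single `numpy` Generator seeded by `params.seed`;
identical parameters give byte-identical output bundles.

**What the generator does not emulate.** No sequence-level processes
(reads, chimeras, OTU clustering), no taxonomy beyond a synthetic lineage
string, no overdispersion beyond multinomial sampling, no spatial or
temporal structure, and no correlation between infection status and host
phylogeny. Passing tests on these data show the pipeline's statistical
machinery is correct and calibrated; they do not show that real
communities satisfy the Brownian/softmax model.

## Diversity conventions

- **Rarefaction** subsamples each sample without replacement
  (multivariate hypergeometric) to a common depth; `depth="min"` uses the
  shallowest sample's total, the usual "sample with the fewest sequences
  sets the standard" rule. Samples below an explicit depth raise an error
  rather than being dropped silently. Zero rows are kept by default so OTU
  indices stay aligned. A single seeded draw is the default; an averaged
  mode is available through `rarefaction_curve`'s `reps`.
- **Shannon** is reported in bits (log base 2, the convention of the
  classic QIIME-era pipelines); natural log is an option. **Simpson** is
  Gini–Simpson 1−Σp²; inverse Simpson is an option.
- **Chao1** defaults to the bias-corrected form
  S + F1(F1−1)/(2(F2+1)), which remains defined when F2=0; the classic
  form S + F1²/(2F2) is an option (falling back to the bias-corrected
  form when F2=0). **ACE** uses the standard rare/abundant cutoff of 10
  and clamps γ² at 0; it is undefined (error) when every rare OTU is a
  singleton (sample coverage 0).
- **Faith's PD** sums branch lengths of the minimal rooted subtree
  spanning the observed OTUs *including the path to the root* (the
  "whole tree" convention).
- **Weighted UniFrac** defaults to the normalized variant (bounded [0,1]),
  dividing the branch-weighted abundance difference by
  Σ_leaf depth·(p_x+p_y); the raw variant is an option. Unweighted UniFrac
  is unique-branch-length over observed-branch-length. On a star tree with
  unit pendants it reduces exactly to binary Jaccard.
- All four beta metrics are validated against scikit-bio on random inputs
  in the test suite; the in-package implementations exist to pin the
  conventions above explicitly.
- **Population collapse** averages all between-sample distances across two
  populations. **Core OTUs** use pooled presence (detected in ≥1 sample of
  every population); a stricter all-samples mode exists. The per-population
  "shared %" is reported against both the population's own richness and
  the total OTU count, since either denominator is defensible.

## Tree metrics and normalization

Both congruence metrics are rooted and topology-only (branch lengths
ignored; both compared trees are rooted dendrograms). A tree's cluster set
is its nontrivial clades: leaf sets under internal nodes, excluding the
root clade and singletons — exactly n−2 clades for a bifurcating n-leaf
tree.

- **RF** raw = |C1 Δ C2|; nRF = raw / (|C1|+|C2|), which is raw / 2(n−2)
  for bifurcating pairs and handles non-bifurcating inputs gracefully.
- **MC** pads the cluster sets with empty clusters to equal cardinality
  and solves the assignment problem (scipy's Hungarian solver) with cost
  |c1 Δ c2|; raw = minimum matching cost. MC refines RF: a clade that is
  almost right contributes little cost instead of a full mismatch.
- **nMC normalization.** The maximum MC distance over same-size leaf sets
  has no closed form in general. For n ≤ 8 the package computes it
  exhaustively, exploiting invariance under joint relabeling to reduce the
  search to (one labeled representative per unlabeled shape) × (all
  labeled topologies) — exact, and tractable where the naive all-pairs
  search is not. For larger n the normalizer is the maximum of (a) a
  caterpillar vs interleaved-caterpillar witness pair, (b) the observed
  Monte-Carlo null sample when one is available, and (c) the observed
  score itself, so nMC never exceeds 1. Every result carries
  `normalizer` and `normalizer_method`, so the convention is explicit in
  all output.

**UPGMA** is true (size-weighted) average linkage, merging the closest
pair at height d/2. Exact ties are broken by the lexicographically
smallest pair of cluster labels (a cluster is labeled by its smallest
leaf), making merge order deterministic across platforms. The output is
ultrametric, and reproduces its input exactly when the input is
ultrametric; on random matrices it matches scipy's average-linkage
cophenetic distances.

## Statistical tests

- **Mantel**: correlation (Pearson default, Spearman option) over the
  n(n−1)/2 off-diagonal entries of two label-aligned distance matrices;
  the null jointly permutes rows/columns of one matrix;
  P = (1+#{r_perm ≥ r_obs})/(n_perm+1), one-sided "greater" by default
  since phylosymbiosis predicts a positive association (two-sided and
  "less" available). For Spearman, entries are rank-transformed once — a
  joint permutation only rearranges them, so the permutation loop stays in
  Pearson form.
- **Topological congruence**: N uniform random topologies on the same
  leaves are scored against the microbiota dendrogram;
  P = (1+#{s_null ≤ s_obs})/(N+1). The +1 correction keeps P in (0,1].
  The library default is N = 100,000; the pipeline default is 1,000 for
  desk-scale runs (the P-value resolution floor is 1/(N+1)). Because the
  null statistic is integer-valued, the test is slightly conservative: the
  exact attainable level at α=0.05 was measured at ≈0.035 (RF/MC, 9
  leaves) to ≈0.040 (MC, 12 leaves). The calibration test in the suite
  uses the MC metric, whose finer lattice sits closest to nominal.
- **ANOSIM**: rank-based R = (mean between − mean within)/(M/2) with
  label-permutation P; invariant to monotone transforms of the distances.
  **MRPP**: δ = size-weighted mean within-group distance;
  A = 1 − δ_obs/mean(δ_perm); P one-sided on small δ. Defaults: 9,999
  permutations.
- **Spearman correlation** is tie-corrected; for n ≤ 9 the two-sided P is
  exact by full enumeration of pairings, otherwise the t approximation.
- **Two-sample comparisons** use the Bartlett gate: Student's pooled
  t-test when Bartlett's P ≥ 0.05, Welch's otherwise. Normality is not
  formally gated (the decision rule is variance-only); Shapiro–Wilk
  P-values are attached as an advisory. One-way ANOVA is classical F.
  No post-hoc letter display is provided; pairwise gated t-tests are the
  explicit alternative.
- No multiple-testing correction is applied across the four beta metrics;
  the report says so in its notes.

## Limits of UPGMA recovery (why the power study uses clock-like hosts)

UPGMA assumes ultrametric (clock-like) divergence. On random topologies
with i.i.d. exponential(1) branch lengths, UPGMA applied to the *exact*
cophenetic distances already misplaces leaves (median raw RF 8 of 14 at
n = 9): a short-pendant non-sister pair can be closer than a true cherry.
No community signal strength can overcome this — it is a property of the
estimator, not of the data. A monotone transform of an ultrametric matrix
is still ultrametric, so with clock-like host trees UPGMA recovery is
exact up to sampling noise. The strong-signal power study therefore uses
coalescent (ultrametric) host trees and `sigma_phylo=1.0 ≫ sigma_ind=0.1`,
where all tests recover the signal in ≥90% of replicates; with
exponential branch lengths the topological tests top out near 85% (RF)
and 50% (MC) regardless of signal. The power study also omits the
endosymbiont spike-in: a dominant taxon whose load varies orthogonally to
the phylogeny is a genuine confounder that masks the Bray–Curtis
dendrogram signal, and its effect is studied separately via the
diversity-dilution test.

## Degenerate inputs and numerical details

- All-zero count vectors, constant distance matrices, and zero-variance
  comparisons raise typed errors rather than returning NaN; the one
  deliberate NaN-guard is MRPP's A, set to 0 with a warning when all
  distances are zero.
- Ultrametricity of UPGMA output holds to 1e−9; distance-matrix symmetry
  is enforced by the skbio container.
- Monte-Carlo and permutation P-values always carry the +1 correction.
- Every stochastic stage takes an explicit seed; the pipeline derives
  per-stage seeds from one root seed and records them in the report, so a
  rerun from the resolved config is byte-identical.

## Problem sizes in the test suite

Exhaustive tree-metric validation runs at 5 leaves (105 topologies, all
pairs) and normalization attainability at 6 leaves (945 topologies,
shape-reduced); calibration checks use 250 replicates with 99–199
permutations; power and dilution studies use 50 replicates of the full
9×6 design with 1,000 random topologies. These sizes give stable
pass/fail behaviour under the frozen seeds while keeping the whole suite
in the low minutes.
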