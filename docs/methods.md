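# Methods

## The gain/loss model

Intron sites are binary characters (absent/present) evolving independently
along a fixed rooted species tree. The model is parameterized directly by
per-branch *intensities* — gain G_b and loss M_b, each a rate × duration
product — rather than by rates against the newick branch lengths: on a
fixed tree, rate and time are not separately identifiable, so the
intensities are the natural parameters. The branch transition matrix is
the exact solution of the two-state chain run for unit time at rates
(G_b, M_b):

    P(0→1) = (G_b/T)(1 − e^−T),  P(1→0) = (M_b/T)(1 − e^−T),  T = G_b + M_b,

with the identity matrix at T = 0. The root state is Bernoulli(π_root).

**Loss-rate variation.** Loss rates differ between intron sites far more
than gain rates do; ignoring this biases ancestral reconstructions
downward, because parallel losses at loss-prone sites get reinterpreted
as independent gains. The rate-variation model therefore multiplies every
branch's loss intensity by a site-specific category multiplier r_c, where
r_1..r_K are the means of the K equal-probability slices of a mean-one
Gamma(α) distribution and each site draws its category uniformly. K is
fixed at 2; gains are shared across categories. The constant-rate model is
the K = 1 (equivalently α → ∞) special case, so the rate-variation model
adds exactly one parameter and the likelihood-ratio statistic
Δ = −2(L1 − L2) is referred to χ²(1).

**Observability conditioning.** A site table built from alignments can
only contain sites where at least one species has the intron. Every site
likelihood is therefore divided by 1 − P(all leaves absent), computed
under the same category mixture. The constant does not depend on the
observed states, so it is computed once per model evaluation. Ambiguous
states ('?') are missing data: their leaves contribute the partial (1, 1)
and are marginalized over both states. The same two rules govern the
table filter (ambiguity cutoff, default 48 '?' per site, and the
requirement of at least one unambiguous present state) and the simulator
(rejection of all-absent draws), keeping the generative and inferential
models aligned.

## Likelihood machinery

Site likelihoods use Felsenstein pruning, vectorized across sites and
categories with per-node rescaling of partials (log-scale accumulators)
against underflow. Identical site patterns are deduplicated with counts;
this changes nothing but the constant factor in run time.

Posterior decoding uses the up–down (outside) algorithm. Per-node
presence posteriors and per-branch joint parent–child posteriors are
formed per category and mixed with the per-site posterior category
weights w_c ∝ L_c. The observability-conditioning constant cancels in
every posterior. The joint posteriors also satisfy, per branch, the
conservation identity P(child = 1) = P(parent = 1) − P(loss) + P(gain),
which the test suite asserts on random data.

**Gradients.** The fit maximizes the conditioned log-likelihood over
{G_b, M_b}, π_root and (rate-variation only) α with L-BFGS-B in a
transformed space (log intensities, logit π, log α). The gradient over
intensities and π is analytic: d logL / dP_b[a,b′] equals the expected
transition "flow" C_b[a,b′] (posterior joint probability over the branch,
divided elementwise by the transition probability, summed over sites with
category weights), and the chain rule through the closed-form derivatives
of the transition matrix gives the intensity gradient; the conditioning
term contributes the same statistics evaluated on the all-absent pattern,
scaled by n·P0/(1 − P0). The α component uses a central finite difference
in log space. The analytic gradient matches numeric differentiation to
~1e-7 relative error and makes the fit roughly fifty times faster than
finite differences over all parameters — a 16-leaf, 5,000-site
rate-variation fit takes ~20–30 s on one CPU.

**Bounds and convergence.** Intensities are constrained to [1e-8, 20],
π_root to [1e-6, 1−1e-6], α to [0.01, 1e5]. The α upper bound matters:
it must place the constant model within reach of the rate-variation
family, otherwise the nested-model ordering L2 ≥ L1 can fail and the LRT
statistic go negative. At α = 1e5 the two category multipliers are within
0.3% of 1 and the ordering holds to below the convergence tolerance
(absolute log-likelihood improvement < 0.001, the same threshold used for
multi-start termination, with at most 1,000 rounds). The rate-variation
fit always includes a start at the constant-rate optimum with large α, in
addition to seeded random starts; ties between restarts go to the first
found.

## Ancestral profiles, Dollo, bootstrap

The "expected present-site count" at a node is the sum over sites of the
posterior presence probability (ML mode) or of the Dollo indicator
(parsimony mode). Whether a root content should be read off a parameter
or as this expected count is a genuine choice; the expected-count
convention is used throughout because it also applies to internal nodes
and to bootstrap replicates. Counts are scaled to introns/kb as
count × ref_density / ref_count with configurable reference constants
(defaults 0.30 and 261, a fission-yeast-style reference).

Dollo parsimony places the single gain at the MRCA of the unambiguously
present leaves, marks the minimal spanning subtree present, and charges
one loss per maximal absent clade that contains at least one unambiguous
absence; all-ambiguous clades carry no constraint and no loss. On trees
small enough to enumerate, the reconstruction provably attains the
brute-force minimum loss count over all single-gain scenarios (asserted
in tests). Note the identifiability limit: presence on a branch whose
descendants all later lost the intron leaves no trace, so parsimony
recovers the true history exactly only when every truly present branch is
witnessed by an extant intron — guaranteed in the loss-free regime,
partial otherwise. The validation study therefore asserts the
reconstruction is always a subset of the truth with minimal losses,
rather than naive full-state equality.

Uncertainty is quantified by a nonparametric bootstrap over sites
(species columns fixed): resample rows with replacement, refit, recompute
node counts, report per-node medians and 2.5/97.5 percentiles. All
replicates share one fit seed so that identical resamples refit
identically (degenerate tables then collapse to zero-width intervals, a
useful sanity property); the resampling stream is separate and seeded.

## Event calling and its precision

Branch events are called where the posterior gain or loss probability
reaches the cutoff (default 0.99, boundary inclusive). Sites with no
called event anywhere and an extant intron are labelled "presence". For
per-species analyses, each site on the root-to-leaf path takes the most
recent called event as its label; with no called event on the path the
label is "presence" (extant intron) or "uncalled".

A caveat discovered while designing the precision benchmark: on a tree
with *uniform* per-branch intensities, no posterior ever reaches 0.99 at
moderate intensities, because the competing scenario "the event happened
one branch earlier plus a compensating second event" always retains
posterior weight on the order of the neighbour branch's intensity. What
makes high-confidence calls possible in real data is branch-duration
heterogeneity — events on long branches flanked by short ones. The
generator therefore provides `rate_time_model` (intensity = rate ×
branch duration, with exponential branch durations), and the precision
study runs under it (16 leaves, gain rate 0.05, loss rate 0.15 per unit
time, 2,000 sites, three seeds): several hundred calls per run with
precision ≈ 0.99 against the simulated truth.

## The synthetic-data generator

The generator is the study-conditions definition for all tests. Defaults:
16-leaf random bifurcating tree (exponential mean-1 branch lengths), per
branch gain 0.1 and loss 0.3 (loss-biased 3:1, per-branch survival
e^−0.3 ≈ 0.74 — a moderate, identifiable regime), π_root = 0.6, α = 1
with K = 2, 2,000 observed sites, 5% independent '?' masking, ~150 nt
mean ancestral exon segments (shifted geometric, 3 nt minimum), and
negative-binomial expression counts (baseline mean 200, size 5) in which
introns double the footprint mean (τ = 2) and a "translation" GO class
(probability 0.2) triples it. Simulation draws the child state from the
interval transition matrix — at most one net event per branch per site —
because multiple hits within a branch are unidentifiable to the
interval-based inference anyway; rejection sampling enforces
observability and the rejection count is reported.

What the generator does *not* emulate: sequence content (no splice
sites, no alignment errors beyond independent masking), correlated
evolution between sites or genes, branch-specific gain bursts (unless
configured), non-uniform intron placement within genes, and any realistic
law for expression or exon lengths (the negative-binomial and geometric
choices are testing devices). Passing tests therefore demonstrate
correctness of the algorithms under the model's own assumptions, not
robustness to real-data violations of them.

## Validation studies and problem sizes

Chosen once, as the package's own desk-scale experiments:

* **Enumeration oracle** — every topology with ≤ 4 leaves plus 12 sampled
  topologies each at 5 and 6 leaves, 5 random observable sites per
  topology (≥ 215 site comparisons), random parameters: pruning
  likelihoods, node posteriors and branch event posteriors agree with
  explicit summation over all 2^N node-state assignments at machine
  precision (observed ~1e-15, asserted < 1e-10).
* **Recovery** — 16 leaves, 5,000 sites, three seeds: root expected count
  within 10% of the simulated truth.
* **LRT null calibration** — 100 replicates of 6-leaf, 2,000-site tables
  under constant-rate truth. Because the null sits on the α boundary, the
  asymptotic reference is the half-mixture 0.5δ0 + 0.5χ²(1) (≈2.5%
  rejections at the χ²(1) 95% cutoff); the acceptance band is 1–12%.
  Smaller tables are *over*-conservative (the χ² regime has not set in),
  which is why 2,000 sites per replicate are used.
* **Dollo** — identifiable-recovery fractions equal to 1 under gain-free
  simulation; brute-force loss minimality on ≤ 6-leaf trees; full
  exactness in the loss-free regime.
* **Structure / concordance / expression** — exon tiling on all fixtures;
  loss-only simulations never produce split classes and gain-only never
  fusion classes; fused-exon median ordering in ≥ 95 of 100 seeds; mean
  concordance ratio 1 with uniform χ² p-values under independence (500
  replicates); the τ = 2 translation-efficiency effect detected at
  p < 0.01 with 2,000 genes.

## Numerical and statistical choices

* χ² tests of independence/homogeneity without continuity correction
  (large-n comparisons; correction available behind a flag).
* Bayesian binomial intervals use the Jeffreys prior Beta(½, ½) with
  posterior sampling (default 1,000 draws) and empirical 2.5/97.5
  percentiles; the concordance-ratio interval is the proportion interval
  transformed by n/expected (a monotone map).
* The bit-score threshold fits a lognormal + normal mixture by EM
  (multi-start over quantile splits, tolerance 1e-6, ≤ 500 iterations;
  responsibilities in closed form; component variances floored at 1e-4
  against degeneracy) and takes the crossing point of the weighted
  component densities between the two modes, located on Monte-Carlo draws
  from the fitted mixture. Fits with a component weight below 1e-3 are
  flagged degenerate with an undefined threshold.
* Box–Cox λ is chosen by profile likelihood on a [−5, 5] grid at 0.01
  resolution, with configurable pseudocounts (0.001 for densities, 1 for
  counts are the conventional settings).
* Independent contrasts implement the standard recursion (trait
  difference scaled by √(t_left + t_right), branch-length-weighted
  ancestral values, harmonic branch-length correction) and refuse
  polytomies; correlations between contrast sets use Spearman's rank.
* Expression comparisons log2(x + 1)-transform RPKM and TE before
  Welch's t-test; genes with zero RNA count have undefined TE and are
  excluded from the TE comparison.
* Exon classification follows the called-event labels literally: an
  extant exon with exactly k ∈ {1, 2} called internal losses and no
  called-gain boundary is "(k+1)-into-1"; a maximal run of k ∈ {1, 2}
  consecutive called-gain sites labels its k+1 exons "1-into-(k+1)";
  exons with both kinds of evidence, or more than two events, are
  "excluded"; everything untouched is "control". Uncalled absent sites do
  not block a fusion class (they are unresolvable history, and the
  classifier counts only called events).

## Known limitations

* Per-branch intensities make the model richly parameterized; on very
  small trees (2 leaves) the branch parameters are not identifiable and
  only the leaf-pattern distribution is — tests assert the identifiable
  functional.
* Root-adjacent parameters (π_root vs the root children's intensities)
  are weakly identifiable under heavy loss; recovery guarantees hold in
  the moderate-intensity regime stated above.
* The LRT calibration band assumes the boundary half-mixture null, which
  needs thousands of sites per replicate to be accurate.
* Acceptor/donor splice-site shifts, intron sliding, and alignment error
  beyond independent masking are out of scope; '?' handling assumes
  missingness is independent of the true state.
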