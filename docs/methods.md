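# Methods

## The enrichment model

For each concept the package fits, by maximum likelihood, a logistic
regression of the membership indicator of every measured gene on an
intercept and the significance covariate x = −log10(p). Inference is a
Wald test on the slope (z = β̂₁/se, two-sided normal p); a likelihood-ratio
variant was considered and rejected to keep a single, per-concept-cheap
inferential path — at the sample sizes involved (thousands of genes per
fit) the two are practically indistinguishable. The equivalent reading is
a "random sets" test: whether the concept's genes are collectively more
(or less) significant than a random set of the same size. The test suite
pins this equivalence with a permutation oracle (Spearman ρ ≥ 0.9 between
the two p-value rankings, and exact slope-sign agreement with the in-set
vs out-of-set mean difference).

Assumptions worth stating: gene-level p-values are treated as exchangeable
under the null across genes (no correlation between neighbouring genes or
probes), the universe is *all measured genes* after probe collapsing — not
only genes annotated to some concept — and each concept is tested
marginally, so overlapping concepts yield correlated results (as in all
marginal set-testing methods).

### Degenerate and ill-posed fits

* Zero-variance covariate (all genes share one p): slope 0, p = 1 by
  convention — the covariate carries no information.
* Complete separation or non-convergence of the MLE: the concept is refit
  with a small quadratic (ridge) penalty, λ = 1e-4, on both coefficients;
  standard errors come from the penalized Hessian and the result is
  flagged `converged=False` rather than dropped. With x bounded by the
  p-value floor (below), separation is rare but possible for small
  concepts concentrated at the extreme of x.
* p-values of exactly 0 are clamped to 1e-15 on input so x stays finite.
  One-sided conversions are clamped to the same floor.

### Directional arms

The directional test converts the two-sided gene p to a one-sided p per
arm before the log transform: arm "up" uses p/2 for positive effects and
1 − p/2 for negative (arm "down" symmetric; a zero effect falls in the
1 − p/2 branch of both arms). This construction makes arm symmetry exact:
negating every effect swaps the two arms' outputs bit-identically, which
the tests assert. The effect's magnitude is never consumed by the
enrichment test itself — only its sign.

### Parameters

| parameter | default | meaning |
|---|---|---|
| min/max concept size | 10 / 500 | effective size bounds after intersection with the measured universe |
| odds-ratio anchors p_lo, p_hi | 0.5, 0.001 | OR = exp(β̂₁·(x_hi − x_lo)): odds change between a null-ish and a clearly significant gene |
| driving-gene cut-off | 0.05 | member genes reported as driving the signal (directional arms also require a matching effect sign) |
| probe collapse | min_p | see below |
| ridge penalty λ | 1e-4 | separation fallback only |

FDR is Benjamini–Hochberg (via statsmodels), applied within each concept
type and arm, matching per-family FDR reporting.

## Probe collapsing and the differential stage

Input tables may carry several probes per gene. `min_p` (default) keeps
the most significant probe's record — any significantly differential probe
marks its gene, which matches reading promoter CpG sites as evidence for
the gene. `fisher` combines probe p-values by Fisher's method (χ² with 2k
df) with the −ln(p)-weighted mean effect so the sign tracks the
significant probes; `mean` is plain averaging. All three are idempotent.
The aggregation rule is a package convention, configurable because
reasonable analyses differ here.

The optional beta-matrix stage is a plain two-sided t test per probe
(Welch unpaired, or paired on within-pair differences), effect =
mean(tumor) − mean(normal) on the beta scale, positive = hypermethylated
in tumor. It deliberately omits empirical-Bayes variance moderation:
moderation matters most at very small n, and the stage exists to feed the
enrichment test, not to compete with dedicated differential-methylation
fitters. Probes with fewer than two usable values per group or zero
variance get p = 1 (effect-0 case) and a `degenerate` flag, keeping the
gene universe stable rather than introducing missing rows; a zero-variance
probe with a non-zero mean shift gets the p floor instead.

## Cross-study clustering

Signed scores v = ±(−log10 p_enrich) (+ for enriched/up, − for
depleted/down) put hyper- and hypomethylated concepts on opposite sides of
zero; directional runs contribute one row per concept — the arm with the
smaller p, tie toward up — not two. Missing cells (concept filtered by
size in one study) are allowed; distances use pairwise-complete positions.

The distance is 1 − uncentered Pearson correlation (cosine-like, no mean
centering), range [0, 2]; a profile that is all zero over the shared
positions is treated as orthogonal (d = 1). Centroid linkage re-represents
a merged cluster by the element-wise mean over its leaves (NaN-aware) and
re-evaluates the correlation distance to that centroid — the Cluster-3.0
convention, which can produce inversions (non-monotone merge heights);
monotonicity is asserted only for average and complete linkage. Equal
minimum distances break toward the lexicographically smallest active pair
(i, j), making the merge sequence deterministic and input-order
invariant. The agglomeration is the naive O(n³) loop: post-filter
matrices are hundreds of rows at most, where exactness and determinism
matter more than speed.

Output is the Eisen Cluster 3.0 triple: `cdt` (header GID/UNIQID/NAME/
GWEIGHT + one column per study, EWEIGHT row, AID row when a column tree
exists, rows in leaf order, 6 significant digits, missing cells empty) and
`gtr`/`atr` (one line per merge: node, children, similarity = 1 − d).
Rendering is TreeView's job.

## Gene-level overlap

For a concept and a study pair, member genes measured in both studies are
cross-tabulated by significance (p < 0.05 by default; the cut-off is a
package convention). The test is one-sided Fisher's exact for positive
association — the hypergeometric upper tail Pr(X ≥ n_both) with margins
fixed — since the question is whether the same genes recur, not whether
they avoid each other. Odds ratios use the Haldane 0.5 correction when a
cell is empty. All k·(k−1)/2 unordered pairs are tested and
BH-adjusted. Optional direction matching (member effect sign must agree
with the concept's direction) is off by default.

## The synthetic generator

Per study: null genes draw p ~ Uniform(0,1) and a random effect sign;
members of a planted enriched concept draw p ~ Beta(a, 1) with a < 1
(mass near 0; a is the single signal-strength knob) and an effect sign
matching the planted direction with probability 0.9 — not 1.0, so
directional tests see realistic sign noise. Depleted members draw
p ~ Beta(1, a), the mirror image under p → 1 − p, putting mass near 1.
Genes in several planted concepts take the strongest (smallest-a) signal.
Effects are |N(0.15, 0.05)| for planted genes and |N(0, 0.05)| for null
ones, on the delta-methylation scale. Each gene carries 1 + Poisson(0.3)
probes with independent draws. Default panel conditions: 5,000 genes, 60
concepts of 30–80 genes, 10 studies, 6 concepts planted at a = 0.2 shared
by all studies.

Study streams are seeded from (seed, study index), so a panel is
reproducible byte-for-byte and each study is independently regenerable.

What the generator does *not* emulate: correlation between genes or
probes, platform-specific beta-value covariance, cellular heterogeneity,
or concept overlap structure beyond an optional shared-core rate. Passing
tests therefore demonstrate correctness and calibration under independent
gene-level noise — they do not certify behaviour under the correlated
noise of real arrays, where marginal set tests are known to be
anti-conservative.

## Problem sizes in the checks

The acceptance script and test suite use: 2,000 null concepts over 10,000
genes for type-I calibration; a 100-gene instance with 10,000 permutation
draws for the random-sets oracle; 15 planted + 60 null concepts over
5,000 genes for power; 100 replicates (size 50 over 2,000 genes) for
depletion; and a 10-study, 4,000-gene, 40-concept panel for the
end-to-end workflow. These sizes give stable statistics at interactive
runtimes; all scale linearly if enlarged.

## Known limitations

* Wald inference can be slightly conservative/anticonservative for very
  small concepts at the size floor; the calibration check covers sizes
  10–200.
* Marginal testing of overlapping concepts; no topology-aware or
  competitive-vs-self-contained distinction beyond the enriched/depleted
  sign.
* The cross-study matrix treats studies as exchangeable columns; no
  study-size weighting in the clustering.
* `read_cdt` reads the files this package writes; it is not a general
  Cluster-3.0 parser.
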