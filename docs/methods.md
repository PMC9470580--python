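# Methods

`glcmbayes` analyses two-class grayscale image collections (its motivating
use case is distinguishing brain-tumour MRI slice types) by extracting
co-occurrence texture features and then profiling the dependence structure
among those features with a tree-structured Bayesian network. This note
records the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic validation does and does not show.

## Texture features

Each image is quantized to `M` gray levels (default `M = 8`) by an
equal-width partition of the full representable intensity range
`[0, 2^bit_depth − 1]`, independent of the image's own dynamic range, so
that identical textures at different brightness offsets map consistently.
Levels are 1-based (`1..M`), matching the convention in which the
co-occurrence matrix is an `M × M` array indexed by level.

A co-occurrence matrix counts ordered pairs of levels at a fixed pixel
displacement (distance `d ∈ {1,2,3,4}`, angle `θ ∈ {0°,45°,90°,135°}`,
rows growing downward so 45° points up-and-right). Pairs whose neighbour
leaves the image are skipped — no padding. In the default symmetric mode
each pair is accumulated in both directions, which makes the matrix
exactly symmetric; counts are normalised to probabilities `p(i,j)`.

Thirteen scalar features are computed per matrix, with marginal means
`μx = Σ i·px(i)`, `μy`, standard deviations `σx, σy`, and the diagonal-sum
distribution `p_{x+y}(k) = Σ_{i+j=k} p(i,j)`:

| feature | formula |
|---|---|
| autocorrelation | `Σ i·j·p(i,j)` |
| contrast | `Σ (i−j)² p` |
| correlation1 | `Σ (i−μx)(j−μy) p / (σx σy)` |
| correlation2 | `(Σ i·j·p − μx μy) / (σx σy)` |
| cluster shade / prominence | `Σ (i+j−μx−μy)^{3,4} p` |
| dissimilarity | `Σ |i−j| p` |
| energy | `Σ p²` |
| entropy | `−Σ p ln p` (natural log) |
| homogeneity1 / 2 | `Σ p/(1+|i−j|)`, `Σ p/(1+(i−j)²)` |
| max probability | `max p` |
| sum variance | `Σ_k (k − SA)² p_{x+y}(k)`, `SA = Σ k p_{x+y}(k)` |

The two correlation forms are algebraically identical; both are kept
because feature sets in this family conventionally carry both, and their
perfect sample correlation (`r = 1.0000`) is a structural fixture of the
downstream arc report — the package's tests verify the identity to 1e-10.
Sum variance is taken about the sum average `SA` (the standard resolution
of the well-known erratum in the original definition, where the printed
formula references the entropy instead). If `σx σy = 0` (a constant
texture) both correlations are set to 0 and a degenerate-texture warning
is issued. Per image, features are computed for every offset in the
`d × θ` grid and averaged (arithmetic mean), the standard rotation-robust
choice; per-offset rows are available via `aggregation="none"`.

## Feature ranking

Each feature is scored by the symmetrised Kullback–Leibler divergence
`½[KL(p‖q) + KL(q‖p)]`, in bits, between its two class-conditional
histograms on shared equal-width bins spanning the pooled range (default
10 bins, pseudo-count `0.5/n_class` per bin). Symmetrisation removes the
dependence on class order; following the pooled range makes the score
invariant under any common affine rescaling of a feature. The top-scored
feature (ties broken lexicographically) becomes the analysis target.

## Discretization

Continuous features are cut into `k` states (default `k = 4`) labelled
`≤c₁ … >c_{k−1}` with the upper boundary closed: a value exactly equal
to a cut belongs to that cut's `≤` state. The default method is
equal-frequency, with cuts at order-statistic quantiles so every cut is
an observed value; equal-width cuts and fully explicit cut vectors are
also supported (explicit cuts let a user mirror externally published
state boundaries). Duplicate quantiles collapse with a warning; constant
features become single-state. The discrete table retains each state's
conditional mean of the underlying continuous values — these are the
"prior/posterior mean" entries of the profiling reports.

## Tree network: learning, fitting, inference

Structure is the Chow–Liu maximum-weight spanning tree over pairwise
mutual information (bits, plug-in estimates from the discrete table),
selected by Kruskal's algorithm with a deterministic tie-break (higher
MI first, then lexicographic node pairs). Arcs are oriented away from
the analysis target — a display convention only: orientation within a
tree is not identifiable from observational data. If every pairwise MI
is numerically zero the learner returns isolated nodes with a warning.

CPTs use uniform Dirichlet smoothing, `(count + 1) / (total + k)` by
default; `prior_count=0` gives maximum likelihood. Inference is exact:
a single leaves-to-root message pass yields the marginal probability of
any hard-evidence set, and posteriors are ratios of such passes. The
implementation is validated against full joint enumeration on random
trees (≤ 1e-10).

The MDL score is `−Σ_rows log₂ P(row)` plus `½·log₂(n)` per free CPT
parameter — the standard BIC-type two-part code. It is reported for the
fitted tree; the package does not search beyond tree structures.

## Arc and node reports

An arc's KL force is the divergence between the fitted joint and the
same tree with that arc deleted and the child refit against the model
(its CPT replaced by the model's own child marginal). Because only one
factor changes, the divergence reduces exactly to the endpoints' mutual
information under the fitted joint — hence the near-identity of the KL
and MI columns in tree arc reports. Relative weight is KL/max KL;
contribution is 100·KL/ΣKL; Pearson correlations are computed on the
continuous (pre-discretization) columns, where perfect ±1 values are
attainable; the per-arc p-value is a likelihood-ratio G test of
independence (`2ΣO·ln(O/E)` against χ² with `(r−1)(c−1)` d.f.) on the
raw discrete counts. Node force sums incident arc forces (outgoing +
incoming = total). The target table reports each node's MI with the
target, normalized MI (percent of the target's marginal entropy) and
relative significance (MI/max MI).

## Profiling

* **Tornado**: for every other node and state, place hard evidence and
  record the posterior delta of the chosen target state; sort by |delta|.
* **Dynamic profile**: greedy accumulation of the single best
  (node, state) hard evidence for the target state. Each step reports
  P(s|H), P(H), P(H|s) = P(H)·P(s|H)/P(s), the Bayes factor
  BF = P(s|H)/P(s), and a generalized Bayes factor taken as posterior
  odds over prior odds — the standard odds-ratio form, chosen because no
  other ratio of the printed step quantities is self-consistent. The
  Bayes-rule identity P(s|H)·P(H) = P(H|s)·P(s) holds exactly at every
  step, and the greedy posterior sequence is non-decreasing by
  construction.
* **Optimization tree**: bounded-depth exhaustive enumeration of
  evidence combinations whose posterior for the target state meets a
  threshold (default depth 3; nodes in lexicographic order so each
  combination appears once).
* **Segment profile**: per target state, min–max-normalized conditional
  means of every feature plus two state-vs-rest tests — a two-tailed
  Welch t test (α = 0.05) and a Bayesian two-group comparison with
  Student-t likelihoods (group means ~ Normal(pooled mean, 1000·pooled
  sd), scales ~ Uniform(pooled sd/1000, 1000·pooled sd), normality ~
  1 + Exponential(29)), sampled by a seeded random-walk Metropolis chain
  (default 20 000 draws, 50 % burn-in) and judged significant when the
  95 % HDI of the mean difference excludes 0. The random-walk sampler is
  adequate for this 5-parameter unimodal posterior; its acceptance rate
  is reported so pathological runs are visible.
* **Target evaluation**: each row's target state is predicted as the
  argmax posterior given full evidence on the other nodes (ties to the
  lowest state). Per state: occurrence, reliability (= recall = purity),
  precision, the error-receiving neighborhood, one-vs-rest ROC index and
  Gini = 2·AUC − 100. Globally, posteriors are converted to a continuous
  prediction through the state conditional means, giving R, R² = R²,
  RMSE and NRMSE (RMSE over the target's range).

## Synthetic study conditions

The texture generator draws white-noise fields, smooths with a Gaussian
kernel at a class-specific radius, and affinely rescales to 8-bit
(default mean 120, sd 40, 64×64 px, 100 images per class; rough class
radius 0, smooth class radius 2). Smoothing is the single controlled
contrast: it provably concentrates the co-occurrence distribution, so
the smooth class has higher energy/homogeneity and lower entropy. What
this does **not** emulate: anatomical structure, intensity
inhomogeneity, partial-volume effects, scanner noise statistics, or the
class-overlap levels of real MRI — passing tests demonstrate the
pipeline's correctness and sensitivity under a known monotone contrast,
not clinical performance. The tree sampler (child copies parent with
probability `strength`, else uniform over the other states) provides
exact ground truth for structure recovery; the feature-table generator
(multivariate normal with a requested correlation matrix, an exactly
duplicated column pair and optional class mean shifts) exercises the
ranking and correlation-reporting paths.

Default problem sizes (100 images/class at 64×64 for image-level checks,
n = 5000 rows for structure recovery, 1000 replicates for test
calibration) were chosen as the smallest sizes at which the generators'
effects are comfortably beyond sampling noise.

## Numerical conventions and edge cases

All discrete information quantities are in bits; the closed-form
Gaussian entropy/MI helpers are in nats, as is conventional for those
formulas. Probability vectors are validated to 1e-6; co-occurrence and
CPT normalisation to 1e-9. Ties: lexicographic everywhere (ranking,
MWST edges, argmax prediction uses the lowest state index). Degenerate
inputs — constant images, constant features, empty discretization
states, impossible evidence — warn-and-degrade where a sensible value
exists and raise with context where none does (e.g. evidence with zero
model probability names the offending assignment).

## Known limitations

* Tree-structured networks only; no general DAG search or taboo-list
  refinement.
* Arc orientation is a display convention, not a causal claim.
* The G test and the MI plug-in estimates are asymptotic; with very
  sparse contingency tables the reported p-values are approximate.
* The generalized Bayes factor follows the odds-ratio definition; other
  software may print a differently defined quantity under the same name.
* Image ingestion is limited to 8-bit grayscale PNG/TIFF (plus in-memory
  arrays); no volumetric (3-D) co-occurrence.
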