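# Methods

## The problem

Trace alkaloids in illicit cocaine reflect the coca cultivar, and stable
isotope ratios reflect the growing environment (altitude, humidity, soil
nitrogen); together the seven measurements carry a regional signature that
survives clandestine processing.  Given a labelled reference collection
from the 19 recognized growing regions, the task is to classify a new
profile to a region, to fall back to a country-level call when sub-regional
confidence is inadequate, and to notice profiles unlike anything in the
reference set.

## Synthetic reference collection

The authentic collection is not distributable, but its per-region means,
SDs and sample counts are published for all seven variables.  The generator
treats those moments as the generative truth:

* **Isotopes** are normal: x ~ 𝒩(μ_v, σ_v).  δ values are unbounded in
  principle and the printed SDs are small relative to their ranges.
* **Alkaloids** are log-normal with the first two moments matched to the
  printed mean m and SD s: μ = ln(m²/√(m²+s²)), σ² = ln(1+s²/m²).  Several
  regions print s > m (Cauca tropacocaine 1.28 ± 2.01; Norte de Santander
  truxillines 26.4 ± 24.7): a normal model would produce impossible
  negative concentrations, while the log-normal is strictly positive and
  right-skewed, matching how such trace percentages behave.  s = 0 rows
  collapse to the constant mean.
* **Cross-variable dependence** defaults to the identity: only marginal
  SDs are published, so any correlation matrix would be invented.  A
  Gaussian copula accepts an arbitrary PSD correlation matrix for
  sensitivity studies.
* **Counts.** The per-region counts sum to 529 while the published country
  totals are 58/361/153 (N = 572); the shortfall is allocated within each
  country by largest-remainder proportional top-up, honoring both sets of
  printed numbers at the level each claims.
* **Artifacts.** Alkaloid values at or below the LOD (0.01%, the smallest
  printed value) are flagged left-censored and stored at the LOD; optional
  missingness blanks cells uniformly; optional outlier rows inflate the
  deviation of 1–3 variables from the column median.  The default
  collection applies only LOD censoring — missing/outlier injection is a
  study condition to be requested explicitly, with ground-truth masks
  returned for calibration of the screening stage.
* **Coordinates** are drawn uniformly inside coarse per-region bounding
  boxes kept in the registry.  The boxes are illustrative (they support
  kriging demonstrations and plausible-looking records), not geodetic
  truth; no within-region spatial autocorrelation is modelled.

What passing tests on this proxy do **not** show: the proxy has independent
variables within each region, exactly log-normal/normal marginals and no
batch effects.  Conclusions about absolute accuracy on authentic, correlated
data do not transfer (see *Performance on the proxy* below).

## Preprocessing and exploratory stage

Alkaloids are log₁₀-transformed (their distributions span orders of
magnitude) and all variables autoscaled to zero mean / unit variance on
training data; censored cells are imputed at LOD/2 before the transform
(the standard substitution for left-censored geochemistry), and missing
cells stay masked until the stage that needs complete vectors (per-class
mean imputation for PCA/HCA/mixture fits).

Outlier screening is report-only: Tukey fences at k = 1.5 (mild) and 3.0
(extreme) per variable, and within-class squared Mahalanobis distance
against the χ²₇ 0.975 quantile (classes under 8 samples skip the
multivariate screen).  Mild/moderate cases stay in the data table; only the
report distinguishes grades.

Superclusters are found by recursive model-based clustering: at each node,
full-covariance Gaussian mixtures (ridge 10⁻⁶, 10 initializations) are
fitted for every k in [2, 19] clipped to the node's label count, the
BIC-optimal mixture partitions the labels by majority component membership
(ties resolved toward the nearer component centroid), and the recursion
continues inside each group.  If a mixture refuses to split a multi-label
node, a centroid bisection guarantees every nonterminal has ≥ 2 children.
Ten initializations are used because the tree topology should be a stable
property of the data, not of initialization luck.  A `pin` option can force
a known grouping (e.g. the UHV/Cusco/Valle de Cauca node observed in
authentic data) into the root partition for regression tests; the
identity-correlation proxy does not reliably reproduce that real-data
grouping on its own.

## CAIM discretization

At the tree root each variable is discretized by greedy class-attribute
interdependence maximization: candidate boundaries are midpoints of
consecutive distinct sorted values, and with intervals r = 1..n the
criterion is CAIM = (1/n)·Σ_r max_r²/M_r.  While the interval count is
below the class count, the best candidate is accepted whenever it strictly
raises the total sum Σ_r max_r²/M_r — that sum is superadditive under
splits, so it stalls only when no boundary is informative (perfectly
interleaved classes legitimately stay a single bin); afterwards a cut must
improve the mean criterion.  Interval membership is left-open/right-closed;
values outside the training range clamp into the edge intervals (the
outlier-moderation effect) and missing values map to a reserved bin, which
is what makes discretization the universal remediation step.  Codes feed
the kernel as integer coordinates; a one-hot encoding was evaluated and was
slightly worse.  Only the root is discretized; deeper nodes see continuous
preprocessed values (configurable).

## DKOPLS-C

With training matrix X (codes at the root, continuous below) and branch
indicator matrix Y:

1. K[i,j] = exp(−‖xᵢ−xⱼ‖²/2σ²), double-centered with training statistics.
   The default width σ is the median *within-branch* pairwise distance —
   the pooled median mixes branch separation into the scale and
   over-smooths tight classes.
2. For each of n_ortho rounds (default 1): the leading eigenvector t of the
   kernel residual outside the predictive score span is taken as the
   response-orthogonal score; its loading direction is projected out of
   feature space, K ← K − (Kt)(Kt)ᵀ/(tᵀKt).  The identical rule applies to
   query rows, which makes training scores and transformed training rows
   coincide exactly.  Rounds with no orthogonal variation left are skipped
   with a warning (so n_ortho is inert on data without such structure).
3. Predictive components: the top n_pred (default: branches − 1)
   eigenvectors C_p of YᵀKY give dual weights U_p = Y C_p and unit-norm
   scores T_p = K U_p / ‖·‖.
4. Assignment is to the branch with the nearest class centroid in score
   space under a per-branch full-covariance Mahalanobis metric (class
   covariances shrunk 20% toward the pooled covariance, trace-scaled
   ridge); confidence is the softmax of negative squared distances, so
   per-branch confidences are in [0,1] and sum to one.

All linear algebra is deterministic (fixed ARPACK start vector for the
single-eigenvector problems); refitting on identical data reproduces the
model JSON byte for byte.  The SVM-C comparison uses a soft-margin RBF SVM
(γ = 1/2σ², C = 10 default, optional small inner grid search) behind the
same predict interface with Platt-scaled confidences.

## Hierarchical descent, RND and novelty

Prediction descends from the root taking the argmax branch; if any on-path
confidence falls below τ (default 0.5 — the argmax must hold a softmax
majority) the descent stops and the sample is labelled "<Country>-RND" when
the remaining label set lies in one country, else "unclassifiable".  The
final region is asserted to lie in every chosen branch (path consistency)
and the candidate set strictly shrinks at each step.

The novelty screen computes, per region, D² = Σ_v ((x_v − μ_v)/σ_v)² over
the observed variables (alkaloids on the log scale, consistent with their
generative family), with per-variable SD floors at the instrument
repeatability (0.1/0.2/3.0/0.4 ‰ for δ¹³C/δ¹⁵N/δ²H/δ¹⁸O) or the LOD
(0.01%) so zero-SD table rows cannot produce infinite distances.  A profile
is novel when even the nearest region's D² exceeds the χ² quantile (default
0.999) at the observed dimensionality; per-region distances are also
returned so individual origins can be excluded — an isotope-only profile
can be ruled inconsistent with a specific region even when it overlaps
others.

## Validation

Hold-out evaluation sorts samples canonically by id, draws seeded
stratified 75/25 (or swept-fraction) splits per class, refits preprocessing,
discretization and every node classifier on the training part, and scores
the held-out part end to end: a prediction is correct only when the
terminal region equals the generating region; RND outcomes count as
incorrect (conservative) but are tabulated separately, and country-level
accuracy credits an RND call's country.  The supercluster topology is
derived once per dataset, mirroring the workflow in which the hierarchy is
fixed by exploratory analysis before validation sweeps; per-iteration
re-derivation would mostly measure mixture-fit noise.  Per-node Matthews
correlation coefficients use the multiclass generalization with the 0/0 → 0
convention.  The full sweep defaults to hold-out fractions 0.05–0.95 in
0.05 steps with 100 iterations each; tests and the acceptance script run
scaled-down sweeps (20 iterations at one fraction), which keeps the
Monte-Carlo standard error of a mean accuracy near half a point.

### Performance on the proxy

Because the proxy is exactly a known generative model, its Bayes classifier
is computable: the quadratic-discriminant oracle using the true generator
parameters reaches ≈ 90–92% 19-region hold-out accuracy — the proxy's
ceiling, already below the headline accuracy reported for the authentic
correlated collection.  The hierarchical DKOPLS pipeline reaches ≈ 76–83%
region-level and ≈ 93–95% country-level accuracy on the proxy.  The gap to
the oracle is structural, not a bug: root discretization (≈ #branches bins
per variable) and rank-limited kernel scores discard part of the
covariance information that this heteroscedastic proxy relies on, and hard
hierarchical routing compounds node errors multiplicatively.  On data whose
class structure lives in correlated mean shifts — as chemometric collections
typically do — these design choices cost far less.

## Isoscapes

Coordinates are projected to local equirectangular kilometers (adequate at
the ~10² km extent of a country; lon/lat degrees are anisotropic).  The
empirical semivariogram uses up to 12–15 lag bins to half the maximum pair
distance; the model (spherical default, exponential and gaussian with the
effective-range convention 1−e^(−3h/a)) is fitted by least squares with
Cressie weights √n_pairs/γ_model, which resolves the nugget from the
short-lag bins.  Ordinary kriging solves, per target, the semivariogram
system on the 15 nearest points (minimum 13 — inside the 14–16 and 12–14
search windows used for the published surfaces) with a Lagrange multiplier
forcing Σλ = 1; first-order trend removal (fit a plane by least squares,
krige residuals, add the plane back) is the default for the alkaloids, δ²H
and δ¹⁸O, and no detrending for δ¹³C/δ¹⁵N.  Grids are clipped to the
convex hull of the data plus a buffer (country-border masking would need
boundary data the package does not ship).  Leave-one-out cross-validation
reports RMS error and standardized RMS (√mean(e²/σ²_OK)); a value near 1
means the kriging variances are calibrated, and scaling the variogram by f
scales it by 1/√f exactly since OK weights are scale-invariant.  Degenerate
cases are handled explicitly: duplicate locations are averaged with a
warning, constant fields collapse to a zero-sill model whose prediction is
the neighbor mean with zero variance.

At ~200 points per country-sized window the nugget and range are only
weakly identified from a single realization (nearest-neighbor spacing
bounds the shortest observable lag); the tests therefore assert recovery at
dense geometries and calibration rather than tight parameter equality.

## Model files and reproducibility

A trained hierarchy serializes to a single JSON document: tree topology,
per-node numeric arrays (reference matrix, centering statistics, dual
weights, orthogonal components, centroids, score precisions), the
preprocessing statistics and the discretization scheme as an ordered list
(the variable order fixes the code-matrix column order).  SVM nodes store
their training data and hyperparameters and are refitted deterministically
on load, since their solver state is not portably serializable as plain
arrays.  Every CLI invocation writes a manifest with the config snapshot,
seed and SHA-256 digests of inputs and outputs; a single master seed drives
all stochastic stages through named substreams (per-region generator
streams, per-iteration split seeds).

## Known limitations

* Identity within-region correlation is an assumption, flagged as such;
  published information does not constrain it.
* The supercluster tree is re-derived from data; it will generally not
  match the grouping found on the authentic collection.
* No variable selection is implemented (deliberately out of scope), no
  terminal coordinate regression, and no cartographic rendering or border
  masking for surfaces.
* Region bounding boxes are coarse illustrations; kriging demonstrations
  on synthetic coordinates say nothing about real spatial structure.
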