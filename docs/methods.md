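# Methods

## The model

`metstab` analyses balanced multi-environment trials (METs): *g*
genotypes grown in *e* environments (location × year combinations) in
a randomized complete block design with *r* replicates.  The working
model for a plot value is

    Y_ger = mu + alpha_g + beta_e + sum_n lambda_n gamma_gn delta_en
            + b_r(e) + eps_ger

where `mu` is the grand mean, `alpha_g` and `beta_e` the genotype and
environment main effects, the multiplicative sum is the
genotype-by-environment interaction (GEI) written as an SVD of the
double-centered cell-means matrix, `b_r(e)` a block effect nested in
environment, and `eps` the plot residual.  All effects are treated as
fixed; no BLUP/mixed-model shrinkage is applied anywhere (the WAAS
statistic below is therefore the fixed-effect variant).

### Joint ANOVA

Sums of squares are computed on the plot scale with the usual balanced
decomposition: ENV (df e−1), REP(ENV) (e(r−1)), GEN (g−1), GEN:ENV
((g−1)(e−1)), Residuals (e(g−1)(r−1)).  F(ENV) is tested against the
REP(ENV) mean square (blocks are the replication unit for
environments); GEN and GEN:ENV against the pooled residual.  The
"share" statistics quoted throughout (`ss_proportions`) divide each of
SS(ENV), SS(GEN), SS(GEN:ENV) by their three-way sum — block and
residual SS are deliberately excluded from the denominator.

### AMMI decomposition

The interaction is the SVD of the double-centered means matrix; axis
*k* carries plot-scale SS `r·lambda_k²`, so the axes sum exactly to
SS(GEN:ENV).  Approximate per-axis F-tests use Gollob degrees of
freedom `g + e − 1 − 2k` against the pooled residual MS, unadjusted
for multiplicity, with significance threshold 0.05 by default.  Scores
are `lambda^alpha`-scaled with `alpha = 0.5` (symmetric) by default;
any exponent can be requested.  Axis signs are fixed by making the
largest-magnitude environment loading of each axis positive, so
results are reproducible across SVD backends; every downstream
statistic is invariant to sign flips anyway (tested).  A means-only
mode (a bare `GEMatrix`, r = 1) fits the decomposition without
F-tests, which is how the hand-sized worked examples are checked.

### GGE biplots

The GGE model centers columns by environment means only (genotype main
effect retained), optionally scaling by the environment standard
deviation.  Default preprocessing is centering without scaling — the
most common GGE form; the sd-scaled variant is one flag away.
Singular-value partitioning is symmetric for the which–won–where view
and genotype-focused for mean-vs-stability/ranking, the standard
choice for each view.  Which–won–where takes the convex hull of the
rank-2 genotype markers; the winner of an environment is the hull
vertex maximizing the inner product with the environment marker,
which equals the genotype with the highest rank-2 modeled value there
(verified against exhaustive argmax in the tests).  Environments
falling exactly on a sector boundary go to the lower-indexed sector.
The average-environment axis (AEA) is the direction of the mean
environment marker; projections on it estimate mean performance,
signed perpendicular distances estimate instability, and genotypes are
ranked by distance to the "ideal" point (on the AEA at the maximum
projection).  The biplot is strictly 2-D.

### Stability indices

Computed on the g×e cell-means matrix (W ≡ ecovalence, dc ≡
double-centered residual, e.g. `dc_ie`):

* `Ecoval`  W_i = Σ_e dc_ie²  (Wricke).
* `Shukla`  σ²_i = g·W_i/((g−2)(e−1)) − ΣW/((g−1)(g−2)(e−1)).
* `bi`, `Sij`  Eberhart–Russell joint regression of genotype values on
  the environmental index (env mean − grand mean); `Sij` is the
  deviation mean square with e−2 df.  The slope mean is identically 1.
* `Wi_g/Wi_f/Wi_u`  Annicchiarico reliability: mean of
  percent-of-environment-mean minus z·sd (sample sd, ddof = 1), with
  one-sided 75 % confidence (z ≈ 0.6745, configurable), over all /
  favorable / unfavorable environments.  Favorability splits at the
  grand mean (ties unfavorable).
* `Pi_a/Pi_f/Pi_u`  Lin & Binns superiority: Σ (x_ie − M_e)²/(2n) with
  M_e the environment maximum, over the same three subsets.
* `S2x`, `CV`, `Gai`  environmental variance (ddof = 1), coefficient
  of variation, geometric adaptability index (geometric mean;
  requires strictly positive yields).
* `Tai_alpha`, `Tai_lambda`  the interaction is regressed on the
  environmental index: alpha_i is the regression coefficient
  (equals b_i − 1), lambda_i the deviation mean square divided by the
  error variance of a cell mean (pooled residual MS / r) with e−2 df.
  The literature prints small variants of these denominators; this
  formulation keeps E[lambda] ≈ 1 for an average-stable genotype and
  is documented here as the package's convention.  Requires r ≥ 2.
* `Theta`, `ThetaPrime`  Plaisted–Peterson mean variance component and
  Plaisted's GE variance component.  Both follow from the exact
  identity that deleting genotype i and re-centering leaves
  interaction SS  ΣW − g·W_i/(g−1):
  `Theta_i = (ΣW + g·W_i)/(4(g−1)(e−1))` (pairwise mean form) and
  `ThetaPrime_i = (ΣW − g·W_i/(g−1))/((g−2)(e−1))`.  Both are linear
  in W_i, so their rankings coincide with (or mirror) ecovalence.
* `S1/S2/S3/S6`  Huehn's nonparametric statistics from
  within-environment ranks (average ranks on ties): S1 = mean absolute
  pairwise rank difference, S2 = rank variance; S3 and S6 (relative
  deviation sums) use ranks of the genotype-effect-corrected values
  `x_ie − x̄_i + x̄`, per Huehn's original definitions.  S1/S2 stay on
  raw ranks.
* `N1`  Thennarasu: mean absolute deviation from the median rank, on
  uncorrected ranks.
* `WAAS`  weighted average of the absolute IPCA scores, weights equal
  to each axis's share of interaction SS; by default only axes
  significant at 0.05 (Gollob) are retained, with `all` or an explicit
  count available.  Low WAAS = stable.

Ranking (`rank_table`): stability statistics rank ascending (small =
stable, rank 1 best); mean yield, GAI, the Annicchiarico reliability
columns and ThetaPrime rank descending (large = good); the joint-
regression slope ranks by |b_i − 1| and Tai's alpha by |alpha|.  Ties
get average ranks, so every rank column sums to g(g+1)/2.

GY × WAAS quadrants split at the grand mean (x) and mean WAAS (y):
I low-yield/unstable, II high-yield/unstable, III low-yield/stable,
IV high-yield/stable.  Boundary points fall to the lower-yield /
higher-WAAS side, a deterministic tie rule.

### Clustering of rank profiles

Genotypes are clustered on their rank vectors (all `*_R` columns) with
squared Euclidean distance and Ward's minimum-variance criterion
applied directly to the squared distances — the classical Ward
formulation.  The Lance–Williams recurrence is implemented in the
package so that merge heights stay on the squared-distance scale and
exact ties merge the smallest (i, j) node pair; the heights equal the
square of scipy's Euclidean-scale Ward heights (cross-checked in the
tests).  Ward on unsquared distances is available by flag.  The number
of groups k is user-supplied (default 8); no automatic selection is
attempted.  Dendrograms export to Newick with branch lengths taken as
height differences between a node's merge and its children's.

### Correlations

Spearman rank correlations among yield and the secondary traits
(panicle length, panicles per plant, thousand-grain weight, sterility
%), pooled over all plot-level records by default — which mixes
between- and within-environment variation, exactly as a naive pooled
analysis does — with a per-environment mode for the partitioned view.
p-values use the t approximation with n−2 df, starred at
0.05/0.01/0.001, unadjusted.

## The synthetic generator

`simulate_met` is the package's test bed and the definition of the
study conditions.  Defaults: g=34, e=8, r=3; three-way SS fractions
(E, G, GEI) = (0.7129, 0.1477, 0.1394); interaction of rank 4 with
axis weights (0.889, 0.079, 0.022, 0.010); pattern RMS per plot
`effect_sd` = 235 g m⁻²; `noise_sd` = 22 g m⁻²; `block_sd` =
3.4 g m⁻²; grand mean 700 g m⁻².  The fractions and axis weights are
the variance structure of the rice trial this toolchain reproduces;
the absolute scales are back-calculated from its printed mean squares
(pattern RMS = sqrt(three-way SS / plots) ≈ 235; residual sd =
sqrt(487) ≈ 22; block variance component (830 − 487)/34 → sd ≈ 3.4),
and the grand mean is a realistic paddy-rice figure chosen once, since
it is not printed anywhere.

Main effects are drawn normal, centered and then *exactly* rescaled to
hit the target SS fractions; the interaction is built from orthonormal
axis pairs drawn in the centered subspace (QR with deterministic
signs), with singular values set from the axis weights.  The draw is
therefore not distribution-faithful in the tails — the realized SS
split is exact by construction rather than in expectation — which is
what makes tight recovery tests possible.  Block effects are centered
within each environment, so cell means (and everything downstream of
them) are provably unaffected by `block_sd`; blocks feed only the
REP(ENV) stratum.  Yields are physical, so a draw that pushes any plot
negative is rejected and redrawn from the next deterministic
substream (exactness is preserved because the rescaling happens within
each attempt).  A single integer seed drives per-component substreams;
identical seeds give bit-identical datasets.

With noise present, the realized shares drift from the configured ones
because residual noise leaks into every stratum: for pure noise the
expected three-way shares are proportional to the stratum degrees of
freedom (7 : 33 : 231 at the default design), not equal thirds.  At the
default signal-to-noise this drift is a fraction of a percentage
point, and the recovery tests band it at ±2 points (ENV share) and
±3 points (PC1 share) over 20 seeds.

Secondary traits use a Gaussian copula on the yield ranks: the latent
normal correlation is `a = 2·sin(pi·rho/6)` for a target Spearman
`rho`, so |rho| = 1 reproduces exactly and intermediate targets are
met up to Monte-Carlo error (±0.05 at n = 816 over 20 seeds in the
acceptance suite).  Default targets: PL 0.825, NPP 0.904, TG 0.491,
ST −0.6.

What the generator does *not* emulate: unbalanced or incomplete
designs, spatial field trends, non-Gaussian plot errors, crossover-
specific interaction patterns, or climate covariates.  Passing tests
therefore demonstrate correctness of the estimators under the assumed
balanced fixed-effect model, not robustness to real-world messiness.

## Numerical choices and degenerate inputs

* Double-centering and marginal-mean identities are held to 1e-9;
  axis-SS conservation to 1e-6 relative; zero-noise recovery to 1e-6.
* Zero interaction: the AMMI model reports all-zero singular values
  with axis proportions defined as 0; WAAS is identically zero.
* r = 1 data have no residual: the joint ANOVA refuses to run,
  the decomposition still fits (means-only mode), F-tests and Tai
  columns are NA.
* A zero-variance environment cannot be sd-scaled (error naming it);
  an empty favorable/unfavorable subset turns the affected Wi/Pi
  columns NA with a warning; GAI demands strictly positive yields.
* Rank ties anywhere use average ranks; the ideal-genotype ranking
  breaks exact distance ties by stable input order.
* Missing plots/cells are rejected by default; `impute=True` fills a
  missing plot with the remaining-rep cell mean and a missing cell
  with mu + alpha + beta, loudly, because silent imputation hides
  design failures.
* Environment identity is the composite label supplied in the input
  (e.g. location × year as E1…E8); it is never inferred.  Yield units
  are carried as g m⁻² metadata only.

## Qualitative expectations not encoded as tests

Several headline findings of the motivating rice trial depend on its
raw plot data, which is not redistributable here; they are recorded as
qualitative expectations a user should see on comparable data, not as
unit tests: the which-won-where view splitting the eight environments
into two sectors with distinct winning genotypes; one broadly adapted
high-yield genotype sitting near the biplot origin and winning the
mean-vs-stability ranking; and the two-main-cluster / several-
subcluster structure of the rank-profile dendrogram.  On synthetic
data the corresponding *structural* properties (sector winners equal
rank-2 argmax, ranking invariances, cluster recovery of planted
groups) are all asserted.

## Problem sizes

All tests run on desk-scale problems: the 3×3 hand example, 6×4 random
matrices for geometry (200 draws), 10×4×3 smoke datasets, and the
34×8×3 design for the recovery suite (20 seeds).  These sizes were
chosen to keep the full suite in the tens of seconds while still
exercising the trial-scale design; every algorithm is O(g·e) to
O(g³) and comfortably handles far larger METs.
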