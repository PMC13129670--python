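# Methods

## Data model and encoding

An MRD measurement is one of three assay outcomes: a quantified tumor-cell
ratio in (0, 1] (QUANT), detected-but-below-quantifiable-range (PNQ), or
undetected (NEG). All modelling happens on a single log10 scale:
QUANT → log10(ratio), PNQ → −6 (the conventional level of a
non-quantifiable positive), NEG → −7. The NEG floor sits one log below PNQ
so that negativity is distinguishable from low-level positivity yet stays
bounded; it is configurable (`neg_floor`), and the encoding is
order-preserving: NEG < PNQ < any quantified value above 10⁻⁶.

Protocol time-point labels map to months from the end of induction:
RCHOP = 0, ARAC = 3, ASCT = 6, and M6…M36 = 6 + k months (M6 → 12 …
M36 → 42). The source trial does not publish its exact sampling calendar,
so this table is an explicit, documented stand-in and every entry can be
overridden in config. The diagnostic (baseline) sample is not an MRD time
point and is dropped on read. Duplicate times within one series keep the
worse (higher) value — a conservative clinical reading — with a warning.
A patient measured in both tissues contributes two independent
trajectories; tissues are only joined in the concordance report.

## Functional clustering model

Encoded series are sparse, irregular samples of latent smooth curves.
With a natural cubic spline basis of dimension `p` (knots at quantiles of
the pooled observation times; natural splines extrapolate linearly, which
keeps late-follow-up behavior tame):

    y_i = S_i (lambda0 + Lambda alpha_{z_i} + gamma_i) + eps_i
    gamma_i ~ N(0, Gamma),  eps_i ~ N(0, sigma2 I),  P(z_i = k) = pi_k

Marginally `y_i | z_i=k ~ N(S_i eta_k, S_i Gamma S_i' + sigma2 I)` with
`eta_k = lambda0 + Lambda alpha_k`. The two variance scales separate
subject-level curve idiosyncrasy (`Gamma`, a full p×p covariance in
coefficient space) from assay noise (`sigma2`).

**Estimation.** EM with the cluster labels as missing data. Each M step
updates the priors, re-estimates the cluster mean coefficients by
cluster-weighted generalized least squares at the current variance
components, and then applies the conditional EM updates for `Gamma` and
`sigma2` (a generalized EM: each conditional step increases the expected
complete-data log-likelihood, so the observed-data log-likelihood is
non-decreasing — asserted with tolerance 1e-8 in the tests). Subjects
sharing an observation-time pattern share a marginal covariance, so the
implementation factorizes one Cholesky per pattern per iteration rather
than per subject.

**Identifiability.** `lambda0`, `Lambda`, `alpha` are only jointly
identified. After fitting, the cluster means are decomposed so that the
prior-weighted mean of `alpha` is zero and `Lambda` has orthonormal
columns (prior-weighted SVD of the centered means). With the default
`h = G−1` this decomposition is exact and changes nothing numerically;
when the user forces `h < G−1` the means are projected onto the rank-h
space inside the M step, which can break strict monotonicity — the
documented price of the extra constraint.

**Numerical floors.** `sigma2 >= 1e-8`; `Gamma` is projected onto the PSD
cone by eigenvalue clipping each update (the EM update is PSD in exact
arithmetic, so this is a guard); near-singular marginal covariances are
ridge-stabilized with a logged jitter. Convergence: relative
log-likelihood change < 1e-6 or 500 iterations. Membership ties in the
hard assignment go to the lowest cluster index.

**Initialization.** Multi-start k-means on the raw observations
interpolated onto a common time grid (flat extension outside each
subject's range), with `Gamma` seeded from the *within*-cluster covariance
of per-subject ridge spline coefficients and `sigma2` from their
residuals. Two alternatives were evaluated and rejected on synthetic
cohorts: k-means directly on ridge-projected spline coefficients (sparse
3-point subjects extrapolate wildly, producing merged-cluster local optima
with a log-likelihood ~100 units below the truth-initialized fit) and a
total-covariance `Gamma` start (the random effect absorbs the cluster
structure before EM can separate it). Each of the `n_starts` (default 10)
starts runs a 40-iteration burn-in; the best by log-likelihood is refined
to convergence. A start that collapses a cluster below prior 1/(10n) is
restarted once and flagged.

## Model selection

- **Spline dimension p**: maximizes a leave-subjects-out cross-validated
  log-likelihood of the single-cluster mixed model (folds split subjects,
  never observations).
- **Cluster count G**: minimizes the functional Davies–Bouldin (fDB)
  index over repeated fits, `(1/G) Σ_k max_{j≠k} (S_k+S_j)/M_kj`, where
  `S_k` is the mean L2 distance of cluster-k reconstructed curves to their
  mean curve and `M_kj` the L2 distance between mean curves, both on a
  fixed 200-point grid over the observed range (deterministic given a
  fit). Identical mean curves give +infinity.
- **G = 1 versus G ≥ 2**: the fDB index is undefined for one cluster, and
  an absolute fDB threshold proved structurally unreliable (BLUP shrinkage
  makes within-cluster dispersion, hence fDB, small even for a homogeneous
  cohort). The adopted convention compares the fDB-minimizing mixture
  against the single-cluster fit by BIC; one cluster is declared when the
  mixture does not pay for its extra parameters.
- **Mean-space dimension h** = min(rule, G−1); ties in any selection break
  to the smaller value (parsimony).

## Classification and uncertainty

A new series is scored by its posterior memberships under the frozen
model; its curve is reconstructed as the membership-weighted BLUP.
Confidence is the Shannon entropy of the membership vector **in bits** —
with four clusters the range is [0, 2], which is what makes a "greater
than one" entropy gate meaningful. A series is UNCLASSIFIED only when
*both* gates fail: maximal membership < 0.6 *and* entropy > 1 bit
(conjunction; a disjunctive variant is available for sensitivity
analyses). Landmark truncation keeps measurements with time ≤ L (closed
interval), is idempotent and monotone in L.

## Survival post-processing

Kaplan–Meier estimation, the K-group log-rank test and the univariate Cox
model are delegated to `lifelines`; the median is read off the step
function as the first time survival falls *strictly below* 0.5
(NOT_REACHED when it never does), and the Cox CI is Wald on the log-hazard
scale. Clusters merge into FAVORABLE/UNFAVORABLE via an explicit total
mapping. Landmark analysis at landmarks L: truncate to data ≤ L, drop
patients with progression/censoring ≤ L, classify survivors, measure
survival from L; fewer than two classifiable groups marks the landmark
non-evaluable rather than failing. The time origin is treatment start for
cohort-level curves and the landmark itself for landmark curves.

## Synthetic cohort generator

The generator *is* the study design the workflow assumes, not a tuning
surface. Defaults, chosen once:

- **Four kinetic archetypes** with piecewise-linear latent mean profiles:
  stable-negative (51%), late-negativization (21%), fluctuating (15%),
  transient-negativization with reappearance (13%) — the proportion mix of
  kinetic behaviors observed in treated mantle cell lymphoma cohorts.
- **Hazards**: exponential time to progression, baseline 0.006/month,
  multipliers (1, 1, 4, 4) so the merged unfavorable group carries a
  four-fold hazard (unfavorable median TTP ≈ 29 months); administrative
  censoring at 72 months.
- **Sampling**: the 9 protocol visits with attendance 0.94 for the three
  restaging visits and 0.675 during maintenance/follow-up, matching
  reported collection compliance; subjects end up with a median of ~7 and
  a range of 3–9 points after the minimum-3 filter.
- **Noise**: subject random effects spanned by the fitting spline space,
  scaled so the per-visit effect sd is `gamma_scale = 0.3`, plus
  measurement noise `sigma = 0.35` log10 — together ≈ 0.46 log10 per
  visit, a realistic quantitative-PCR variability, and a ≈3:1 minimum
  separation-to-noise ratio between archetype mean profiles.
  `scale_to_separation()` rescales both noise terms to hit a stated ratio
  exactly where an experiment specifies one.
- **Censoring**: latent values ≤ −6 become PNQ, ≤ −6.5 become NEG, exactly
  as the assay would report them.

What the generator does *not* emulate: assay-specific quantification error
models, visit-time jitter around the protocol calendar, informative
missingness (attendance independent of disease state), treatment-arm
effects, and competing risks. Passing recovery tests therefore show the
estimator works when the model's assumptions hold at realistic sparsity
and noise — not that real cohorts satisfy those assumptions.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on 15–80-subject cohorts; the label-recovery
check uses 20 seeds of 120 subjects at the 3:1 separation condition with 3
EM starts; hazard-ratio recovery uses 20 seeds of 500 subjects. The
acceptance script analyzes one 120-subject training cohort, a 100-subject
validation cohort and a 120-subject second-tissue cohort, with model
selection over G ∈ {1,…,5}. These sizes mirror the cohort scale the
workflow targets (~100 trajectories, 3–9 points each).

## Known limitations

- The EM can need several hundred iterations near convergence; the
  burn-in/refine multi-start mitigates but does not remove this.
- A forced `h < G−1` trades likelihood monotonicity for interpretability
  of a low-dimensional mean space.
- Entropy gating calibrates confidence only relative to the fitted model;
  a mis-specified model can be confidently wrong.
- PNQ/NEG values enter as fixed levels (−6/−7) rather than censored
  likelihood contributions; with heavy negativization this compresses
  late-time separation between durably negative kinetics.
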