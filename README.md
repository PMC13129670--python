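# mrdflow

Functional clustering and survival stratification of longitudinal minimal
residual disease (MRD) trajectories.

## The problem

MRD — the small residual tumor burden measured molecularly during and after
therapy — is one of the strongest prognostic markers in hematologic
malignancies such as mantle cell lymphoma. In practice MRD arrives as a
sparse, irregular series per patient and tissue (bone marrow or peripheral
blood): a quantified log-scale tumor-cell ratio when the assay can measure
it, *positive not quantifiable* (PNQ) when disease is detected below the
quantifiable range, or *negative* (NEG). Single time points predict poorly;
the *kinetics* of the whole series — rapid and stable negativization versus
fluctuating or reappearing disease — carry the signal. `mrdflow` turns raw
MRD tables into that kinetic stratification:

1. **Pre-processing** — status encoding to a common log10 scale
   (QUANT → log10 ratio, PNQ → −6, NEG → −7), protocol time-point mapping,
   minimum-time-point filtering, cohort I/O.
2. **Predictive model definition** — model-based functional clustering of
   the trajectories by EM, with data-driven selection of the spline
   dimension and cluster count.
3. **Model abstraction** — classification of never-before-seen series
   against the frozen model, with Shannon-entropy-gated uncertainty and an
   UNCLASSIFIED verdict when confidence is insufficient.
4. **Post-processing** — Kaplan–Meier, log-rank and Cox analyses of the
   merged favorable/unfavorable kinetic groups, cross-tissue concordance,
   and leak-free landmark analysis.

## The model

Patient *i*'s encoded series $y_i \in \mathbb{R}^{n_i}$, observed at times
$t_i$, is modeled as a noisy draw from a Gaussian mixture over smooth latent
curves represented in a natural cubic spline basis with design matrix
$S_i$ ($n_i \times p$, knots at quantiles of the pooled times):

$$ y_i = S_i(\lambda_0 + \Lambda\,\alpha_{z_i} + \gamma_i) + \varepsilon_i,
   \qquad \gamma_i \sim N(0, \Gamma), \quad
   \varepsilon_i \sim N(0, \sigma^2 I), $$

where $z_i$ is the latent cluster label with priors $\pi_k$,
$\lambda_0$ the grand-mean coefficients, $\Lambda$ ($p \times h$,
$h \le G-1$) the mean-space directions with cluster scores $\alpha_k$, and
$\gamma_i$ a subject-level random effect. Marginally
$y_i \mid z_i{=}k \sim N(S_i\eta_k,\; S_i\Gamma S_i^\top + \sigma^2 I)$ with
$\eta_k = \lambda_0 + \Lambda\alpha_k$. EM treats $z_i$ as missing; the
observed-data log-likelihood is non-decreasing by construction and tested.
Posterior memberships give each patient a soft cluster assignment, a
best-linear-unbiased-prediction reconstruction of the full curve at any
time, and discriminant curves $\Sigma_T^{-1} S_T \Lambda$ whose magnitude
marks the time windows most informative for assignment. Assignment
uncertainty is the Shannon entropy of the membership vector (bits); cluster
count is selected by the functional Davies–Bouldin index.

## Worked example

`examples/` holds one narrative script per capability. Running
`python examples/04_survival_stratification.py` simulates a 120-subject
cohort with four kinetic archetypes and a 4× progression hazard for the
unfavorable ones, fits the 4-cluster model, merges clusters into prognostic
groups, and prints:

```
FAVORABLE    n= 87 events= 30 median TTP: not reached
UNFAVORABLE  n= 33 events= 23 median TTP: 37 months

log-rank chi-square 14.1, p = 0.00017
hazard ratio (unfavorable vs favorable) 2.74 (95% CI 1.59-4.74)
```

The favorable group never reaches median time to progression, the
unfavorable group does at 37 months, and the Cox confidence interval
brackets the simulated hazard ratio. `examples/02_fit_clusters.py` shows
perfect label recovery (adjusted Rand index 1.0) on the same generator,
and `examples/05_landmark_analysis.py` shows the log-rank p-value of the
landmark classification falling from 5×10⁻² at month 12 to 1×10⁻⁵ at
month 30 as more of each series becomes available.

## Command line

```bash
mrdflow simulate --n-subjects 120 --seed 1 --out data/
mrdflow fit data/measurements.csv -G 4 --model-out model.json
mrdflow classify model.json new_measurements.csv --out classification.csv
mrdflow survival classification.csv data/clinical.csv
mrdflow landmark model.json data/measurements.csv data/clinical.csv
mrdflow run config.yml          # all phases from one YAML config
```

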