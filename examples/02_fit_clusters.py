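"""Fit the functional clustering model and inspect the fitted kinetics.

Each patient's sparse log10 MRD series is modeled as a noisy observation of
a smooth latent curve drawn from a Gaussian mixture over natural-spline
coefficients; EM estimates the cluster mean curves, the subject-level
random-effect covariance and the posterior memberships.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import mrdflow as m

specs = m.default_archetypes()
config = m.default_config(n_subjects=100, seed=1)
cohort, labels = m.generate_cohort(specs, config)
cohort = m.filter_cohort(cohort, min_timepoints=3)

fit = m.fit_fcm(cohort, G=4, p=5, n_starts=5, seed=1)
print(f"converged: {fit.converged} after {len(fit.loglik_trace)} EM iterations")
print(f"final log-likelihood: {fit.loglik:.1f}")
print(f"cluster sizes: {np.bincount(fit.assignments, minlength=4).tolist()}")
print(f"fDB cluster-validity index: {m.fdb_index(fit, cohort):.3f} (lower = "
      "tighter, better-separated clusters)")

keep = [int(t.patient_id[1:]) - 1 for t in cohort.trajectories]
ari = adjusted_rand_score(np.asarray(labels)[keep], fit.assignments)
print(f"adjusted Rand index vs simulated truth: {ari:.3f} (1.0 = perfect recovery)")

months = np.array([0.0, 6.0, 18.0, 30.0, 42.0])
print("\ncluster mean curves (log10 MRD):")
print("  month:  " + "".join(f"{t:8.0f}" for t in months))
for k, row in enumerate(fit.model.mean_curves(months)):
    print(f"  cluster {k}: " + "".join(f"{v:8.2f}" for v in row))

D = np.abs(m.discriminant_functions(fit.model, np.linspace(0, 42, 200)))
peak = np.linspace(0, 42, 200)[D[:, 0].argmax()]
print(f"\nleading discriminant curve peaks at month {peak:.0f}: measurements "
      "near that visit carry the most information for cluster assignment.")
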