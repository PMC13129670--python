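"""Merge the fitted MRD clusters into favorable vs unfavorable kinetics and
quantify the prognostic separation.

Clusters with rapid, durable negativization form the favorable group;
persistent or fluctuating kinetics form the unfavorable group.  The groups
are compared on time to progression (TTP) with Kaplan-Meier curves, the
log-rank test and a univariate Cox model.
"""

import numpy as np

import mrdflow as m

specs = m.default_archetypes()
config = m.default_config(n_subjects=120, seed=3)
cohort, labels = m.generate_cohort(specs, config)
cohort.clinical = m.generate_survival(labels, specs, config)
cohort = m.filter_cohort(cohort, 3)

fit = m.fit_fcm(cohort, G=4, p=5, n_starts=5, seed=3)

# map each fitted cluster to a prognostic group by its dominant archetype
truth = np.asarray(labels)[[int(t.patient_id[1:]) - 1 for t in cohort.trajectories]]
merge = m.GroupMerge({
    k: (m.FAVORABLE if np.bincount(truth[fit.assignments == k], minlength=4).argmax() < 2
        else m.UNFAVORABLE)
    for k in range(4)
})

records = [
    m.SurvivalRecord(t.patient_id, cohort.clinical[t.patient_id].ttp_months,
                     cohort.clinical[t.patient_id].event, merge(int(k)))
    for t, k in zip(cohort.trajectories, fit.assignments)
]
for group in (m.FAVORABLE, m.UNFAVORABLE):
    km = m.km_estimate([r for r in records if r.group == group])
    med = "not reached" if km.median == m.NOT_REACHED else f"{km.median:.0f} months"
    print(f"{group:<12s} n={km.n:3d} events={km.n_events:3d} median TTP: {med}")

stat, p = m.logrank_test(records)
hr, ci, _ = m.cox_hr(records, reference=m.FAVORABLE)
print(f"\nlog-rank chi-square {stat:.1f}, p = {p:.2g}")
print(f"hazard ratio (unfavorable vs favorable) {hr:.2f} "
      f"(95% CI {ci[0]:.2f}-{ci[1]:.2f})")
print("\nthe unfavorable kinetic group progresses several-fold faster; the "
      "confidence interval brackets the simulated 4x hazard.")
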