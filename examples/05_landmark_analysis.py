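"""Landmark analysis: how early can MRD kinetics stratify patients?

At each landmark time L the trajectories are truncated to measurements at
or before L, patients who progressed by L are removed from the risk set,
the survivors are re-classified with the truncated data only, and survival
is measured from L.  By construction no post-landmark measurement can leak
into a landmark classification.
"""

import numpy as np

import mrdflow as m

specs = m.default_archetypes()
train, tl = m.generate_cohort(specs, m.default_config(n_subjects=100, seed=4))
train = m.filter_cohort(train, 3)
fit = m.fit_fcm(train, G=4, p=5, n_starts=5, seed=4)

truth = np.asarray(tl)[[int(t.patient_id[1:]) - 1 for t in train.trajectories]]
merge = m.GroupMerge({
    k: (m.FAVORABLE if np.bincount(truth[fit.assignments == k], minlength=4).argmax() < 2
        else m.UNFAVORABLE)
    for k in range(4)
})

vconfig = m.default_config(n_subjects=120, seed=40)
val, vl = m.generate_cohort(specs, vconfig)
val.clinical = m.generate_survival(vl, specs, vconfig)
val = m.filter_cohort(val, 3)

print("landmark  classified  assigned  log-rank p")
for res in m.landmark_analysis(fit.model, val, [12.0, 18.0, 24.0, 30.0],
                               min_timepoints=3, merge=merge):
    if res.evaluable:
        print(f"  M{res.landmark:<6.0f} {len(res.labels):5d} "
              f"{len(res.records):10d}  {res.logrank_p:10.2e}")
    else:
        print(f"  M{res.landmark:<6.0f} not evaluable ({res.reason})")

print("\nsmall p-values mean the kinetic groups, built from pre-landmark "
      "data only, already separate subsequent progression risk.")
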