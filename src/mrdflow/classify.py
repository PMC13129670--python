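"""Classification of new MRD trajectories against a frozen fitted model.

A never-before-seen patient series is scored by its posterior cluster
memberships under the fitted functional model.  Assignment confidence is
quantified by the Shannon entropy of that membership distribution, in bits:
with G clusters the entropy ranges from 0 (certain) to log2 G.  A series is
left UNCLASSIFIED only when both confidence gates fail — the maximal
membership probability is below the cut-off (default 0.6) AND the entropy
exceeds the threshold (default 1 bit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clustering import FcmModel, posterior_membership, predict_curve
from .data import MrdTrajectory

__all__ = [
    "UNCLASSIFIED",
    "ClassificationResult",
    "shannon_entropy",
    "unclassified_rule",
    "classify",
    "classify_cohort",
    "entropy_vs_length_table",
    "truncate_trajectory",
]

UNCLASSIFIED = "UNCLASSIFIED"

#: default maximal-probability cut-off of the unclassified rule
DEFAULT_CUTOFF = 0.6
#: default entropy gate in bits
DEFAULT_ENTROPY_MAX = 1.0


def shannon_entropy(probs) -> float:
    """Shannon entropy of a probability vector, in bits (0 log 0 = 0)."""
    p = np.asarray(probs, dtype=float)
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"not a probability vector (sum {p.sum():.12g})")
    p = np.clip(p, 0.0, None)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def unclassified_rule(
    probs,
    cutoff: float = DEFAULT_CUTOFF,
    entropy_max: float = DEFAULT_ENTROPY_MAX,
    require_both: bool = True,
) -> bool:
    """The unclassified gate on a membership vector: True when the maximal
    probability is below ``cutoff`` AND the entropy exceeds ``entropy_max``
    bits (conjunction of both conditions; set ``require_both=False`` for
    the disjunctive sensitivity variant)."""
    p = np.asarray(probs, dtype=float)
    low_conf = float(p.max()) < cutoff
    high_ent = shannon_entropy(p) > entropy_max
    return (low_conf and high_ent) if require_both else (low_conf or high_ent)


@dataclass(frozen=True)
class ClassificationResult:
    """Memberships, entropy, label-or-UNCLASSIFIED and reconstructed curve."""

    patient_id: str
    memberships: np.ndarray
    entropy_bits: float
    label: int | str           # cluster index or UNCLASSIFIED
    n_timepoints: int
    curve_times: Optional[np.ndarray] = None
    curve_values: Optional[np.ndarray] = None

    @property
    def assigned(self) -> bool:
        return self.label != UNCLASSIFIED


def classify(
    model: FcmModel,
    trajectory: MrdTrajectory,
    cutoff: float = DEFAULT_CUTOFF,
    entropy_max: float = DEFAULT_ENTROPY_MAX,
    curve_grid=None,
    require_both: bool = True,
) -> ClassificationResult:
    """Classify one trajectory against a frozen fitted model.

    The series is UNCLASSIFIED iff (i) its maximal membership probability is
    below ``cutoff`` and (ii) its entropy exceeds ``entropy_max`` bits
    (conjunction; set ``require_both=False`` for the disjunctive variant in
    sensitivity analyses).  Otherwise the label is the argmax cluster
    (lowest index on ties).
    """
    w = posterior_membership(model, trajectory)
    ent = shannon_entropy(w)
    rejected = unclassified_rule(w, cutoff, entropy_max, require_both)
    label: int | str = UNCLASSIFIED if rejected else int(np.argmax(w))
    times = values = None
    if curve_grid is not None:
        times = np.atleast_1d(np.asarray(curve_grid, dtype=float))
        values = predict_curve(model, trajectory, times, memberships=w)
    return ClassificationResult(
        patient_id=trajectory.patient_id,
        memberships=w,
        entropy_bits=ent,
        label=label,
        n_timepoints=len(trajectory),
        curve_times=times,
        curve_values=values,
    )


def classify_cohort(
    model: FcmModel,
    trajectories: Sequence[MrdTrajectory],
    cutoff: float = DEFAULT_CUTOFF,
    entropy_max: float = DEFAULT_ENTROPY_MAX,
    min_timepoints: int = 1,
    curve_grid=None,
) -> list[ClassificationResult]:
    """Classify every trajectory meeting the minimum-timepoint rule."""
    return [
        classify(model, t, cutoff=cutoff, entropy_max=entropy_max, curve_grid=curve_grid)
        for t in trajectories
        if len(t) >= min_timepoints
    ]


def entropy_vs_length_table(
    results: Sequence[ClassificationResult], split_at: int = 6
) -> tuple[pd.DataFrame, dict]:
    """Per-subject (n_timepoints, entropy) table plus a short/long summary.

    Assignment uncertainty concentrates in short series, so the summary
    contrasts the median entropy of series with fewer than ``split_at``
    time points against the rest.
    """
    if not results:
        raise ValueError("no classification results")
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in results],
            "n_timepoints": [r.n_timepoints for r in results],
            "entropy_bits": [r.entropy_bits for r in results],
            "label": [r.label for r in results],
        }
    )
    short = df.loc[df["n_timepoints"] < split_at, "entropy_bits"]
    long = df.loc[df["n_timepoints"] >= split_at, "entropy_bits"]
    summary = {
        "median_entropy_short": float(short.median()) if len(short) else float("nan"),
        "median_entropy_long": float(long.median()) if len(long) else float("nan"),
        "n_short": int(len(short)),
        "n_long": int(len(long)),
        "split_at": split_at,
    }
    return df, summary


def truncate_trajectory(trajectory: MrdTrajectory, landmark: float) -> MrdTrajectory:
    """Keep exactly the measurements with time <= landmark (closed interval).

    Idempotent, and monotone: a larger landmark keeps a superset of points.
    """
    if landmark <= 0:
        raise ValueError("landmark must be positive")
    keep = trajectory.times <= landmark
    return MrdTrajectory(
        patient_id=trajectory.patient_id,
        tissue=trajectory.tissue,
        times=trajectory.times[keep],
        values=trajectory.values[keep],
        statuses=tuple(s for s, k in zip(trajectory.statuses, keep) if k)
        if trajectory.statuses
        else (),
        labels=tuple(l for l, k in zip(trajectory.labels, keep) if k)
        if trajectory.labels
        else (),
    )
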