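"""Survival post-processing: Kaplan-Meier, log-rank, Cox HR, landmarking.

The fitted MRD clusters become prognostic groups here.  Clusters are merged
into FAVORABLE (rapid, sustained negativization) vs UNFAVORABLE (persistent
or fluctuating MRD) kinetics, and the groups are compared on
time-to-progression with the product-limit estimator, the log-rank test and
a univariate Cox proportional-hazards model.  Landmark analysis re-runs the
classification using only data up to each landmark time, among patients
still event-free then, with survival measured from the landmark — so no
post-landmark information can leak into a landmark classification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .classify import UNCLASSIFIED, classify, truncate_trajectory
from .clustering import FcmModel
from .data import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "NOT_REACHED",
    "FAVORABLE",
    "UNFAVORABLE",
    "SurvivalRecord",
    "GroupMerge",
    "KmCurve",
    "km_estimate",
    "logrank_test",
    "cox_hr",
    "landmark_analysis",
    "concordance_table",
]

#: sentinel median when the survival curve never falls below 0.5
NOT_REACHED = math.inf

FAVORABLE = "FAVORABLE"
UNFAVORABLE = "UNFAVORABLE"


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float
    event: int
    group: str

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"survival time must be positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass(frozen=True)
class GroupMerge:
    """Total mapping cluster index -> merged prognostic group.

    The default merges the first two clusters (by convention the rapidly
    and durably negativizing kinetics) into FAVORABLE and the rest into
    UNFAVORABLE.
    """

    mapping: Mapping[int, str] = field(
        default_factory=lambda: {0: FAVORABLE, 1: FAVORABLE, 2: UNFAVORABLE, 3: UNFAVORABLE}
    )

    def __call__(self, cluster: int | str) -> str:
        if cluster == UNCLASSIFIED:
            return UNCLASSIFIED
        try:
            return self.mapping[int(cluster)]
        except KeyError:
            raise KeyError(f"cluster {cluster} missing from merge mapping") from None


@dataclass
class KmCurve:
    """Product-limit estimate: step function plus median."""

    times: np.ndarray
    survival: np.ndarray
    median: float              # NOT_REACHED when S never falls below 0.5
    n: int
    n_events: int

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: Sequence[SurvivalRecord]) -> KmCurve:
    """Kaplan-Meier estimate with the median read off the step function as
    the first time the estimated survival falls strictly below 0.5."""
    if not records:
        raise ValueError("no survival records")
    T = np.array([r.time for r in records])
    E = np.array([r.event for r in records])
    kmf = KaplanMeierFitter()
    kmf.fit(T, E)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    below = surv < 0.5
    median = float(times[below][0]) if below.any() else NOT_REACHED
    return KmCurve(times=times, survival=surv, median=median, n=len(records),
                   n_events=int(E.sum()))


def logrank_test(records: Sequence[SurvivalRecord]) -> tuple[float, float]:
    """K-group log-rank chi-square test across the record groups."""
    df = pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "group": [r.group for r in records],
        }
    )
    counts = df["group"].value_counts()
    empty = [g for g in counts.index if counts[g] == 0]
    if empty:
        logger.warning("excluding empty groups from log-rank: %s", empty)
    if counts.size < 2:
        raise ValueError("log-rank requires at least 2 nonempty groups")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_hr(
    records: Sequence[SurvivalRecord], reference: str
) -> tuple[float, tuple[float, float], float]:
    """Univariate Cox PH hazard ratio of the non-reference group versus
    ``reference``, with a Wald 95% CI on the log hazard scale.

    Returns (HR, (ci_low, ci_high), p_value).  A group without events
    yields a degenerate estimate and is flagged with a warning.
    """
    df = pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "exposed": [0 if r.group == reference else 1 for r in records],
        }
    )
    if df["exposed"].nunique() != 2:
        raise ValueError("cox_hr needs exactly two groups (reference vs other)")
    for g, sub in df.groupby("exposed"):
        if sub["event"].sum() == 0:
            logger.warning("group %s has no events: HR estimate is degenerate", g)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["exposed"])
    se = float(cph.standard_errors_["exposed"])
    hr = math.exp(beta)
    ci = (math.exp(beta - 1.959963984540054 * se), math.exp(beta + 1.959963984540054 * se))
    p = float(cph.summary.loc["exposed", "p"])
    return hr, ci, p


@dataclass
class LandmarkResult:
    landmark: float
    evaluable: bool
    records: list[SurvivalRecord]
    labels: dict[str, int | str]
    km: dict[str, KmCurve]
    logrank_p: Optional[float]
    reason: Optional[str] = None


def landmark_analysis(
    model: FcmModel,
    cohort: Cohort,
    landmarks: Sequence[float],
    min_timepoints: int = 3,
    merge: Optional[GroupMerge] = None,
    cutoff: float = 0.6,
    entropy_max: float = 1.0,
) -> list[LandmarkResult]:
    """Landmark re-classification and survival at each landmark time.

    At landmark L: trajectories are truncated to measurements at or before
    L, patients whose progression or censoring time is <= L are dropped
    from the risk set, survivors meeting the minimum-timepoint rule are
    classified, and KM/log-rank are computed on time measured from L.  Only
    data up to L ever reach the classifier, so the analysis is leak-free by
    construction.
    """
    if np.any(np.diff(np.asarray(landmarks, dtype=float)) <= 0):
        raise ValueError("landmarks must be strictly increasing")
    merge = merge or GroupMerge()
    out = []
    for L in landmarks:
        records: list[SurvivalRecord] = []
        labels: dict[str, int | str] = {}
        for traj in cohort.trajectories:
            clin = cohort.clinical.get(traj.patient_id)
            if clin is None or clin.ttp_months <= L:
                continue  # not event-free (or unobserved) at the landmark
            trunc = truncate_trajectory(traj, L)
            if len(trunc) < min_timepoints:
                continue
            res = classify(model, trunc, cutoff=cutoff, entropy_max=entropy_max)
            labels[traj.patient_id] = res.label
            if res.label == UNCLASSIFIED:
                continue
            records.append(
                SurvivalRecord(
                    patient_id=traj.patient_id,
                    time=clin.ttp_months - L,
                    event=clin.event,
                    group=merge(res.label),
                )
            )
        groups = {r.group for r in records}
        if len(groups) < 2:
            out.append(
                LandmarkResult(
                    landmark=float(L), evaluable=False, records=records,
                    labels=labels, km={}, logrank_p=None,
                    reason=f"{len(groups)} classifiable group(s) at landmark {L}",
                )
            )
            continue
        km = {
            g: km_estimate([r for r in records if r.group == g]) for g in sorted(groups)
        }
        _, p = logrank_test(records)
        out.append(
            LandmarkResult(
                landmark=float(L), evaluable=True, records=records,
                labels=labels, km=km, logrank_p=p,
            )
        )
    return out


def concordance_table(
    bm_labels: Mapping[str, int],
    pb_labels: Mapping[str, int],
    merge: Optional[GroupMerge] = None,
) -> tuple[float, pd.DataFrame]:
    """Cross-tissue cluster agreement for patients measured in both tissues.

    Returns the fraction of paired subjects whose merged (favorable vs
    unfavorable) groups agree, plus the full cluster-by-cluster transition
    counts (the chord-diagram table).
    """
    merge = merge or GroupMerge()
    paired = sorted(set(bm_labels) & set(pb_labels))
    if not paired:
        raise ValueError("no paired subjects between tissues")
    agree = sum(merge(bm_labels[p]) == merge(pb_labels[p]) for p in paired)
    clusters = sorted(
        {bm_labels[p] for p in paired} | {pb_labels[p] for p in paired},
        key=str,
    )
    counts = pd.DataFrame(0, index=clusters, columns=clusters)
    for pid in paired:
        counts.loc[bm_labels[pid], pb_labels[pid]] += 1
    counts.index.name = "BM"
    counts.columns.name = "PB"
    return agree / len(paired), counts
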