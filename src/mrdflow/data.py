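"""Domain types and I/O for longitudinal minimal residual disease (MRD) cohorts.

MRD is reported per sample as one of three statuses: a quantified tumor-cell
ratio (QUANT), detectable-but-below-quantifiable-range (PNQ, conventionally
10**-6), or undetectable (NEG).  All downstream modelling works on a single
log10 scale, so the three statuses are encoded to real numbers here in a way
that preserves the clinical ordering NEG < PNQ < any quantified value.

A cohort is a collection of per-patient, per-tissue trajectories (bone marrow
BM or peripheral blood PB) plus an optional clinical table with
time-to-progression outcomes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Tissue",
    "MrdStatus",
    "MrdMeasurement",
    "MrdTrajectory",
    "ClinicalRecord",
    "Cohort",
    "DEFAULT_SCHEDULE",
    "PNQ_LOG_LEVEL",
    "DEFAULT_NEG_FLOOR",
    "encode_mrd_value",
    "map_timepoint_to_months",
    "build_trajectories",
    "filter_cohort",
    "read_cohort",
    "write_cohort",
    "CohortParseError",
    "InvalidMeasurementError",
]


class Tissue(str, Enum):
    BM = "BM"
    PB = "PB"


class MrdStatus(str, Enum):
    QUANT = "QUANT"
    PNQ = "PNQ"
    NEG = "NEG"


#: log10 level assigned to a positive-not-quantifiable result (10**-6).
PNQ_LOG_LEVEL = -6.0
#: default log10 level assigned to a negative result; strictly below PNQ.
DEFAULT_NEG_FLOOR = -7.0

#: Protocol time-point -> months from the end of induction (R-CHOP).
#: The consolidation (high-dose ARA-C) and transplant (ASCT) samples are
#: placed 3 and 6 months after induction; maintenance/follow-up samples
#: M6..M36 fall k months after ASCT.  The exact trial calendar is not part
#: of the data dictionary, so the whole table is overridable in config.
DEFAULT_SCHEDULE: dict[str, float] = {
    "RCHOP": 0.0,
    "ARAC": 3.0,
    "ASCT": 6.0,
    "M6": 12.0,
    "M12": 18.0,
    "M18": 24.0,
    "M24": 30.0,
    "M30": 36.0,
    "M36": 42.0,
}

#: labels marking the diagnostic sample, which is not an MRD time point.
BASELINE_LABELS = frozenset({"BASELINE", "DIAGNOSIS", "DX"})


class CohortParseError(ValueError):
    """Raised when a cohort CSV violates the documented layout."""


class InvalidMeasurementError(ValueError):
    """Raised when a measurement's status and value are inconsistent."""


def encode_mrd_value(
    status: MrdStatus | str,
    quant_value: Optional[float] = None,
    neg_floor: float = DEFAULT_NEG_FLOOR,
) -> float:
    """Encode one MRD result to the common log10 scale.

    QUANT maps to log10(quant_value); PNQ to the conventional -6; NEG to
    ``neg_floor`` (default -7, one log below PNQ so negativity stays
    distinguishable yet bounded).

    Raises
    ------
    InvalidMeasurementError
        if a QUANT status comes without a value in (0, 1], or the floor is
        not strictly below the PNQ level.
    """
    status = MrdStatus(status)
    if neg_floor >= PNQ_LOG_LEVEL:
        raise InvalidMeasurementError(
            f"neg_floor must be strictly below the PNQ level {PNQ_LOG_LEVEL}, got {neg_floor}"
        )
    if status is MrdStatus.QUANT:
        if quant_value is None or not (0.0 < quant_value <= 1.0):
            raise InvalidMeasurementError(
                f"QUANT requires a tumor-cell ratio in (0, 1], got {quant_value!r}"
            )
        return float(np.log10(quant_value))
    if status is MrdStatus.PNQ:
        return PNQ_LOG_LEVEL
    return float(neg_floor)


def map_timepoint_to_months(
    label: str, schedule: Mapping[str, float] = DEFAULT_SCHEDULE
) -> float:
    """Resolve a protocol time-point label to months from treatment start."""
    try:
        return float(schedule[label])
    except KeyError:
        known = ", ".join(sorted(schedule))
        raise KeyError(
            f"unknown time-point label {label!r}; known labels: {known}"
        ) from None


@dataclass(frozen=True)
class MrdMeasurement:
    """One MRD sample of one patient in one tissue."""

    patient_id: str
    tissue: Tissue
    time_months: float
    status: MrdStatus
    quant_value: Optional[float] = None
    timepoint_label: Optional[str] = None
    neg_floor: float = DEFAULT_NEG_FLOOR

    def __post_init__(self) -> None:
        if self.time_months < 0:
            raise InvalidMeasurementError(
                f"time_months must be nonnegative, got {self.time_months}"
            )
        # validate eagerly so a bad row fails at construction, not at encode
        encode_mrd_value(self.status, self.quant_value, self.neg_floor)

    @property
    def log_value(self) -> float:
        return encode_mrd_value(self.status, self.quant_value, self.neg_floor)


@dataclass(frozen=True)
class MrdTrajectory:
    """One patient-tissue series of (months, encoded log10 MRD) points."""

    patient_id: str
    tissue: Tissue
    times: np.ndarray
    values: np.ndarray
    statuses: tuple[MrdStatus, ...] = ()
    labels: tuple[Optional[str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-d vectors of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(
                f"times must be strictly increasing for {self.patient_id}/{self.tissue}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite MRD value for {self.patient_id}")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ClinicalRecord:
    """Time-to-progression outcome of one patient."""

    patient_id: str
    ttp_months: float
    event: int
    arm: Optional[str] = None  # LEN (maintenance) or OBS

    def __post_init__(self) -> None:
        if self.ttp_months <= 0:
            raise ValueError(f"ttp_months must be positive, got {self.ttp_months}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass
class Cohort:
    """Trajectories plus clinical outcomes keyed by patient id."""

    trajectories: list[MrdTrajectory] = field(default_factory=list)
    clinical: dict[str, ClinicalRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trajectories)

    def patient_ids(self) -> list[str]:
        return [t.patient_id for t in self.trajectories]

    def subset(self, keep: Iterable[MrdTrajectory]) -> "Cohort":
        keep = list(keep)
        ids = {t.patient_id for t in keep}
        return Cohort(
            trajectories=keep,
            clinical={pid: r for pid, r in self.clinical.items() if pid in ids},
        )


def build_trajectories(measurements: Sequence[MrdMeasurement]) -> list[MrdTrajectory]:
    """Group measurements into per-(patient, tissue) trajectories.

    Baseline samples are expected to be dropped upstream.  Duplicate times
    within one series are resolved conservatively by keeping the worse
    (higher) MRD value, with a warning.
    """
    groups: dict[tuple[str, Tissue], list[MrdMeasurement]] = {}
    for m in measurements:
        groups.setdefault((m.patient_id, m.tissue), []).append(m)

    out: list[MrdTrajectory] = []
    for (pid, tissue), ms in groups.items():
        ms = sorted(ms, key=lambda m: m.time_months)
        dedup: dict[float, MrdMeasurement] = {}
        for m in ms:
            prev = dedup.get(m.time_months)
            if prev is not None:
                worse = m if m.log_value > prev.log_value else prev
                logger.warning(
                    "duplicate time %s for %s/%s: keeping worse value %.3g",
                    m.time_months, pid, tissue.value, worse.log_value,
                )
                dedup[m.time_months] = worse
            else:
                dedup[m.time_months] = m
        ms = [dedup[t] for t in sorted(dedup)]
        out.append(
            MrdTrajectory(
                patient_id=pid,
                tissue=tissue,
                times=np.array([m.time_months for m in ms]),
                values=np.array([m.log_value for m in ms]),
                statuses=tuple(m.status for m in ms),
                labels=tuple(m.timepoint_label for m in ms),
            )
        )
    out.sort(key=lambda t: (t.patient_id, t.tissue.value))
    return out


def filter_cohort(cohort: Cohort, min_timepoints: int) -> Cohort:
    """Keep trajectories with at least ``min_timepoints`` post-baseline samples.

    Clinical records of dropped patients are removed; order is preserved.
    Idempotent and monotone: a larger threshold retains a subset.
    """
    if min_timepoints < 1:
        raise ValueError("min_timepoints must be >= 1")
    kept = [t for t in cohort.trajectories if len(t) >= min_timepoints]
    if not kept:
        warnings.warn("filter_cohort removed every trajectory", stacklevel=2)
    return cohort.subset(kept)


MEASUREMENT_COLUMNS = ["patient_id", "tissue", "timepoint_label", "time_months", "status", "quant_value"]
CLINICAL_COLUMNS = ["patient_id", "ttp_months", "event", "arm"]


def _parse_measurement_row(
    idx: int,
    row: pd.Series,
    schedule: Mapping[str, float],
    neg_floor: float,
) -> Optional[MrdMeasurement]:
    label = row.get("timepoint_label")
    label = None if pd.isna(label) else str(label).strip().upper()
    if label in BASELINE_LABELS:
        return None  # diagnostic sample: not an MRD time point
    status_token = str(row["status"]).strip().upper()
    try:
        status = MrdStatus(status_token)
    except ValueError:
        raise CohortParseError(
            f"row {idx}: unparseable status token {row['status']!r} "
            f"(expected one of {[s.value for s in MrdStatus]})"
        ) from None
    time = row.get("time_months")
    if pd.isna(time):
        if label is None:
            raise CohortParseError(
                f"row {idx}: needs time_months or a timepoint_label"
            )
        try:
            time = map_timepoint_to_months(label, schedule)
        except KeyError as e:
            raise CohortParseError(f"row {idx}: {e.args[0]}") from None
    qv = row.get("quant_value")
    qv = None if pd.isna(qv) else float(qv)
    try:
        return MrdMeasurement(
            patient_id=str(row["patient_id"]),
            tissue=Tissue(str(row["tissue"]).strip().upper()),
            time_months=float(time),
            status=status,
            quant_value=qv,
            timepoint_label=label,
            neg_floor=neg_floor,
        )
    except (InvalidMeasurementError, ValueError) as e:
        raise CohortParseError(f"row {idx}: {e}") from None


def read_cohort(
    measurements_path,
    clinical_path=None,
    schedule: Mapping[str, float] = DEFAULT_SCHEDULE,
    neg_floor: float = DEFAULT_NEG_FLOOR,
) -> Cohort:
    """Read a cohort from the long-format measurements CSV (one row per
    sample) and an optional clinical CSV.  Baseline rows are dropped."""
    df = pd.read_csv(measurements_path)
    missing = {"patient_id", "tissue", "status"} - set(df.columns)
    if missing:
        raise CohortParseError(
            f"measurements CSV missing mandatory column(s): {sorted(missing)}"
        )
    measurements = []
    for idx, row in df.iterrows():
        m = _parse_measurement_row(int(idx) + 2, row, schedule, neg_floor)  # +2: header + 1-based
        if m is not None:
            measurements.append(m)
    cohort = Cohort(trajectories=build_trajectories(measurements))

    if clinical_path is not None:
        cdf = pd.read_csv(clinical_path)
        missing = {"patient_id", "ttp_months", "event"} - set(cdf.columns)
        if missing:
            raise CohortParseError(
                f"clinical CSV missing mandatory column(s): {sorted(missing)}"
            )
        for idx, row in cdf.iterrows():
            arm = row.get("arm")
            try:
                rec = ClinicalRecord(
                    patient_id=str(row["patient_id"]),
                    ttp_months=float(row["ttp_months"]),
                    event=int(row["event"]),
                    arm=None if pd.isna(arm) else str(arm),
                )
            except ValueError as e:
                raise CohortParseError(f"clinical row {int(idx) + 2}: {e}") from None
            cohort.clinical[rec.patient_id] = rec
    return cohort


def write_cohort(cohort: Cohort, measurements_path, clinical_path=None) -> None:
    """Write a cohort back to the standard CSV layout.

    Rows are sorted (patient_id, tissue, time) so write -> read round-trips
    to an identical cohort.
    """
    rows = []
    for t in cohort.trajectories:
        statuses = t.statuses or (None,) * len(t)
        labels = t.labels or (None,) * len(t)
        for time, val, status, label in zip(t.times, t.values, statuses, labels):
            if status is None:
                # encoded-value-only trajectory: reconstruct status from level
                if val <= PNQ_LOG_LEVEL - 1e-12:
                    status, qv = MrdStatus.NEG, None
                elif abs(val - PNQ_LOG_LEVEL) <= 1e-12:
                    status, qv = MrdStatus.PNQ, None
                else:
                    status, qv = MrdStatus.QUANT, 10.0 ** val
            else:
                qv = 10.0 ** val if status is MrdStatus.QUANT else None
            rows.append(
                {
                    "patient_id": t.patient_id,
                    "tissue": t.tissue.value,
                    "timepoint_label": label,
                    "time_months": time,
                    "status": status.value,
                    "quant_value": qv,
                }
            )
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    df = df.sort_values(["patient_id", "tissue", "time_months"], kind="stable")
    df.to_csv(measurements_path, index=False)

    if clinical_path is not None:
        crows = [
            {
                "patient_id": r.patient_id,
                "ttp_months": r.ttp_months,
                "event": r.event,
                "arm": r.arm,
            }
            for r in sorted(cohort.clinical.values(), key=lambda r: r.patient_id)
        ]
        pd.DataFrame(crows, columns=CLINICAL_COLUMNS).to_csv(clinical_path, index=False)
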