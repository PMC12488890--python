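"""Domain types for sparse longitudinal records and deterministic preprocessing.

The preprocessing chain is: temporal binning (last observed value per bin),
patient-level splitting, two-step outlier filtering fitted on the training
split, and landmark example construction.  Time is stored as integer bin
offsets: within a :class:`ForecastExample` the landmark sits at offset 0,
history at offsets <= 0, and forecast horizons at 1..H.  Calendar dates are a
presentation concern of the text encoder, not of this module.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: All numeric observation values live on a fixed decimal grid (lab-report
#: granularity).  Keeping values, clip bounds and medians on this grid makes
#: the text rendering of a value an exact bit-level round trip.
VALUE_DECIMALS = 1


def round_value(x: float) -> float:
    """Snap a numeric value onto the package-wide decimal grid."""
    return float(np.round(float(x), VALUE_DECIMALS))


# ---------------------------------------------------------------------------
# Variable registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one clinical variable.

    ``reference_range`` is either a ``(v_min, v_max)`` pair or, for ranges
    conditioned on a static attribute (sex), a mapping from the attribute
    value to a pair, stored as ``{"by": attribute, attr_value: (lo, hi)}``.
    """

    name: str
    value_kind: str = "numeric"  # numeric | categorical
    role: str = "covariate"  # target | covariate | static
    code: str | None = None
    unit: str = ""
    reference_range: tuple[float, float] | Mapping[str, object] | None = None

    def __post_init__(self) -> None:
        if self.value_kind not in ("numeric", "categorical"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.role not in ("target", "covariate", "static"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "target" and self.value_kind != "numeric":
            raise ValueError(f"target variable {self.name!r} must be numeric")
        for rng in self._all_ranges():
            lo, hi = rng
            if not lo < hi:
                raise ValueError(f"{self.name}: reference range requires v_min < v_max, got {rng}")

    def _all_ranges(self) -> list[tuple[float, float]]:
        if self.reference_range is None:
            return []
        if isinstance(self.reference_range, Mapping):
            return [tuple(v) for k, v in self.reference_range.items() if k != "by"]
        return [tuple(self.reference_range)]

    def range_for(self, statics: Mapping[str, object] | None = None) -> tuple[float, float] | None:
        """Resolve the reference range, using static attributes when conditional."""
        if self.reference_range is None:
            return None
        if isinstance(self.reference_range, Mapping):
            by = self.reference_range["by"]
            key = None if statics is None else statics.get(by)
            rng = self.reference_range.get(key)
            return None if rng is None else tuple(rng)
        return tuple(self.reference_range)


class VariableRegistry:
    """Name-unique collection of :class:`VariableSpec`."""

    def __init__(self, specs: Iterable[VariableSpec] = ()):
        self._specs: dict[str, VariableSpec] = {}
        for spec in specs:
            self.add(spec)

    def add(self, spec: VariableSpec) -> None:
        if spec.name in self._specs:
            raise ValueError(f"duplicate variable name {spec.name!r}")
        self._specs[spec.name] = spec

    def __getitem__(self, name: str) -> VariableSpec:
        return self._specs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    @property
    def targets(self) -> list[str]:
        return [s.name for s in self if s.role == "target"]


def nsclc_registry() -> VariableRegistry:
    """Registry for the lung-cancer style forecasting task.

    Six routinely measured laboratory targets (with their LOINC codes and
    literature reference intervals; hemoglobin's interval is sex-specific),
    plus therapy and ECOG performance status as covariates and sex as a
    static attribute.
    """
    return VariableRegistry(
        [
            VariableSpec(
                "hemoglobin", role="target", code="718-7", unit="g/dL",
                reference_range={"by": "sex", "M": (14.0, 18.0), "F": (12.0, 16.0)},
            ),
            VariableSpec("leukocytes", role="target", code="26464-8", unit="10^9/L",
                         reference_range=(4.5, 11.0)),
            VariableSpec("lymphocytes/leukocytes", role="target", code="26478-8", unit="%",
                         reference_range=(20.0, 40.0)),
            VariableSpec("lymphocytes", role="target", code="26474-7", unit="10^9/L",
                         reference_range=(1.0, 4.0)),
            VariableSpec("neutrophils", role="target", code="26499-4", unit="10^9/L",
                         reference_range=(1.8, 7.5)),
            VariableSpec("lactate dehydrogenase", role="target", code="2532-0", unit="U/L",
                         reference_range=(122.0, 222.0)),
            VariableSpec("therapy", value_kind="categorical", role="covariate"),
            VariableSpec("ecog", role="covariate", unit="score"),
            VariableSpec("sex", value_kind="categorical", role="static"),
        ]
    )


# ---------------------------------------------------------------------------
# Records and observations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Observation:
    """One (variable, time, value) measurement.

    ``time`` is a raw timestamp before binning and an integer bin index after.
    """

    variable: str
    time: float
    value: float | str

    def __post_init__(self) -> None:
        if not math.isfinite(float(self.time)):
            raise ValueError(f"non-finite time for {self.variable!r}")
        if isinstance(self.value, (int, float)) and not math.isfinite(float(self.value)):
            raise ValueError(f"non-finite value for {self.variable!r}")

    @property
    def is_numeric(self) -> bool:
        return isinstance(self.value, (int, float))


@dataclass
class PatientRecord:
    """Static attributes plus time-sorted sparse observations for one patient."""

    patient_id: str
    statics: dict = field(default_factory=dict)
    observations: list[Observation] = field(default_factory=list)
    binned: bool = False

    def __post_init__(self) -> None:
        self.observations = sorted(self.observations, key=lambda o: (o.time, o.variable))

    def variables(self) -> set[str]:
        return {o.variable for o in self.observations}

    def last_value(self, variable: str, at_or_before: float | None = None):
        """Latest observed value of ``variable``, optionally up to a time."""
        best = None
        for obs in self.observations:
            if obs.variable != variable:
                continue
            if at_or_before is not None and obs.time > at_or_before:
                break
            best = obs
        return None if best is None else best.value


def bin_last_observed(record: PatientRecord, bin_width: float) -> PatientRecord:
    """Aggregate a record onto integer time bins, keeping the last observed value.

    For each (variable, bin) the value of the observation with the latest raw
    timestamp inside the bin is kept; bins with no observation stay absent (no
    imputation).  Already-binned records are fixed points and returned
    unchanged, which makes binning idempotent.
    """
    if record.binned:
        return replace(record)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    last: dict[tuple[str, int], tuple[float, Observation]] = {}
    for obs in record.observations:
        b = int(math.floor(obs.time / bin_width))
        key = (obs.variable, b)
        prev = last.get(key)
        if prev is None or obs.time >= prev[0]:
            last[key] = (obs.time, obs)
    binned = [
        Observation(variable=var, time=b, value=item[1].value)
        for (var, b), item in sorted(last.items(), key=lambda kv: (kv[0][1], kv[0][0]))
    ]
    return PatientRecord(record.patient_id, dict(record.statics), binned, binned=True)


# ---------------------------------------------------------------------------
# Two-step outlier filtering
# ---------------------------------------------------------------------------


@dataclass
class VariableBounds:
    """Per-variable bounds report from the two-step outlier procedure."""

    mean1: float
    sd1: float
    step1_low: float
    step1_high: float
    mean2: float
    sd2: float
    clip_low: float
    clip_high: float
    sigma: float  # sd of training values after removal + clipping
    n_train: int
    n_removed_train: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class OutlierReport:
    bounds: dict[str, VariableBounds]

    def sigma(self, variable: str) -> float:
        return self.bounds[variable].sigma

    def to_json(self, path=None) -> str:
        text = json.dumps({k: v.to_dict() for k, v in self.bounds.items()}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "OutlierReport":
        raw = json.loads(text)
        return cls({k: VariableBounds(**v) for k, v in raw.items()})


def fit_outlier_bounds(train_values: Mapping[str, Sequence[float]]) -> OutlierReport:
    """Fit the two-step filter on per-variable training values.

    Step 1 removes values outside mean +/- 3 sd.  Step 2 recomputes mean and
    sd on the survivors and defines clip bounds at the recomputed mean +/- 3
    sd; clip bounds are snapped to the value grid so clipped observations stay
    renderable at full precision.  Sample standard deviations (ddof=1) are
    used throughout.  A zero recomputed sd disables clipping for that variable
    and is flagged.
    """
    bounds: dict[str, VariableBounds] = {}
    for var, values in train_values.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise ValueError(f"no training values for {var!r}")
        mean1 = float(np.mean(v))
        sd1 = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        lo1, hi1 = mean1 - 3 * sd1, mean1 + 3 * sd1
        survivors = v[(v >= lo1) & (v <= hi1)]
        mean2 = float(np.mean(survivors))
        sd2 = float(np.std(survivors, ddof=1)) if survivors.size > 1 else 0.0
        degenerate = sd2 == 0.0
        if degenerate:
            lo2, hi2 = -math.inf, math.inf
        else:
            lo2 = round_value(mean2 - 3 * sd2)
            hi2 = round_value(mean2 + 3 * sd2)
        clipped = np.clip(survivors, lo2, hi2)
        sigma = float(np.std(clipped, ddof=1)) if clipped.size > 1 else 0.0
        bounds[var] = VariableBounds(
            mean1=mean1, sd1=sd1, step1_low=lo1, step1_high=hi1,
            mean2=mean2, sd2=sd2, clip_low=lo2, clip_high=hi2, sigma=sigma,
            n_train=int(v.size), n_removed_train=int(v.size - survivors.size),
            degenerate=degenerate,
        )
    return OutlierReport(bounds)


def apply_outlier_bounds(cohort: Sequence[PatientRecord], report: OutlierReport) -> list[PatientRecord]:
    """Remove step-1 outliers and clip survivors, for covered variables only.

    Categorical observations and variables without fitted bounds pass through
    untouched.
    """
    out = []
    for record in cohort:
        kept: list[Observation] = []
        for obs in record.observations:
            b = report.bounds.get(obs.variable)
            if b is None or not obs.is_numeric:
                kept.append(obs)
                continue
            v = float(obs.value)
            if v < b.step1_low or v > b.step1_high:
                continue
            clipped = min(max(v, b.clip_low), b.clip_high)
            kept.append(obs if clipped == v else replace(obs, value=clipped))
        out.append(PatientRecord(record.patient_id, dict(record.statics), kept, binned=record.binned))
    return out


def filter_outliers_two_step(
    train_values: Mapping[str, Sequence[float]], cohort: Sequence[PatientRecord]
) -> tuple[list[PatientRecord], OutlierReport]:
    """Convenience wrapper: fit bounds on training values and apply to a cohort."""
    report = fit_outlier_bounds(train_values)
    return apply_outlier_bounds(cohort, report), report


def collect_target_values(
    cohort: Sequence[PatientRecord], targets: Sequence[str], patient_ids: Iterable[str] | None = None
) -> dict[str, list[float]]:
    """Pool numeric values per target variable, optionally restricted to a split."""
    ids = None if patient_ids is None else set(patient_ids)
    values: dict[str, list[float]] = {t: [] for t in targets}
    for record in cohort:
        if ids is not None and record.patient_id not in ids:
            continue
        for obs in record.observations:
            if obs.variable in values and obs.is_numeric:
                values[obs.variable].append(float(obs.value))
    return values


# ---------------------------------------------------------------------------
# Patient-level splitting
# ---------------------------------------------------------------------------


@dataclass
class SplitManifest:
    train: list[str]
    val: list[str]
    test: list[str]

    def as_dict(self) -> dict[str, list[str]]:
        return {"train": self.train, "val": self.val, "test": self.test}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.as_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _allocate(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n items across fractions."""
    quotas = [n * f for f in fractions]
    counts = [int(math.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def split_patients(
    cohort: Sequence[PatientRecord],
    fractions: Sequence[float] = (0.8, 0.1, 0.1),
    strata: Sequence[str] | None = None,
    seed: int = 0,
) -> SplitManifest:
    """Split patients into disjoint train/validation/test id sets.

    With ``strata`` (a list of static attribute names) the split is performed
    independently within each stratum so per-stratum proportions track the
    requested fractions up to rounding.  Strata smaller than the number of
    splits degrade to a random allocation within the stratum (warned).
    Deterministic for a given seed.
    """
    if len(fractions) != 3 or not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must be three values summing to 1")
    rng = np.random.default_rng(seed)
    ids = sorted(r.patient_id for r in cohort)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids in cohort")
    by_stratum: dict[tuple, list[str]] = {}
    if strata:
        statics = {r.patient_id: r.statics for r in cohort}
        for pid in ids:
            missing = [a for a in strata if a not in statics[pid]]
            if missing:
                raise ValueError(f"patient {pid} lacks strata attributes {missing}")
            by_stratum.setdefault(tuple(statics[pid][a] for a in strata), []).append(pid)
    else:
        by_stratum[()] = list(ids)

    parts: list[list[str]] = [[], [], []]
    n_splits = sum(1 for f in fractions if f > 0)
    for key in sorted(by_stratum, key=repr):
        members = by_stratum[key]
        if len(members) < n_splits and strata:
            warnings.warn(
                f"stratum {key!r} has {len(members)} patients (< {n_splits} splits); "
                "falling back to random allocation within the stratum"
            )
        perm = rng.permutation(len(members))
        shuffled = [members[i] for i in perm]
        counts = _allocate(len(members), fractions)
        start = 0
        for part, c in zip(parts, counts):
            part.extend(shuffled[start : start + c])
            start += c
    return SplitManifest(*(sorted(p) for p in parts))


# ---------------------------------------------------------------------------
# Task configuration and landmark examples
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskConfig:
    """What to forecast and how records are anchored in time.

    ``bin_width`` is in raw timestamp units per bin (7 for daily stamps and
    weekly bins); ``unit_label`` names the bin for text rendering ("week",
    "hour", "month").  ``landmark_policy`` selects how the history/future
    boundary t0 is placed: at each event of ``landmark_variable``
    (therapy_start), after a fixed number of history bins (fixed_history), or
    at the earliest observation (baseline_only).
    """

    targets: tuple[str, ...]
    horizon_offsets: tuple[int, ...]
    bin_width: float = 1.0
    unit_label: str = "week"
    landmark_policy: str = "therapy_start"
    landmark_variable: str | None = "therapy"
    history_bins: int | None = None

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("targets must be nonempty")
        offs = self.horizon_offsets
        if not offs:
            raise ValueError("horizon_offsets must be nonempty")
        if any(o <= 0 for o in offs):
            raise ValueError("horizon_offsets must be positive")
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("horizon_offsets must be strictly increasing")
        if self.landmark_policy not in ("therapy_start", "fixed_history", "baseline_only"):
            raise ValueError(f"unknown landmark_policy {self.landmark_policy!r}")
        if self.landmark_policy == "fixed_history" and not self.history_bins:
            raise ValueError("fixed_history policy requires history_bins")


def nsclc_task(targets: Sequence[str] | None = None) -> TaskConfig:
    """Weekly forecasting of lab panels up to 13 weeks after each therapy start."""
    if targets is None:
        targets = nsclc_registry().targets
    return TaskConfig(tuple(targets), tuple(range(1, 14)), bin_width=7.0, unit_label="week",
                      landmark_policy="therapy_start", landmark_variable="therapy")


def icu_task(targets: Sequence[str]) -> TaskConfig:
    """Hourly forecasting of the next 24 h from the first 24 h of ICU stay."""
    return TaskConfig(tuple(targets), tuple(range(1, 25)), bin_width=1.0, unit_label="hour",
                      landmark_policy="fixed_history", landmark_variable=None, history_bins=24)


def ad_task(targets: Sequence[str]) -> TaskConfig:
    """Six-monthly forecasting of cognitive scores over 24 months from baseline."""
    return TaskConfig(tuple(targets), (1, 2, 3, 4), bin_width=182.0, unit_label="6-month period",
                      landmark_policy="baseline_only", landmark_variable=None)


@dataclass
class ForecastExample:
    """Landmark-split unit: history at offsets <= 0, truth at horizon offsets.

    ``baseline_values`` holds v0 per target (last observed value at or before
    the landmark); targets never observed pre-landmark are absent.  ``truth``
    maps target -> {horizon offset -> value} and contains only observed cells.
    """

    patient_id: str
    t0: int
    statics: dict
    history: list[Observation]
    baseline_values: dict[str, float]
    truth: dict[str, dict[int, float]]
    horizon_offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(o.time > 0 for o in self.history):
            raise ValueError("history observation after landmark")
        allowed = set(self.horizon_offsets)
        for target, cells in self.truth.items():
            if not set(cells) <= allowed:
                raise ValueError(f"truth offsets outside horizon for {target!r}")

    def t_counts(self) -> dict[str, int]:
        """Observed future points per target (T_i)."""
        return {t: len(cells) for t, cells in self.truth.items()}

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "t0": self.t0,
            "statics": dict(self.statics),
            "history": [[o.variable, int(o.time), o.value] for o in self.history],
            "baseline_values": dict(self.baseline_values),
            "truth": {t: {str(o): v for o, v in cells.items()} for t, cells in self.truth.items()},
            "horizon_offsets": list(self.horizon_offsets),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForecastExample":
        return cls(
            patient_id=d["patient_id"],
            t0=int(d["t0"]),
            statics=dict(d["statics"]),
            history=[Observation(v, int(t), val) for v, t, val in d["history"]],
            baseline_values={k: float(v) for k, v in d["baseline_values"].items()},
            truth={
                t: {int(o): float(v) for o, v in cells.items()}
                for t, cells in d["truth"].items()
            },
            horizon_offsets=tuple(int(o) for o in d["horizon_offsets"]),
        )

    @property
    def n_truth_cells(self) -> int:
        return sum(len(c) for c in self.truth.values())


def _landmarks(record: PatientRecord, task: TaskConfig) -> list[int]:
    times = [int(o.time) for o in record.observations]
    if not times:
        return []
    if task.landmark_policy == "therapy_start":
        if task.landmark_variable is None:
            raise ValueError("therapy_start policy requires landmark_variable")
        marks = sorted({int(o.time) for o in record.observations if o.variable == task.landmark_variable})
        return marks
    if task.landmark_policy == "fixed_history":
        first = min(times)
        return [first + task.history_bins - 1]
    return [min(times)]


def make_landmark_examples(record: PatientRecord, task: TaskConfig) -> list[ForecastExample]:
    """Cut a binned record into forecast examples, one per landmark.

    History is every observation at or before t0 (times re-expressed relative
    to t0); truth holds the target values observed exactly at the configured
    horizon offsets.  Examples with no observed future target value at all
    are dropped.  Records whose landmark variable never occurs under the
    therapy_start policy yield an empty list.
    """
    if not record.binned:
        raise ValueError("record must be binned to task time units first")
    examples = []
    for t0 in _landmarks(record, task):
        history = [
            replace(obs, time=int(obs.time) - t0)
            for obs in record.observations
            if obs.time <= t0
        ]
        baseline = {}
        for target in task.targets:
            v = record.last_value(target, at_or_before=t0)
            if v is not None and isinstance(v, (int, float)):
                baseline[target] = float(v)
        truth: dict[str, dict[int, float]] = {}
        for obs in record.observations:
            if obs.variable not in task.targets or not obs.is_numeric:
                continue
            off = int(obs.time) - t0
            if off in task.horizon_offsets:
                truth.setdefault(obs.variable, {})[off] = float(obs.value)
        ex = ForecastExample(
            patient_id=record.patient_id, t0=t0, statics=dict(record.statics),
            history=history, baseline_values=baseline, truth=truth,
            horizon_offsets=tuple(task.horizon_offsets),
        )
        if ex.n_truth_cells > 0:
            examples.append(ex)
    return examples


def build_examples(
    cohort: Sequence[PatientRecord], task: TaskConfig
) -> tuple[list[ForecastExample], dict]:
    """Build examples for a whole cohort with drop accounting."""
    examples: list[ForecastExample] = []
    n_landmarks = 0
    for record in cohort:
        n_landmarks += len(_landmarks(record, task))
        examples.extend(make_landmark_examples(record, task))
    accounting = {
        "n_patients": len(cohort),
        "n_landmarks": n_landmarks,
        "n_examples": len(examples),
        "n_dropped_empty": n_landmarks - len(examples),
    }
    return examples, accounting


# ---------------------------------------------------------------------------
# Cohort I/O (long-format CSV)
# ---------------------------------------------------------------------------


def write_cohort(cohort: Sequence[PatientRecord], obs_path, statics_path) -> None:
    """Write a cohort as a long observations CSV plus a statics CSV."""
    obs_rows = [
        {"patient_id": r.patient_id, "variable": o.variable, "time": o.time, "value": o.value}
        for r in cohort
        for o in r.observations
    ]
    static_rows = [
        {"patient_id": r.patient_id, "attribute": k, "value": v}
        for r in cohort
        for k, v in sorted(r.statics.items())
    ]
    cols = ["patient_id", "variable", "time", "value"]
    pd.DataFrame(obs_rows, columns=cols).to_csv(obs_path, index=False)
    pd.DataFrame(static_rows, columns=["patient_id", "attribute", "value"]).to_csv(
        statics_path, index=False
    )


def _coerce(value):
    try:
        return float(value)
    except (TypeError, ValueError):
        return str(value)


def read_cohort(obs_path, statics_path, binned: bool = False) -> list[PatientRecord]:
    """Read the long-format CSV pair back into patient records."""
    obs = pd.read_csv(obs_path, dtype={"patient_id": str})
    statics = pd.read_csv(statics_path, dtype={"patient_id": str})
    by_patient: dict[str, PatientRecord] = {}
    for pid, grp in statics.groupby("patient_id", sort=True):
        by_patient[pid] = PatientRecord(
            pid, {row.attribute: _coerce(row.value) for row in grp.itertuples()}, [], binned=binned
        )
    for pid, grp in obs.groupby("patient_id", sort=True):
        rec = by_patient.setdefault(pid, PatientRecord(pid, {}, [], binned=binned))
        rec.observations = sorted(
            (
                Observation(row.variable, float(row.time), _coerce(row.value))
                for row in grp.itertuples()
            ),
            key=lambda o: (o.time, o.variable),
        )
    return [by_patient[k] for k in sorted(by_patient)]
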