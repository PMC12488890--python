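"""Trajectory ensembles, aggregation, and the reference forecasters.

A backend is sampled k times per example; every generation is decoded with
full parse accounting and the per-cell arithmetic mean of the parsed values
is the final forecast (cells with no parsed value fall back to copy-forward,
flagged).  The oracle-best analysis selects, per example, the single sampled
trajectory with the lowest scaled MAE against the truth — a hindsight lower
bound on what better aggregation could achieve.  Two native reference
forecasters are included: copy-forward (repeat the last observed value) and
a per-(target, horizon) least-squares model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LinearRegression

from twinforecast.data_model import ForecastExample, round_value
from twinforecast.encoding import DecodedForecast, EncodedExample, decode_forecast
from twinforecast.lm_backend.base import LMBackend

Trajectory = dict[str, dict[int, float]]


# ---------------------------------------------------------------------------
# Training statistics shared by forecasters
# ---------------------------------------------------------------------------


@dataclass
class TrainingStats:
    """Per-target medians of observed future values in the training split.

    Medians are snapped to the value grid so that a median emitted through
    the text channel survives rendering exactly.
    """

    medians: dict[str, float]

    @classmethod
    def from_examples(cls, examples: Sequence[ForecastExample],
                      targets: Sequence[str]) -> "TrainingStats":
        pools: dict[str, list[float]] = {t: [] for t in targets}
        for ex in examples:
            for target, cells in ex.truth.items():
                if target in pools:
                    pools[target].extend(cells.values())
        medians = {t: round_value(np.median(vs)) for t, vs in pools.items() if vs}
        return cls(medians)


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryEnsemble:
    """k decoded sampled trajectories for one example, with accounting."""

    example: ForecastExample
    forecasts: list[DecodedForecast]
    raw_texts: list[str]
    k: int

    @property
    def n_parsed(self) -> int:
        return sum(1 for f in self.forecasts if f.parse_status != "failed")

    def cell_values(self, target: str, offset: int) -> list[float]:
        return [
            f.values[target][offset]
            for f in self.forecasts
            if target in f.values and offset in f.values[target]
        ]


@dataclass
class AggregatedForecast:
    values: Trajectory
    cell_counts: dict[str, dict[int, int]]
    fallback_cells: list[tuple[str, int]] = field(default_factory=list)


def sample_trajectories(backend: LMBackend, encoded: EncodedExample, k: int = 30,
                        rng: np.random.Generator | None = None) -> TrajectoryEnsemble:
    """Draw k completions for one encoded example and decode them all.

    All-failed ensembles are valid data; raw texts are retained for audit.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    texts = backend.generate(encoded.input_text, k, rng)
    forecasts = [decode_forecast(t, encoded.schema) for t in texts]
    return TrajectoryEnsemble(example=encoded.example, forecasts=forecasts,
                              raw_texts=texts, k=k)


def aggregate_mean(ensemble: TrajectoryEnsemble,
                   fallback: Trajectory | None = None) -> AggregatedForecast:
    """Per-cell arithmetic mean of parsed sampled values.

    Cells where every draw failed to parse take the copy-forward ``fallback``
    value (flagged); without a fallback they stay absent.  When all parsed
    values of a cell are identical the mean short-circuits to that exact
    value, so an ensemble of identical samples aggregates to itself bit for
    bit.
    """
    values: Trajectory = {}
    counts: dict[str, dict[int, int]] = {}
    fallback_cells: list[tuple[str, int]] = []
    targets = set()
    for f in ensemble.forecasts:
        targets.update(f.values)
    if fallback:
        targets.update(fallback)
    for target in sorted(targets):
        cell_offsets = set()
        for f in ensemble.forecasts:
            cell_offsets.update(f.values.get(target, ()))
        if fallback and target in fallback:
            cell_offsets.update(fallback[target])
        for offset in sorted(cell_offsets):
            vals = ensemble.cell_values(target, offset)
            counts.setdefault(target, {})[offset] = len(vals)
            if vals:
                first = vals[0]
                agg = first if all(v == first for v in vals) else float(np.mean(vals))
                values.setdefault(target, {})[offset] = agg
            elif fallback and target in fallback and offset in fallback[target]:
                values.setdefault(target, {})[offset] = fallback[target][offset]
                fallback_cells.append((target, offset))
    return AggregatedForecast(values=values, cell_counts=counts,
                              fallback_cells=fallback_cells)


# ---------------------------------------------------------------------------
# Scaled MAE at the single-example level and the oracle analysis
# ---------------------------------------------------------------------------


def example_scaled_mae(values: Trajectory, truth: Trajectory,
                       sigmas: Mapping[str, float]) -> float:
    """Scaled MAE of one trajectory against one example's observed cells.

    Per target: mean absolute error over the target's observed future points
    divided by the target's sigma; averaged across targets with at least one
    observed point.  Missing predicted cells are skipped.
    """
    per_target = []
    for target, cells in truth.items():
        errs = [
            abs(v - values[target][o])
            for o, v in cells.items()
            if target in values and o in values[target]
        ]
        if errs:
            per_target.append(float(np.mean(errs)) / sigmas[target])
    if not per_target:
        return float("nan")
    return float(np.mean(per_target))


def _covers_truth(values: Trajectory, truth: Trajectory) -> bool:
    return all(
        target in values and offset in values[target]
        for target, cells in truth.items()
        for offset in cells
    )


def oracle_best_trajectory(ensemble: TrajectoryEnsemble, truth: Trajectory,
                           sigmas: Mapping[str, float]) -> tuple[int, Trajectory, float]:
    """Hindsight-best sampled trajectory: lowest per-example scaled MAE.

    Considers fully scorable samples — those whose parsed cells cover every
    observed truth cell, so the score skips nothing; ties break to the
    lowest index.  Raises when no sample is fully scorable.
    """
    best = None
    for idx, f in enumerate(ensemble.forecasts):
        if f.parse_status == "failed" or not _covers_truth(f.values, truth):
            continue
        score = example_scaled_mae(f.values, truth, sigmas)
        if np.isnan(score):
            continue
        if best is None or score < best[2]:
            best = (idx, f.values, score)
    if best is None:
        raise ValueError("ensemble has no fully scorable sample")
    return best


# ---------------------------------------------------------------------------
# Native reference forecasters
# ---------------------------------------------------------------------------


def copy_forward_forecast(example: ForecastExample, stats: TrainingStats,
                          targets: Sequence[str] | None = None
                          ) -> tuple[Trajectory, dict[str, bool]]:
    """Repeat each target's last observed pre-landmark value across the horizon.

    Targets never observed before the landmark take the training-split
    median; the flag map records which targets needed it.
    """
    targets = list(targets) if targets is not None else list(stats.medians)
    values: Trajectory = {}
    median_used: dict[str, bool] = {}
    for target in targets:
        v0 = example.baseline_values.get(target)
        if v0 is None:
            v0 = stats.medians[target]
            median_used[target] = True
        else:
            median_used[target] = False
        values[target] = {o: float(v0) for o in example.horizon_offsets}
    return values, median_used


def _static_categories(examples: Sequence[ForecastExample]) -> dict[str, list]:
    cats: dict[str, set] = {}
    for ex in examples:
        for key, val in ex.statics.items():
            if isinstance(val, str):
                cats.setdefault(key, set()).add(val)
    return {k: sorted(v) for k, v in sorted(cats.items())}


def _features(example: ForecastExample, target: str, stats: TrainingStats,
              categories: dict[str, list]) -> np.ndarray:
    v0 = example.baseline_values.get(target)
    if v0 is None:
        v0, gap = stats.medians[target], float(len(example.horizon_offsets))
    else:
        last_t = max(
            int(o.time) for o in example.history
            if o.variable == target and o.is_numeric
        )
        gap = float(-last_t)
    feats = [float(v0), gap]
    for key, levels in categories.items():
        val = example.statics.get(key)
        feats.extend(1.0 if val == lv else 0.0 for lv in levels)
    for key, val in sorted(example.statics.items()):
        if isinstance(val, (int, float)):
            feats.append(float(val))
    return np.array(feats)


class LinearReferenceModel:
    """Per-(target, horizon) least squares on simple landmark features.

    Features: last observed value, time since that observation, one-hot
    categorical statics and numeric statics.  Cells that cannot be fitted
    (fewer than two training rows, or a degenerate design) fall back to
    copy-forward, flagged.
    """

    def __init__(self, targets: Sequence[str], horizon_offsets: Sequence[int]):
        self.targets = list(targets)
        self.horizon_offsets = list(horizon_offsets)
        self.models: dict[tuple[str, int], LinearRegression] = {}
        self.categories: dict[str, list] = {}
        self.stats: TrainingStats | None = None

    def fit(self, train_examples: Sequence[ForecastExample],
            stats: TrainingStats | None = None) -> "LinearReferenceModel":
        self.stats = stats or TrainingStats.from_examples(train_examples, self.targets)
        self.categories = _static_categories(train_examples)
        for target in self.targets:
            for offset in self.horizon_offsets:
                rows, ys = [], []
                for ex in train_examples:
                    cell = ex.truth.get(target, {}).get(offset)
                    if cell is None:
                        continue
                    rows.append(_features(ex, target, self.stats, self.categories))
                    ys.append(cell)
                if len(rows) < 2:
                    continue
                X = np.vstack(rows)
                model = LinearRegression()
                model.fit(X, np.array(ys))
                if not np.all(np.isfinite(model.coef_)):
                    continue
                self.models[(target, offset)] = model
        return self

    def predict(self, example: ForecastExample) -> tuple[Trajectory, list[tuple[str, int]]]:
        if self.stats is None:
            raise RuntimeError("model is not fitted")
        cf, _ = copy_forward_forecast(example, self.stats, self.targets)
        values: Trajectory = {}
        fallback_cells: list[tuple[str, int]] = []
        for target in self.targets:
            for offset in example.horizon_offsets:
                model = self.models.get((target, offset))
                if model is None:
                    values.setdefault(target, {})[offset] = cf[target][offset]
                    fallback_cells.append((target, offset))
                    continue
                x = _features(example, target, self.stats, self.categories)
                values.setdefault(target, {})[offset] = float(model.predict(x[None, :])[0])
        return values, fallback_cells


def linear_reference_forecast(train_examples: Sequence[ForecastExample],
                              example: ForecastExample,
                              targets: Sequence[str]) -> Trajectory:
    """One-shot functional form of :class:`LinearReferenceModel`."""
    model = LinearReferenceModel(targets, list(example.horizon_offsets))
    model.fit(train_examples)
    return model.predict(example)[0]
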