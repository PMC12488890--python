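"""Patient-nested forecasting metrics and derived classification metrics.

Regression metrics (per target variable) average errors in two stages: an
inner mean over each patient's observed future points (1/T_i) and an outer
mean over patients (1/n), so densely observed patients do not dominate.
MAE, scaled MAE (MAE divided by the target's post-outlier-filtering standard
deviation sigma), MASE (MAE relative to always predicting the baseline value
v0), SMAPE (bounded in [0, 200], zero-denominator terms skipped), and a
rank-weighted Spearman correlation that pools a single rank function across
patients while weighting each point by 1/T_i.

Classification metrics derive events from reference intervals [v_min, v_max]
(low / normal / high, with per-class and count-weighted Mann-Whitney AUCs)
and from strict monotone trends over a lookback window of length s.
Distributional checks: the two-sample Kolmogorov-Smirnov statistic per
target and a correlation-preservation R^2 across target pairs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

Trajectory = dict[str, dict[int, float]]


# ---------------------------------------------------------------------------
# Configuration and report
# ---------------------------------------------------------------------------


@dataclass
class MetricConfig:
    """Constants the metric suite depends on.

    ``sigmas``: per-target standard deviation after outlier filtering
    (training split).  ``reference_ranges``: per-target (v_min, v_max), or a
    sex-conditional mapping ``{"by": attr, value: (lo, hi)}``.  ``trend_window``
    is s in task time units.  ``events`` adds extra single-sided range tasks,
    e.g. a hemoglobin bleed threshold: ``{"hemoglobin_bleed": ("hemoglobin",
    (7.5, inf))}``.
    """

    sigmas: dict[str, float]
    reference_ranges: dict[str, object] = field(default_factory=dict)
    trend_window: int = 3
    events: dict[str, tuple[str, tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, s in self.sigmas.items():
            if not s > 0:
                raise ValueError(f"sigma for {t!r} must be positive")
        if not self.trend_window > 0:
            raise ValueError("trend_window must be positive")

    def range_for(self, target: str, statics: Mapping | None = None):
        rng = self.reference_ranges.get(target)
        if rng is None:
            return None
        if isinstance(rng, Mapping):
            by = rng["by"]
            key = None if statics is None else statics.get(by)
            pair = rng.get(key)
            return None if pair is None else tuple(pair)
        return tuple(rng)


@dataclass
class PatientSeries:
    """One patient's scored cells for one target."""

    truth: dict[int, float]
    pred: dict[int, float]
    v0: float | None = None
    statics: dict = field(default_factory=dict)

    def scored_offsets(self) -> list[int]:
        return sorted(set(self.truth) & set(self.pred))


@dataclass
class MetricReport:
    per_target: dict[str, dict]
    pooled: dict
    constants: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {"per_target": self.per_target, "pooled": self.pooled, "constants": self.constants},
            indent=2, sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for target, metrics in sorted(self.per_target.items()):
            row = {"target": target}
            row.update({k: v for k, v in metrics.items() if not isinstance(v, dict)})
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Regression metrics (patient-nested)
# ---------------------------------------------------------------------------


def forecast_errors(panel: Sequence[PatientSeries], sigma: float) -> dict:
    """MAE, scaled MAE, MASE and SMAPE with patient-nested averaging.

    Patients with no scored cell are ignored.  MASE is computed on the
    sub-panel of patients with a known baseline value and a nonzero baseline
    deviation; the exclusion count is reported.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    inner_mae, inner_smape = [], []
    mase_num, mase_den = [], []
    n_mase_excluded = 0
    for series in panel:
        offs = series.scored_offsets()
        if not offs:
            continue
        t_i = len(offs)
        errs = [abs(series.truth[o] - series.pred[o]) for o in offs]
        inner_mae.append(sum(errs) / t_i)
        terms = []
        for o in offs:
            v, vh = series.truth[o], series.pred[o]
            denom = abs(v) + abs(vh)
            terms.append(abs(v - vh) / denom if denom != 0 else 0.0)
        inner_smape.append(sum(terms) / t_i)
        if series.v0 is None:
            n_mase_excluded += 1
            continue
        base = [abs(series.truth[o] - series.v0) for o in offs]
        if sum(base) == 0:
            n_mase_excluded += 1
            continue
        mase_num.append(sum(errs) / t_i)
        mase_den.append(sum(base) / t_i)
    n = len(inner_mae)
    if n == 0:
        return {"n_patients": 0, "mae": None, "scaled_mae": None, "mase": None,
                "smape": None, "n_mase_excluded": 0,
                "diagnostic": "no scoreable patients"}
    mae = sum(inner_mae) / n
    smape = 200.0 * sum(inner_smape) / n
    mase = (sum(mase_num) / len(mase_num)) / (sum(mase_den) / len(mase_den)) if mase_num else None
    return {
        "n_patients": n,
        "mae": mae,
        "scaled_mae": mae / sigma,
        "mase": mase,
        "n_mase_excluded": n_mase_excluded,
        "smape": smape,
    }


def spearman_weighted(panel: Sequence[PatientSeries]) -> float | None:
    """Rank correlation with a single pooled rank function and 1/T_i weights.

    Ranks (average rank for ties) are assigned over all patients' pooled
    observed values — once for the truths, once for the predictions — and
    each point is weighted by the reciprocal of its patient's point count.
    Undefined (None) when fewer than two points are scored or a side has
    zero rank variance.
    """
    truths, preds, weights = [], [], []
    n = 0
    for series in panel:
        offs = series.scored_offsets()
        if not offs:
            continue
        n += 1
        w = 1.0 / len(offs)
        for o in offs:
            truths.append(series.truth[o])
            preds.append(series.pred[o])
            weights.append(w)
    if len(truths) < 2:
        return None
    r_v = sps.rankdata(truths)
    r_p = sps.rankdata(preds)
    w = np.asarray(weights)
    mean_rv = float((w * r_v).sum()) / n
    mean_rp = float((w * r_p).sum()) / n
    num = float((w * (r_v - mean_rv) * (r_p - mean_rp)).sum())
    var_v = float((w * (r_v - mean_rv) ** 2).sum())
    var_p = float((w * (r_p - mean_rp) ** 2).sum())
    if var_v == 0 or var_p == 0:
        return None
    return num / math.sqrt(var_v * var_p)


# ---------------------------------------------------------------------------
# Reference-range classification
# ---------------------------------------------------------------------------


def label_reference(values: Sequence[float], rng: tuple[float, float]) -> list[str]:
    """Label values low / normal / high; boundary equality counts as normal."""
    lo, hi = rng
    return ["low" if v < lo else "high" if v > hi else "normal" for v in values]


def mann_whitney_auc(scores: Sequence[float], positives: Sequence[bool]) -> float | None:
    """Rank-sum AUC with half credit for score ties; None if a class is empty."""
    pos = np.asarray(positives, dtype=bool)
    n_pos = int(pos.sum())
    n_neg = int(len(pos) - n_pos)
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = sps.rankdata(np.asarray(scores, dtype=float))
    return (float(ranks[pos].sum()) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auc_reference(pred_values: Sequence[float], true_labels: Sequence[str],
                  ranges: Sequence[tuple[float, float]] | tuple[float, float]) -> dict:
    """Per-class and count-weighted AUCs for the low/normal/high tasks.

    Prediction scores are signed distances past the relevant threshold:
    ``v_min - pred`` for low, ``pred - v_max`` for high, and
    ``min(pred - v_min, v_max - pred)`` for normal — monotone in the
    predicted value and threshold-free.  ``ranges`` may vary per point (for
    sex-conditional intervals).
    """
    preds = list(pred_values)
    if isinstance(ranges, tuple) and len(ranges) == 2 and not isinstance(ranges[0], tuple):
        ranges = [ranges] * len(preds)
    scores = {
        "low": [lo - p for p, (lo, hi) in zip(preds, ranges)],
        "high": [p - hi for p, (lo, hi) in zip(preds, ranges)],
        "normal": [min(p - lo, hi - p) for p, (lo, hi) in zip(preds, ranges)],
    }
    out = {}
    counts = {}
    for cls in ("low", "normal", "high"):
        positives = [lab == cls for lab in true_labels]
        counts[cls] = sum(positives)
        out[f"auc_{cls}"] = mann_whitney_auc(scores[cls], positives)
    avail = [(out[f"auc_{c}"], counts[c]) for c in ("low", "normal", "high")
             if out[f"auc_{c}"] is not None]
    total = sum(c for _, c in avail)
    out["auc_weighted"] = (
        sum(a * c for a, c in avail) / total if avail and total > 0 else None
    )
    out["counts"] = counts
    return out


# ---------------------------------------------------------------------------
# Trend classification
# ---------------------------------------------------------------------------


def trend_labels(trajectory: Mapping[int, float], s: int) -> dict[int, str]:
    """Label each point increasing / decreasing / neither / excluded.

    A point at time t is decreasing only if every consecutive pair inside the
    lookback window [t-s, t] strictly decreases (increasing symmetric).
    Points with t < s, or whose window is not completely observed on the
    unit grid, are excluded.
    """
    times = sorted(trajectory)
    present = set(times)
    labels: dict[int, str] = {}
    for t in times:
        if t < s:
            labels[t] = "excluded"
            continue
        window = list(range(t - s, t + 1))
        if any(k not in present for k in window):
            labels[t] = "excluded"
            continue
        diffs = [trajectory[k + 1] - trajectory[k] for k in window[:-1]]
        if all(d < 0 for d in diffs):
            labels[t] = "decreasing"
        elif all(d > 0 for d in diffs):
            labels[t] = "increasing"
        else:
            labels[t] = "neither"
    return labels


def trend_score(trajectory: Mapping[int, float], t: int, s: int,
                direction: str) -> float | None:
    """Worst-case consecutive margin over the window; positive iff labeled.

    Returns None when the window is incomplete or t < s.
    """
    if t < s:
        return None
    window = list(range(t - s, t + 1))
    if any(k not in trajectory for k in window):
        return None
    if direction == "decreasing":
        return min(trajectory[k] - trajectory[k + 1] for k in window[:-1])
    if direction == "increasing":
        return min(trajectory[k + 1] - trajectory[k] for k in window[:-1])
    raise ValueError(f"unknown direction {direction!r}")


def auc_trend(pred_trajectories: Sequence[Mapping[int, float]],
              true_trajectories: Sequence[Mapping[int, float]], s: int) -> dict:
    """Mann-Whitney AUC for the increasing and decreasing trend tasks.

    A (patient, time) point enters the evaluation when its truth label is not
    excluded and the predicted trajectory covers the same window; the number
    of excluded points is reported.
    """
    rows: list[tuple[str, float, float]] = []  # (truth label, score_up, score_down)
    n_excluded = 0
    for pred, truth in zip(pred_trajectories, true_trajectories):
        labels = trend_labels(truth, s)
        for t, lab in labels.items():
            if lab == "excluded":
                n_excluded += 1
                continue
            up = trend_score(pred, t, s, "increasing")
            down = trend_score(pred, t, s, "decreasing")
            if up is None or down is None:
                n_excluded += 1
                continue
            rows.append((lab, up, down))
    result = {"n_points": len(rows), "n_excluded": n_excluded}
    result["auc_trend_up"] = mann_whitney_auc(
        [r[1] for r in rows], [r[0] == "increasing" for r in rows]) if rows else None
    result["auc_trend_down"] = mann_whitney_auc(
        [r[2] for r in rows], [r[0] == "decreasing" for r in rows]) if rows else None
    return result


# ---------------------------------------------------------------------------
# Distributional checks
# ---------------------------------------------------------------------------


def ks_statistic(pred_pool: Sequence[float], truth_pool: Sequence[float]) -> float | None:
    """Two-sample sup-norm ECDF distance between prediction and truth pools."""
    if len(pred_pool) == 0 or len(truth_pool) == 0:
        return None
    return float(
        sps.ks_2samp(np.asarray(pred_pool), np.asarray(truth_pool), method="asymp").statistic
    )


def correlation_preservation(
    truth_cells: Mapping[str, Mapping[tuple, float]],
    pred_cells: Mapping[str, Mapping[tuple, float]],
    targets: Sequence[str],
    min_points: int = 3,
) -> tuple[float | None, dict]:
    """R^2 between truth and prediction inter-variable correlation vectors.

    For every target pair, the Pearson correlation is computed on the
    (patient, time) cells where the truth observes both variables — once for
    the truths and once for the predictions at those same cells — and the
    squared Pearson correlation between the two pair-correlation vectors is
    returned.  Pairs with fewer than ``min_points`` shared cells or zero
    variance on either side are flagged and skipped.
    """
    truth_vec, pred_vec, skipped = [], [], []
    for i in range(len(targets)):
        for j in range(i + 1, len(targets)):
            a, b = targets[i], targets[j]
            keys = sorted(set(truth_cells.get(a, {})) & set(truth_cells.get(b, {})))
            keys = [k for k in keys if k in pred_cells.get(a, {}) and k in pred_cells.get(b, {})]
            if len(keys) < min_points:
                skipped.append((a, b, "too few co-observed points"))
                continue
            ta = np.array([truth_cells[a][k] for k in keys])
            tb = np.array([truth_cells[b][k] for k in keys])
            pa = np.array([pred_cells[a][k] for k in keys])
            pb = np.array([pred_cells[b][k] for k in keys])
            if min(ta.std(), tb.std(), pa.std(), pb.std()) == 0:
                skipped.append((a, b, "zero variance"))
                continue
            truth_vec.append(float(np.corrcoef(ta, tb)[0, 1]))
            pred_vec.append(float(np.corrcoef(pa, pb)[0, 1]))
    info = {"n_pairs": len(truth_vec), "skipped": skipped,
            "truth_correlations": truth_vec, "pred_correlations": pred_vec}
    if len(truth_vec) < 2:
        return None, info
    tv, pv = np.asarray(truth_vec), np.asarray(pred_vec)
    if tv.std() == 0 or pv.std() == 0:
        return None, info
    return float(np.corrcoef(tv, pv)[0, 1] ** 2), info


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------


def evaluate_forecasts(examples: Sequence, forecasts: Sequence[Trajectory],
                       config: MetricConfig,
                       targets: Sequence[str] | None = None) -> MetricReport:
    """Score aligned (example, predicted trajectory) pairs into a report.

    Trend trajectories are anchored with the baseline value at offset 0 on
    both sides when available, so the first window can close.  KS pools
    predictions at the truth-observed cells against the observed truths.
    """
    targets = list(targets) if targets is not None else sorted(config.sigmas)
    per_target: dict[str, dict] = {}
    truth_cells: dict[str, dict[tuple, float]] = {t: {} for t in targets}
    pred_cells: dict[str, dict[tuple, float]] = {t: {} for t in targets}

    for target in targets:
        panel: list[PatientSeries] = []
        range_points: list[tuple[float, float, tuple[float, float]]] = []
        pred_trajs, true_trajs = [], []
        for idx, (ex, fc) in enumerate(zip(examples, forecasts)):
            truth = ex.truth.get(target, {})
            pred = fc.get(target, {})
            v0 = ex.baseline_values.get(target)
            series = PatientSeries(truth=dict(truth), pred=dict(pred), v0=v0,
                                   statics=dict(ex.statics))
            panel.append(series)
            rng = config.range_for(target, ex.statics)
            for o in series.scored_offsets():
                key = (idx, o)
                truth_cells[target][key] = truth[o]
                pred_cells[target][key] = pred[o]
                if rng is not None:
                    range_points.append((truth[o], pred[o], rng))
            t_traj = dict(truth)
            p_traj = dict(pred)
            if v0 is not None:
                t_traj[0] = v0
                p_traj[0] = v0
            true_trajs.append(t_traj)
            pred_trajs.append(p_traj)

        metrics = forecast_errors(panel, config.sigmas[target])
        metrics["spearman"] = spearman_weighted(panel)
        if range_points:
            labels = [label_reference([tv], rng)[0] for tv, _, rng in range_points]
            metrics["reference"] = auc_reference(
                [pv for _, pv, _ in range_points], labels,
                [rng for _, _, rng in range_points],
            )
        metrics["trend"] = auc_trend(pred_trajs, true_trajs, config.trend_window)
        pool_keys = sorted(truth_cells[target])
        metrics["ks"] = ks_statistic(
            [pred_cells[target][k] for k in pool_keys],
            [truth_cells[target][k] for k in pool_keys],
        )
        per_target[target] = metrics

    for name, (target, rng) in config.events.items():
        points = []
        for idx, (ex, fc) in enumerate(zip(examples, forecasts)):
            truth = ex.truth.get(target, {})
            pred = fc.get(target, {})
            for o in sorted(set(truth) & set(pred)):
                points.append((truth[o], pred[o]))
        if points:
            labels = label_reference([tv for tv, _ in points], rng)
            per_target[name] = {"event": auc_reference([pv for _, pv in points], labels, rng)}

    r2, r2_info = correlation_preservation(truth_cells, pred_cells, targets)
    scaled = [m["scaled_mae"] for m in per_target.values()
              if isinstance(m.get("scaled_mae"), float)]
    pooled = {
        "correlation_r2": r2,
        "correlation_info": {"n_pairs": r2_info["n_pairs"],
                             "skipped": [list(s) for s in r2_info["skipped"]]},
        "mean_scaled_mae": float(np.mean(scaled)) if scaled else None,
        "n_examples": len(examples),
    }
    constants = {
        "sigmas": dict(config.sigmas),
        "reference_ranges": {
            k: (dict(v) if isinstance(v, Mapping) else list(v))
            for k, v in config.reference_ranges.items()
        },
        "trend_window": config.trend_window,
    }
    return MetricReport(per_target=per_target, pooled=pooled, constants=constants)
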