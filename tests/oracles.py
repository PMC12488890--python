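"""Independent literal transcriptions of the metric definitions.

Everything here is written as plain loops straight from the metric
definitions, deliberately sharing no code with the package implementation,
so the test suite can compare the two routes.
"""

from __future__ import annotations

import math


def average_ranks(values: list[float]) -> list[float]:
    """Rank from lowest to highest; tied values share their average rank."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for kk in range(i, j + 1):
            ranks[order[kk]] = avg
        i = j + 1
    return ranks


def mae_nested(truths: list[dict], preds: list[dict]) -> float:
    """(1/n) sum_i (1/T_i) sum_t |v - vhat| over patients with T_i > 0."""
    inner = []
    for tr, pr in zip(truths, preds):
        offs = sorted(set(tr) & set(pr))
        if not offs:
            continue
        inner.append(sum(abs(tr[o] - pr[o]) for o in offs) / len(offs))
    return sum(inner) / len(inner)


def mase_nested(truths: list[dict], preds: list[dict], v0s: list) -> tuple[float | None, int]:
    """MASE over the sub-panel with known v0 and nonzero baseline deviation."""
    num_terms, den_terms = [], []
    excluded = 0
    for tr, pr, v0 in zip(truths, preds, v0s):
        offs = sorted(set(tr) & set(pr))
        if not offs:
            continue
        if v0 is None:
            excluded += 1
            continue
        den = sum(abs(tr[o] - v0) for o in offs) / len(offs)
        if den == 0:
            excluded += 1
            continue
        num_terms.append(sum(abs(tr[o] - pr[o]) for o in offs) / len(offs))
        den_terms.append(den)
    if not num_terms:
        return None, excluded
    n = len(num_terms)
    return (sum(num_terms) / n) / (sum(den_terms) / n), excluded


def smape_nested(truths: list[dict], preds: list[dict]) -> float:
    inner = []
    for tr, pr in zip(truths, preds):
        offs = sorted(set(tr) & set(pr))
        if not offs:
            continue
        total = 0.0
        for o in offs:
            denom = abs(tr[o]) + abs(pr[o])
            if denom != 0:
                total += abs(tr[o] - pr[o]) / denom
        inner.append(total / len(offs))
    return 200.0 * sum(inner) / len(inner)


def spearman_pooled_weighted(truths: list[dict], preds: list[dict]) -> float | None:
    """Single pooled rank function; every point weighted by 1/T_i."""
    vals_t, vals_p, weights = [], [], []
    n = 0
    for tr, pr in zip(truths, preds):
        offs = sorted(set(tr) & set(pr))
        if not offs:
            continue
        n += 1
        for o in offs:
            vals_t.append(tr[o])
            vals_p.append(pr[o])
            weights.append(1.0 / len(offs))
    if len(vals_t) < 2:
        return None
    r_t = average_ranks(vals_t)
    r_p = average_ranks(vals_p)
    mean_t = sum(w * r for w, r in zip(weights, r_t)) / n
    mean_p = sum(w * r for w, r in zip(weights, r_p)) / n
    num = sum(w * (a - mean_t) * (b - mean_p) for w, a, b in zip(weights, r_t, r_p))
    var_t = sum(w * (a - mean_t) ** 2 for w, a in zip(weights, r_t))
    var_p = sum(w * (b - mean_p) ** 2 for w, b in zip(weights, r_p))
    if var_t == 0 or var_p == 0:
        return None
    return num / math.sqrt(var_t * var_p)


def label_value(v: float, lo: float, hi: float) -> str:
    if v < lo:
        return "low"
    if v > hi:
        return "high"
    return "normal"


def pairwise_auc(scores: list[float], positives: list[bool]) -> float | None:
    """Probability a positive outscores a negative; ties count half."""
    pos = [s for s, p in zip(scores, positives) if p]
    neg = [s for s, p in zip(scores, positives) if not p]
    if not pos or not neg:
        return None
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def weighted_auc(aucs: dict[str, float | None], counts: dict[str, int]) -> float | None:
    """Count-weighted mean of the per-class AUCs over available classes."""
    num, den = 0.0, 0
    for cls in ("low", "normal", "high"):
        if aucs[cls] is not None:
            num += aucs[cls] * counts[cls]
            den += counts[cls]
    return num / den if den else None


def trend_label_brute(trajectory: dict[int, float], t: int, s: int) -> str:
    if t < s:
        return "excluded"
    window = list(range(t - s, t + 1))
    for k in window:
        if k not in trajectory:
            return "excluded"
    decreasing = all(trajectory[k + 1] < trajectory[k] for k in window[:-1])
    increasing = all(trajectory[k + 1] > trajectory[k] for k in window[:-1])
    if decreasing:
        return "decreasing"
    if increasing:
        return "increasing"
    return "neither"


def ks_brute(a: list[float], b: list[float]) -> float:
    """Sup-norm distance between the two empirical CDFs."""
    points = sorted(set(a) | set(b))
    d = 0.0
    for x in points:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        d = max(d, abs(fa - fb))
    return d


def pearson(xs: list[float], ys: list[float]) -> float:
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    dx = math.sqrt(sum((x - mx) ** 2 for x in xs))
    dy = math.sqrt(sum((y - my) ** 2 for y in ys))
    return num / (dx * dy)


def correlation_r2_brute(truth_cells, pred_cells, targets, min_points=3):
    tv, pv = [], []
    for i in range(len(targets)):
        for j in range(i + 1, len(targets)):
            a, b = targets[i], targets[j]
            keys = sorted(set(truth_cells.get(a, {})) & set(truth_cells.get(b, {})))
            keys = [k for k in keys if k in pred_cells.get(a, {}) and k in pred_cells.get(b, {})]
            if len(keys) < min_points:
                continue
            ta = [truth_cells[a][k] for k in keys]
            tb = [truth_cells[b][k] for k in keys]
            pa = [pred_cells[a][k] for k in keys]
            pb = [pred_cells[b][k] for k in keys]
            def _sd(v):
                m = sum(v) / len(v)
                return math.sqrt(sum((x - m) ** 2 for x in v))
            if min(_sd(ta), _sd(tb), _sd(pa), _sd(pb)) == 0:
                continue
            tv.append(pearson(ta, tb))
            pv.append(pearson(pa, pb))
    if len(tv) < 2:
        return None
    return pearson(tv, pv) ** 2
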