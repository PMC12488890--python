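"""Seeded synthetic cohorts with the statistical structure the method assumes.

The generator emits sparse, irregularly observed longitudinal lab panels with
correlated variables, patient-specific linear trends, treatment-dependent
post-landmark dynamics, an ordinal performance-status covariate, and heavy
missingness — so every downstream stage (encoding, backends, forecasting,
evaluation) is testable without access to restricted clinical datasets.

Latent model per patient i and variable j on a dense integer bin grid t in
[-H_hist, H_hor] (landmark at t = 0):

    x_ij(t) = b_ij + s_ij * t + treat_ij * max(t, 0) + eta_ij(t)

with baseline b ~ N(mu_b, sd_b), slope s ~ N(mu_s, sd_s) plus an ordinal
status contribution, a treatment-class slope applied after the landmark, and
eta an AR(1) process whose innovations are correlated across variables
through the Cholesky factor of a configured correlation matrix.  Observed
records are the latent values thinned by independent Bernoulli draws (MCAR by
default; an optional value-dependent MNAR mode shifts the keep probability
with the latent z-score).  Values are rounded to one decimal, matching
lab-report granularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from twinforecast.data_model import Observation, PatientRecord, round_value

__all__ = [
    "LatentVariable",
    "CohortConfig",
    "GroundTruth",
    "simulate_cohort",
    "cohort_summary",
    "nsclc_like_config",
    "learnable_config",
]


@dataclass(frozen=True)
class LatentVariable:
    """Latent dynamics of one numeric variable.

    ``noise_sd`` is the stationary standard deviation of the AR(1) component;
    slopes are per bin.
    """

    name: str
    baseline_mean: float
    baseline_sd: float
    slope_mean: float = 0.0
    slope_sd: float = 0.0
    noise_sd: float = 1.0


@dataclass
class CohortConfig:
    n_patients: int
    variables: list[LatentVariable]
    #: cross-variable correlation of AR(1) innovations (and of the stationary
    #: noise); must be positive semi-definite.  None means independent noise.
    noise_corr: Sequence[Sequence[float]] | None = None
    ar_phi: float = 0.5
    #: treatment class -> variable -> extra slope per bin after the landmark
    treatments: dict[str, dict[str, float]] = field(default_factory=dict)
    treatment_probs: dict[str, float] | None = None
    #: variable -> slope shift per unit of the ordinal status score
    status_effects: dict[str, float] = field(default_factory=dict)
    status_levels: Sequence[int] = (0, 1, 2)
    status_probs: Sequence[float] = (0.4, 0.4, 0.2)
    sex_probs: Mapping[str, float] = field(default_factory=lambda: {"F": 0.5, "M": 0.5})
    #: per-variable probability that a latent grid value is NOT observed
    missingness: float | dict[str, float] = 0.944
    #: MNAR shift: keep-probability logit moves by this much per latent z-score
    mnar_strength: float = 0.0
    history_bins: int = 8
    horizon_bins: int = 13
    landmark_variable: str = "therapy"
    seed: int = 0

    def missing_for(self, name: str) -> float:
        m = self.missingness if not isinstance(self.missingness, dict) else self.missingness[name]
        if not 0.0 <= m < 1.0:
            raise ValueError("missingness must lie in [0, 1)")
        return float(m)


@dataclass
class GroundTruth:
    """Dense latent trajectories and per-patient assignments."""

    latent: pd.DataFrame  # patient_id, variable, time, value
    assignments: pd.DataFrame  # patient_id, sex, status, treatment

    def to_csv(self, latent_path, assignments_path) -> None:
        self.latent.to_csv(latent_path, index=False)
        self.assignments.to_csv(assignments_path, index=False)


def _chol(config: CohortConfig, n_vars: int) -> np.ndarray:
    if config.noise_corr is None:
        return np.eye(n_vars)
    corr = np.asarray(config.noise_corr, dtype=float)
    if corr.shape != (n_vars, n_vars):
        raise ValueError("noise_corr shape does not match the number of variables")
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as err:
        raise ValueError("noise correlation matrix is not positive definite") from err


def simulate_cohort(config: CohortConfig) -> tuple[list[PatientRecord], GroundTruth]:
    """Simulate a cohort; fully reproducible from ``config.seed``.

    Returns binned patient records (integer bin times, landmark event at bin
    0) plus the dense ground truth.  A categorical observation of
    ``config.landmark_variable`` at bin 0 records the assigned treatment
    class, so the therapy-start landmark policy applies directly.
    """
    rng = np.random.default_rng(config.seed)
    n, V = config.n_patients, len(config.variables)
    grid = np.arange(-config.history_bins, config.horizon_bins + 1)
    T = grid.size
    L = _chol(config, V)
    phi = config.ar_phi
    if not 0.0 <= phi < 1.0:
        raise ValueError("ar_phi must lie in [0, 1)")

    classes = sorted(config.treatments) or ["none"]
    probs = (
        np.array([config.treatment_probs[c] for c in classes], dtype=float)
        if config.treatment_probs
        else np.full(len(classes), 1.0 / len(classes))
    )
    if n > 0:
        treat_idx = rng.choice(len(classes), size=n, p=probs / probs.sum())
        sexes = rng.choice(list(config.sex_probs), size=n,
                           p=np.array(list(config.sex_probs.values())) / sum(config.sex_probs.values()))
        status = rng.choice(config.status_levels, size=n,
                            p=np.array(config.status_probs) / sum(config.status_probs))
    else:
        treat_idx = np.zeros(0, dtype=int)
        sexes = np.zeros(0, dtype="U1")
        status = np.zeros(0, dtype=int)

    mu_b = np.array([v.baseline_mean for v in config.variables])
    sd_b = np.array([v.baseline_sd for v in config.variables])
    mu_s = np.array([v.slope_mean for v in config.variables])
    sd_s = np.array([v.slope_sd for v in config.variables])
    noise_sd = np.array([v.noise_sd for v in config.variables])

    baselines = mu_b + sd_b * rng.standard_normal((n, V))
    slopes = mu_s + sd_s * rng.standard_normal((n, V))
    for j, var in enumerate(config.variables):
        slopes[:, j] += config.status_effects.get(var.name, 0.0) * status

    # AR(1) noise, stationary start, innovations correlated across variables
    eta = np.empty((n, V, T))
    z0 = rng.standard_normal((n, V)) @ L.T
    eta[:, :, 0] = noise_sd * z0
    innov_scale = noise_sd * np.sqrt(1.0 - phi**2)
    for k in range(1, T):
        zk = rng.standard_normal((n, V)) @ L.T
        eta[:, :, k] = phi * eta[:, :, k - 1] + innov_scale * zk

    treat_effect = np.zeros((n, V))
    for j, var in enumerate(config.variables):
        eff = np.array([config.treatments.get(classes[c], {}).get(var.name, 0.0) for c in treat_idx])
        treat_effect[:, j] = eff

    t = grid[None, None, :]
    latent = (
        baselines[:, :, None]
        + slopes[:, :, None] * t
        + treat_effect[:, :, None] * np.maximum(t, 0)
        + eta
    )

    # Bernoulli thinning (MCAR, optionally value-dependent)
    keep_base = np.array([1.0 - config.missing_for(v.name) for v in config.variables])
    if config.mnar_strength == 0.0:
        keep_p = np.broadcast_to(keep_base[None, :, None], latent.shape)
    else:
        zscore = (latent - mu_b[None, :, None]) / np.where(noise_sd > 0, noise_sd, 1.0)[None, :, None]
        logit = np.log(keep_base / (1.0 - keep_base))[None, :, None] + config.mnar_strength * zscore
        keep_p = 1.0 / (1.0 + np.exp(-logit))
    keep = rng.random(latent.shape) < keep_p

    records = []
    latent_rows = []
    width = max(4, len(str(max(n - 1, 0))))
    for i in range(n):
        pid = f"P{i:0{width}d}"
        statics = {"sex": str(sexes[i]), "status": int(status[i]), "treatment": classes[treat_idx[i]]}
        obs = [Observation(config.landmark_variable, 0, classes[treat_idx[i]])]
        for j, var in enumerate(config.variables):
            for k, tt in enumerate(grid):
                val = round_value(latent[i, j, k])
                latent_rows.append((pid, var.name, int(tt), val))
                if keep[i, j, k]:
                    obs.append(Observation(var.name, int(tt), val))
        records.append(PatientRecord(pid, statics, obs, binned=True))

    truth = GroundTruth(
        latent=pd.DataFrame(latent_rows, columns=["patient_id", "variable", "time", "value"]),
        assignments=pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in records],
                "sex": list(sexes),
                "status": list(status.astype(int)),
                "treatment": [classes[c] for c in treat_idx],
            }
        ),
    )
    return records, truth


def cohort_summary(cohort: Sequence[PatientRecord]) -> dict:
    """Deterministic structural summary of a binned cohort.

    Missingness per variable is measured against each patient's observed time
    span (min..max observed bin, all variables pooled); correlations are
    Pearson over co-observed (patient, bin) value pairs with at least three
    points.
    """
    if not cohort:
        return {"n_patients": 0, "missingness": {}, "correlations": {}, "visits_per_patient": {}}
    numeric_vars = sorted(
        {o.variable for r in cohort for o in r.observations if o.is_numeric}
    )
    observed = {v: 0 for v in numeric_vars}
    total_bins = 0
    visits = {}
    cells: dict[str, dict[tuple[str, int], float]] = {v: {} for v in numeric_vars}
    for r in cohort:
        if not r.observations:
            visits[r.patient_id] = 0
            continue
        times = [int(o.time) for o in r.observations]
        span = max(times) - min(times) + 1
        total_bins += span
        visits[r.patient_id] = len(set(times))
        for o in r.observations:
            if o.is_numeric and o.variable in observed:
                observed[o.variable] += 1
                cells[o.variable][(r.patient_id, int(o.time))] = float(o.value)
    missingness = {
        v: (1.0 - observed[v] / total_bins) if total_bins else 0.0 for v in numeric_vars
    }
    correlations = {}
    for a_i in range(len(numeric_vars)):
        for b_i in range(a_i + 1, len(numeric_vars)):
            a, b = numeric_vars[a_i], numeric_vars[b_i]
            shared = sorted(set(cells[a]) & set(cells[b]))
            if len(shared) >= 3:
                xa = np.array([cells[a][k] for k in shared])
                xb = np.array([cells[b][k] for k in shared])
                if np.std(xa) > 0 and np.std(xb) > 0:
                    correlations[f"{a}|{b}"] = float(np.corrcoef(xa, xb)[0, 1])
    return {
        "n_patients": len(cohort),
        "missingness": missingness,
        "correlations": correlations,
        "visits_per_patient": visits,
    }


def nsclc_like_config(n_patients: int, seed: int = 0) -> CohortConfig:
    """Sparse lung-cancer-like cohort: three lab targets, 94.4% missingness.

    Emulates the structure of a real-world oncology panel: correlated blood
    counts, therapy-dependent post-landmark dynamics (immunotherapy milder
    than chemotherapy on hemoglobin), and an ordinal status covariate.
    """
    return CohortConfig(
        n_patients=n_patients,
        variables=[
            LatentVariable("hemoglobin", 12.5, 1.3, slope_mean=-0.03, slope_sd=0.02, noise_sd=0.7),
            LatentVariable("leukocytes", 8.0, 2.0, slope_mean=0.02, slope_sd=0.03, noise_sd=1.4),
            LatentVariable("neutrophils", 5.2, 1.6, slope_mean=0.02, slope_sd=0.03, noise_sd=1.2),
        ],
        noise_corr=[[1.0, 0.25, 0.35], [0.25, 1.0, 0.8], [0.35, 0.8, 1.0]],
        ar_phi=0.5,
        treatments={
            "chemotherapy": {"hemoglobin": -0.12, "leukocytes": 0.10, "neutrophils": 0.08},
            "immunotherapy": {"hemoglobin": 0.02, "leukocytes": -0.02, "neutrophils": -0.02},
        },
        status_effects={"hemoglobin": -0.02},
        missingness=0.944,
        history_bins=8,
        horizon_bins=13,
        seed=seed,
    )


def learnable_config(n_patients: int, seed: int = 0) -> CohortConfig:
    """Compact cohort with strongly learnable dynamics for skill recovery.

    Short history and horizon, moderate missingness, and pronounced planted
    structure: a shared downward hemoglobin drift that is much steeper under
    chemotherapy than immunotherapy, an opposite leukocyte drift, and AR(1)
    measurement-scale noise large relative to the between-patient baseline
    spread.  Under these dynamics a forecaster that has learned the
    class-conditional trends beats copying the last (noisy, often stale)
    observation forward, which is what the learning-skill checks probe.
    """
    return CohortConfig(
        n_patients=n_patients,
        variables=[
            LatentVariable("hemoglobin", 12.0, 0.6, slope_mean=-0.10, slope_sd=0.03, noise_sd=1.2),
            LatentVariable("leukocytes", 8.0, 0.8, slope_mean=0.15, slope_sd=0.05, noise_sd=1.8),
        ],
        noise_corr=[[1.0, -0.3], [-0.3, 1.0]],
        ar_phi=0.6,
        treatments={
            "chemotherapy": {"hemoglobin": -0.35, "leukocytes": 0.45},
            "immunotherapy": {"hemoglobin": 0.10, "leukocytes": -0.10},
        },
        status_effects={"hemoglobin": -0.05, "leukocytes": 0.05},
        missingness=0.55,
        history_bins=4,
        horizon_bins=6,
        seed=seed,
    )
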