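import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from twinforecast.data_model import ForecastExample, Observation, PatientRecord, TaskConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_task():
    return TaskConfig(
        targets=("hemoglobin", "leukocytes"),
        horizon_offsets=(1, 2, 3, 4),
        unit_label="week",
        landmark_policy="therapy_start",
        landmark_variable="therapy",
    )


def make_example(truth=None, history=None, baselines=None, statics=None,
                 horizon=(1, 2, 3, 4), patient_id="P0"):
    """Small hand-built forecast example for codec and metric tests."""
    truth = truth if truth is not None else {"hemoglobin": {1: 11.2, 3: 10.8}}
    history = history if history is not None else [
        Observation("hemoglobin", -2, 12.0),
        Observation("leukocytes", -1, 6.5),
        Observation("hemoglobin", 0, 11.8),
    ]
    baselines = baselines if baselines is not None else {"hemoglobin": 11.8}
    statics = statics if statics is not None else {"sex": "F", "treatment": "chemotherapy"}
    return ForecastExample(
        patient_id=patient_id, t0=0, statics=statics, history=history,
        baseline_values=baselines, truth=truth, horizon_offsets=tuple(horizon),
    )


def random_example(rng, targets=("hemoglobin", "leukocytes"), horizon=(1, 2, 3, 4),
                   p_cell=0.6, n_history=6):
    """Randomized example with one-decimal values, for round-trip tests."""
    history = []
    for _ in range(n_history):
        var = targets[int(rng.integers(len(targets)))]
        t = -int(rng.integers(0, 5))
        history.append(Observation(var, t, float(np.round(rng.uniform(3, 18), 1))))
    seen = {}
    for o in history:
        if o.time <= 0 and (o.variable not in seen or o.time >= seen[o.variable][0]):
            seen[o.variable] = (o.time, o.value)
    baselines = {v: val for v, (_, val) in seen.items()}
    truth = {}
    for target in targets:
        cells = {
            int(o): float(np.round(rng.uniform(3, 18), 1))
            for o in horizon if rng.random() < p_cell
        }
        if cells:
            truth[target] = cells
    if not truth:
        truth = {targets[0]: {int(horizon[0]): float(np.round(rng.uniform(3, 18), 1))}}
    return ForecastExample(
        patient_id=f"P{int(rng.integers(1e6))}", t0=0,
        statics={"sex": "M" if rng.random() < 0.5 else "F"},
        history=sorted(history, key=lambda o: (o.time, o.variable)),
        baseline_values=baselines, truth=truth, horizon_offsets=tuple(horizon),
    )


def make_record(patient_id="P0", statics=None, observations=(), binned=False):
    return PatientRecord(patient_id, statics or {}, list(observations), binned=binned)
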