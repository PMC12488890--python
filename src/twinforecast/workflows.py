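"""Config-driven orchestration of the full forecasting pipeline.

Stages: simulate (or ingest) -> bin -> split -> outlier-filter -> landmark ->
encode -> train backend -> sample k trajectories -> aggregate -> evaluate.
Every stage draws its randomness from a child of the single experiment seed,
so a run is reproducible artifact-for-artifact; a manifest with content
hashes is written alongside the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from twinforecast import data_model as dm
from twinforecast import encoding as enc
from twinforecast import evaluation as ev
from twinforecast import forecasting as fc
from twinforecast import synthetic_cohort as sc
from twinforecast.lm_backend import BackendConfig, EchoBackend, LMBackend, TinyLMBackend

_STAGES = ("cohort", "split", "backend", "sampling", "ablation", "zero_shot")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage 31-bit seeds derived from the experiment seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(_STAGES, children)}


# ---------------------------------------------------------------------------
# Experiment configuration
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    scenario: str = "learnable"  # learnable | nsclc_like
    n_patients: int = 500
    seed: int = 0
    backend: str = "echo"  # echo | tiny
    k: int = 30
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    strata: tuple[str, ...] | None = ("treatment",)
    trend_window: int = 3
    backend_config: BackendConfig = field(default_factory=BackendConfig)
    ablation_subsample: int = 200
    misspelling_grid: tuple[int, ...] = (0, 5, 25)
    masking_grid: tuple[float, ...] = (0.0, 0.4, 0.8)

    def cohort_config(self, seed: int) -> sc.CohortConfig:
        builder = {"learnable": sc.learnable_config, "nsclc_like": sc.nsclc_like_config}
        if self.scenario not in builder:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        return builder[self.scenario](self.n_patients, seed=seed)

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "backend_config" in d and isinstance(d["backend_config"], dict):
            d["backend_config"] = BackendConfig(**d["backend_config"])
        for key in ("fractions", "strata", "misspelling_grid", "masking_grid"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def make_backend(config: ExperimentConfig, template: enc.PromptTemplate,
                 seed: int) -> LMBackend:
    if config.backend == "echo":
        return EchoBackend(template)
    if config.backend == "tiny":
        return TinyLMBackend(replace(config.backend_config, seed=seed))
    raise ValueError(f"unknown backend {config.backend!r}")


# ---------------------------------------------------------------------------
# Prepared data (shared by run and ablate)
# ---------------------------------------------------------------------------


@dataclass
class PreparedData:
    task: dm.TaskConfig
    template: enc.PromptTemplate
    split: dm.SplitManifest
    outliers: dm.OutlierReport
    train_examples: list[dm.ForecastExample]
    test_examples: list[dm.ForecastExample]
    train_encoded: list[enc.EncodedExample]
    test_encoded: list[enc.EncodedExample]
    stats: fc.TrainingStats
    metric_config: ev.MetricConfig
    accounting: dict


def prepare(config: ExperimentConfig, seeds: dict[str, int]) -> PreparedData:
    """Simulate, split, filter and encode; everything before model training."""
    cohort_cfg = config.cohort_config(seeds["cohort"])
    cohort, _truth = sc.simulate_cohort(cohort_cfg)
    targets = tuple(v.name for v in cohort_cfg.variables)
    task = dm.TaskConfig(
        targets=targets,
        horizon_offsets=tuple(range(1, cohort_cfg.horizon_bins + 1)),
        unit_label="week",
        landmark_policy="therapy_start",
        landmark_variable=cohort_cfg.landmark_variable,
    )
    strata = list(config.strata) if config.strata else None
    split = dm.split_patients(cohort, config.fractions, strata=strata, seed=seeds["split"])
    train_vals = dm.collect_target_values(cohort, targets, split.train)
    cohort, outliers = dm.filter_outliers_two_step(train_vals, cohort)
    by_split = {pid: s for s in ("train", "val", "test") for pid in getattr(split, s)}
    grouped: dict[str, list[dm.PatientRecord]] = {"train": [], "val": [], "test": []}
    for record in cohort:
        grouped[by_split[record.patient_id]].append(record)
    train_examples, acc_train = dm.build_examples(grouped["train"], task)
    test_examples, acc_test = dm.build_examples(grouped["test"], task)
    template = enc.PromptTemplate.for_task(task)
    train_encoded = [enc.encode_example(ex, task, template) for ex in train_examples]
    test_encoded = [enc.encode_example(ex, task, template) for ex in test_examples]
    stats = fc.TrainingStats.from_examples(train_examples, targets)
    registry = dm.nsclc_registry()
    ranges = {
        t: registry[t].reference_range for t in targets
        if t in registry and registry[t].reference_range is not None
    }
    metric_config = ev.MetricConfig(
        sigmas={t: outliers.sigma(t) for t in targets},
        reference_ranges=ranges,
        trend_window=config.trend_window,
    )
    accounting = {"train": acc_train, "test": acc_test,
                  "split_sizes": {s: len(getattr(split, s)) for s in ("train", "val", "test")}}
    return PreparedData(task, template, split, outliers, train_examples, test_examples,
                        train_encoded, test_encoded, stats, metric_config, accounting)


# ---------------------------------------------------------------------------
# Forecast + evaluate
# ---------------------------------------------------------------------------


def forecast_examples(backend: LMBackend, encoded: Sequence[enc.EncodedExample],
                      stats: fc.TrainingStats, targets: Sequence[str], k: int,
                      seed: int) -> tuple[list[fc.Trajectory], dict, list[fc.TrajectoryEnsemble]]:
    """Sample, decode and mean-aggregate trajectories for a list of examples."""
    forecasts: list[fc.Trajectory] = []
    ensembles: list[fc.TrajectoryEnsemble] = []
    parse_counts = {"ok": 0, "partial": 0, "failed": 0}
    n_fallback_cells = 0
    for i, pair in enumerate(encoded):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        ensemble = fc.sample_trajectories(backend, pair, k=k, rng=rng)
        fallback, _ = fc.copy_forward_forecast(pair.example, stats, targets)
        agg = fc.aggregate_mean(ensemble, fallback=fallback)
        forecasts.append(agg.values)
        ensembles.append(ensemble)
        n_fallback_cells += len(agg.fallback_cells)
        for f in ensemble.forecasts:
            parse_counts[f.parse_status] += 1
    accounting = {"parse_counts": parse_counts, "n_fallback_cells": n_fallback_cells,
                  "k": k, "n_examples": len(encoded)}
    return forecasts, accounting, ensembles


@dataclass
class RunResult:
    reports: dict[str, ev.MetricReport]
    accounting: dict
    prepared: PreparedData
    out_dir: Path | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_experiment(config: ExperimentConfig, out_dir=None,
                   keep_ensembles: bool = False) -> RunResult:
    """Execute the full pipeline; optionally write artifacts + manifest."""
    seeds = stage_seeds(config.seed)
    prepared = prepare(config, seeds)
    targets = list(prepared.task.targets)

    backend = make_backend(config, prepared.template, seeds["backend"])
    t0 = time.time()
    backend.fine_tune(prepared.train_encoded)
    train_seconds = time.time() - t0

    forecasts, fc_acc, ensembles = forecast_examples(
        backend, prepared.test_encoded, prepared.stats, targets, config.k, seeds["sampling"]
    )
    reports = {
        config.backend: ev.evaluate_forecasts(prepared.test_examples, forecasts,
                                              prepared.metric_config, targets)
    }
    cf_forecasts = [
        fc.copy_forward_forecast(ex, prepared.stats, targets)[0]
        for ex in prepared.test_examples
    ]
    reports["copy_forward"] = ev.evaluate_forecasts(
        prepared.test_examples, cf_forecasts, prepared.metric_config, targets)
    linear = fc.LinearReferenceModel(targets, list(prepared.task.horizon_offsets))
    linear.fit(prepared.train_examples, prepared.stats)
    lin_forecasts = [linear.predict(ex)[0] for ex in prepared.test_examples]
    reports["linear"] = ev.evaluate_forecasts(
        prepared.test_examples, lin_forecasts, prepared.metric_config, targets)

    accounting = dict(prepared.accounting)
    accounting["forecast"] = fc_acc
    accounting["train_seconds"] = round(train_seconds, 2)
    accounting["stage_seeds"] = seeds

    result = RunResult(reports=reports, accounting=accounting, prepared=prepared)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        prepared.split.to_json(out / "splits.json")
        prepared.outliers.to_json(out / "outlier_bounds.json")
        enc.write_corpus(prepared.train_encoded, out / "train_corpus.jsonl")
        enc.write_corpus(prepared.test_encoded, out / "test_corpus.jsonl")
        for name, report in reports.items():
            report.to_json(out / f"metrics_{name}.json")
        (out / "accounting.json").write_text(json.dumps(accounting, indent=2, sort_keys=True))
        if keep_ensembles:
            with open(out / "ensembles.jsonl", "w") as fh:
                for pair, ensemble in zip(prepared.test_encoded, ensembles):
                    fh.write(json.dumps({
                        "patient_id": pair.example.patient_id,
                        "t0": pair.example.t0,
                        "texts": ensemble.raw_texts,
                    }) + "\n")
        files = sorted(p for p in out.iterdir() if p.name != "manifest.json" and p.is_file())
        manifest = {p.name: _sha256(p) for p in files}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        result.out_dir = out
    return result


# ---------------------------------------------------------------------------
# Ablations: misspellings and added missingness
# ---------------------------------------------------------------------------


def run_ablation(config: ExperimentConfig, axis: str,
                 grid: Sequence | None = None) -> dict:
    """Repeat evaluation over a perturbation grid on a test subsample.

    ``axis`` is "misspellings" (n operations injected into each prompt) or
    "missingness" (fraction of history observations masked before encoding).
    Grid value 0 reproduces the unperturbed subsample report exactly.
    """
    if axis not in ("misspellings", "missingness"):
        raise ValueError(f"unknown ablation axis {axis!r}")
    if grid is None:
        grid = config.misspelling_grid if axis == "misspellings" else config.masking_grid
    grid = list(grid)
    if not grid:
        raise ValueError("ablation grid is empty")
    seeds = stage_seeds(config.seed)
    prepared = prepare(config, seeds)
    targets = list(prepared.task.targets)
    backend = make_backend(config, prepared.template, seeds["backend"])
    backend.fine_tune(prepared.train_encoded)

    rng = np.random.default_rng(seeds["ablation"])
    n_sub = min(config.ablation_subsample, len(prepared.test_examples))
    idx = sorted(rng.choice(len(prepared.test_examples), size=n_sub, replace=False))
    sub_examples = [prepared.test_examples[i] for i in idx]

    reports: dict = {}
    for value in grid:
        perturb_rng = np.random.default_rng(np.random.SeedSequence([seeds["ablation"], 1]))
        encoded = []
        for ex in sub_examples:
            if axis == "missingness":
                ex_used = enc.mask_observations(ex, float(value), perturb_rng)
                pair = enc.encode_example(ex_used, prepared.task, prepared.template)
            else:
                pair = enc.encode_example(ex, prepared.task, prepared.template)
                if int(value) > 0:
                    pair.input_text = enc.inject_misspellings(
                        pair.input_text, int(value), perturb_rng)
            encoded.append(pair)
        forecasts, _, _ = forecast_examples(
            backend, encoded, prepared.stats, targets, config.k, seeds["sampling"])
        reports[value] = ev.evaluate_forecasts(
            sub_examples, forecasts, prepared.metric_config, targets)
    return reports


# ---------------------------------------------------------------------------
# Zero-shot forecasting of a variable not trained on
# ---------------------------------------------------------------------------


def run_zero_shot(backend: LMBackend, examples: Sequence[dm.ForecastExample],
                  template: enc.PromptTemplate, variable: str,
                  offsets: Sequence[int], registry: dm.VariableRegistry,
                  k: int, seed: int) -> dict:
    """Prompt a tuned backend for a new variable; decode with accounting."""
    parse_counts = {"ok": 0, "partial": 0, "failed": 0}
    extracted = []
    for i, ex in enumerate(examples):
        prompt, schema = enc.build_zero_shot_prompt(ex, template, variable, offsets, registry)
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        texts = backend.generate(prompt, k, rng)
        decoded = [enc.decode_forecast(t, schema) for t in texts]
        for d in decoded:
            parse_counts[d.parse_status] += 1
        ensemble = fc.TrajectoryEnsemble(example=ex, forecasts=decoded, raw_texts=texts, k=k)
        extracted.append(fc.aggregate_mean(ensemble).values)
    n_total = k * len(examples)
    return {
        "variable": variable,
        "parse_counts": parse_counts,
        "extraction_rate": (parse_counts["ok"] + parse_counts["partial"]) / n_total
        if n_total else None,
        "forecasts": extracted,
    }
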