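# Methods

## The forecasting problem

`twinforecast` forecasts multivariate clinical trajectories — laboratory
panels, vital signs, cognitive scores — from sparse, irregular longitudinal
patient records. Each patient's record is cut at a *landmark time* t0 (the
start of a therapy line, a fixed number of history bins, or the first
observation): everything at or before t0 is model input, and the task is to
predict each target variable at integer horizon offsets 1..H after t0.
Real-world records of this kind are extremely sparse (the lung-cancer-like
synthetic preset uses 94.4% missingness on the dense bin grid), so the
pipeline never imputes: missing cells are simply absent from the model input,
and only observed future cells are ever scored.

The distinguishing mechanism is a **text channel**: records are serialized
into a structured natural-language prompt, the forecast is produced by a
generative language model as JSON text, k completions are sampled per
example, and the per-cell arithmetic mean of the parsed samples is the final
forecast. Any text-in/text-out model can stand behind this contract; the
package ships a deterministic echo backend, a tiny trainable causal
transformer, and an adapter interface for external instruction-tuned LLMs.

## Preprocessing

- **Binning** keeps, per (variable, bin), the value with the latest raw
  timestamp in the bin ("last observed value"). Binned records are fixed
  points of the operation, making it idempotent.
- **Two-step outlier filtering**, fitted on training-split target values
  only and applied to all splits: step 1 removes values outside mean ± 3 sd;
  step 2 recomputes mean and sd on the survivors and clips the remainder
  into the recomputed mean ± 3 sd. Sample standard deviations (ddof = 1) are
  used. The per-target sd after both steps is the σ used by scaled MAE. A
  zero recomputed sd disables clipping for that variable (flagged).
  The "three standard deviations" rule is centered on the mean (the standard
  z-score convention). Clip bounds are snapped to the package-wide
  one-decimal value grid — see *Numerical choices*.
- **Splitting** is at the patient level (default 80/10/10), optionally
  stratified on static attributes with largest-remainder apportionment
  within each stratum; strata smaller than the number of splits degrade to
  random allocation with a warning.
- **Landmarking** emits one example per landmark; examples with no observed
  future target cell at all are dropped (counted). The baseline value v0 of
  a target is its last observed value at or before t0; targets never
  observed pre-landmark carry no v0 — forecasters fall back to the
  training-split median (flagged) and such patients are excluded from MASE
  (counted).

## Encoding and decoding

Prompts have four sections — patient history (one line per bin, only
observed `variable = value` pairs), patient information (statics), forecast
dates, and the task instruction. Offsets are rendered as "week k" / "hour k"
etc.; the exact header wording is a configuration object
(`PromptTemplate`), so alternates are pluggable. Targets are JSON:
`{"variable": {"week 1": value, ...}}`, containing only observed cells for
training pairs.

Decoding is tolerant with full accounting: the first parseable JSON object
in the generated text is used; if generation stopped mid-object the decoder
tries closing open braces; if strict parsing extracts nothing, a pairwise
regex scan salvages `"label": number` cells, attributing each to the nearest
preceding target-name mention. Extraction status is ok / partial / failed
with expected and extracted cell counts; failures are data, never
exceptions.

Two input perturbations support robustness studies: `inject_misspellings`
applies n character operations (adjacent swap, insertion, deletion,
replacement; insert/replace characters uniform over ASCII letters+digits)
uniformly over the whole prompt — an operation that needs characters on an
empty string is re-drawn as an insertion; `mask_observations` removes each
history observation independently with a configured probability, leaving
truth and evaluation constants untouched. "Perturbation" is implemented as
an adjacent-character swap — the standard typo model distinct from the other
three operations.

## Backends

All backends implement `fine_tune(pairs)` and `generate(prompt, k, rng)`.

- **Echo** parses the prompt the way any model would read it and returns k
  identical JSON completions repeating each target's last observed history
  value (training-corpus median if absent). It exists to pin down the
  pipeline: end to end, the echo run must be bit-identical to the native
  copy-forward baseline, so any drift in encoding, decoding, aggregation or
  evaluation breaks an exact test.
- **Tiny causal LM**: a decoder-only transformer written in numpy (forward,
  hand-derived backward, Adam, KV-cached nucleus sampling), gradient-checked
  against numerical derivatives. Defaults: 2 layers, d_model 64, 2 heads,
  learned positions, ReLU MLP, float32. The tokenizer splits text into
  words, punctuation, whitespace runs and *whole decimal numbers*, so a
  one-decimal lab value is a single token and predicting a value is one
  softmax over the value vocabulary. Training minimizes next-token cross
  entropy **masked to the target text** (the gradient at input positions is
  exactly zero), with right padding, per-epoch shuffling, gradient-norm
  clipping at 1.0, and a recorded loss curve. Sampling defaults: temperature
  1.0, top-p 0.9; both are config knobs, as are all training
  hyperparameters.
- **External adapter**: interface only — a completion callable (API client,
  local server, test fake); no weights ship with the package, and
  fine-tuning happens out of process.

Sequences longer than `max_len` follow a declared truncation policy:
`error` rejects the pair with its index, `left` drops the oldest history
tokens.

## Forecasting

`sample_trajectories` draws k completions (default 30) and decodes each with
accounting; raw texts are retained for audit. `aggregate_mean` averages
parsed values per (target, offset); a cell with no parsed value takes the
copy-forward value, flagged, so evaluation denominators stay comparable
across models. Partial parses contribute their parsed cells. When all parsed
values of a cell are equal, the mean short-circuits to that exact value —
this makes the mean exactly idempotent and is what lets the echo pipeline
reproduce copy-forward bit for bit.

`oracle_best_trajectory` selects, per example, the sampled trajectory with
the lowest per-example scaled MAE against the truth — a hindsight lower
bound on what better aggregation could achieve, reported alongside the mean
aggregate. Candidates are *fully scorable* samples: those whose parsed cells
cover every observed truth cell (trained backends imitate the sparse
training targets, so their completions are legitimately partial against the
full-grid decode schema). Ties break to the lowest sample index.

Native references: **copy-forward** repeats v0 (training median when
absent, flagged) across the horizon; the **linear reference** fits ordinary
least squares per (target, offset) on [last observed value, time since that
observation, one-hot categorical statics, numeric statics], falling back to
copy-forward (flagged) when fewer than two training rows exist or the fit is
degenerate.

## Evaluation

Regression metrics use patient-nested averaging — an inner mean over each
patient's T_i observed future points, an outer mean over the n patients:

    MAE        = (1/n) Σ_i (1/T_i) Σ_t |v_t^(i) − v̂_t^(i)|
    scaled MAE = MAE / σ              (σ: post-filtering training sd)
    MASE       = MAE / [(1/n) Σ_i (1/T_i) Σ_t |v_t^(i) − v0^(i)|]
    SMAPE      = (200/n) Σ_i (1/T_i) Σ_t |v_t − v̂_t| / (|v_t| + |v̂_t|)

with zero-denominator SMAPE terms skipped via an indicator, and MASE
computed on the sub-panel of patients with a known v0 and a nonzero
baseline deviation (exclusions counted). The weighted Spearman coefficient
assigns a single pooled rank function (average ranks for ties) across all
patients' values — once for truths, once for predictions — and weights every
point by 1/T_i in the correlation sums. Pooling one rank function across
patients is unusual but deliberate; it is transcribed literally and
cross-checked against an independent loop implementation in the tests.

Classification derives events from reference intervals [v_min, v_max]
(sex-conditional where clinically defined, e.g. hemoglobin 14–18 g/dL for
male and 12–16 g/dL for female patients): a value is low below v_min, high
above v_max, normal otherwise — boundary equality counts as normal (the
closed-interval reading; strict inequalities leave equality undefined).
Each binary task (low / high / normal vs rest) is scored with a
Mann–Whitney AUC (half credit for ties) using signed threshold distances as
prediction scores — v_min − v̂ for low, v̂ − v_max for high,
min(v̂ − v_min, v_max − v̂) for normal — monotone in the predicted value and
threshold-free. The weighted AUC is the count-weighted mean over available
classes. Single-sided event thresholds (e.g. a hemoglobin bleed at
v_min = 7.5 g/dL) are ordinary config entries with an open upper bound — no
separate code path.

Trend labels require strictly consistent consecutive changes over a
lookback window of s time units (3 weekly bins by default): a point at time
t is decreasing only if every consecutive pair in [t−s, t] strictly
decreases; points with t < s, or whose window is not completely observed on
the unit grid, are excluded (counted) — the same rule on truth and
predictions. The trend AUC scores a point by its worst-case consecutive
margin over the window, positive exactly when the strict label holds.
Trajectories are anchored at offset 0 with v0 on both sides when available
so the first window can close.

Distributional checks: the two-sample Kolmogorov–Smirnov statistic per
target (predictions pooled at the truth-observed cells against the observed
truths, so both pools have the same support in time), and a
correlation-preservation R² — the squared Pearson correlation between the
vector of truth pair-correlations and the vector of prediction
pair-correlations over all target pairs with at least 3 co-observed cells
and nonzero variance (pairs failing that are flagged; fewer than 2 valid
pairs gives a missing value, which is always the case for two-target
tasks).

Statistical significance machinery for model comparisons is deliberately
out of scope; reports carry point estimates.

## Synthetic cohorts

The generator exists so every stage is testable without access to
restricted clinical data. Per patient and variable it draws a baseline and
a per-bin slope from Gaussians, adds a treatment-class slope after the
landmark and an ordinal-status slope contribution, and overlays AR(1) noise
whose innovations are correlated across variables through the Cholesky
factor of a configured correlation matrix (non-positive-definite matrices
are rejected). Observations are the latent values on the integer bin grid,
rounded to one decimal, thinned by independent Bernoulli draws — MCAR by
default; an optional MNAR mode shifts the keep-probability logit with the
latent z-score, since non-random missingness is the realistic regime and
robustness experiments need both. A categorical therapy observation at bin
0 carries the treatment class, so therapy-start landmarking applies
directly.

Two presets:

- `nsclc_like_config`: three correlated blood-count targets, 94.4%
  missingness, 8 history + 13 horizon weekly bins, chemotherapy vs
  immunotherapy effects (chemotherapy depresses hemoglobin faster), ordinal
  status effect. This mirrors the *structure* of real oncology panels —
  sparsity, correlation, treatment-dependent drift — not any disease
  biology; a linear-trend + AR(1) latent process is deliberately chosen over
  a disease-specific model because it is exactly rich enough to plant the
  correlations, trends and effects the evaluation must detect.
- `learnable_config`: a compact two-target scenario for skill-recovery
  experiments — short history (4 bins) and horizon (6 bins), 55%
  missingness, strong planted structure (hemoglobin drifts −0.10/week
  baseline and −0.35/week extra under chemotherapy vs +0.10 under
  immunotherapy; leukocytes mirror it; baseline spread 0.6–0.8 sd), and
  AR(1) noise (sd 1.2–1.8, φ = 0.6) large relative to the between-patient
  spread. Under these dynamics the last observed value is a noisy, often
  stale predictor, so a model that learns the class-conditional trends
  through the text channel measurably beats copy-forward — while a
  copy-forward-equivalent model cannot, which is the point of the check.

What passing tests on synthetic data do **not** show: fidelity to any real
disease's dynamics, to real missingness mechanisms (the generator's MCAR
default is a simplification its own documentation flags), or to the
behavior of billion-parameter LLMs; the tiny backend exercises the
mechanism — text-channel learning with output-masked loss and ensemble
aggregation — not the scale.

## Numerical choices

- All numeric observation values, two-step clip bounds, and training-split
  medians live on a one-decimal grid (lab-report granularity). Because a
  one-decimal double renders and re-parses exactly, encode→decode is a
  bit-level round trip and the echo/copy-forward equivalence is exact
  rather than approximate.
- Values are rendered with one decimal in prompts and JSON; Python's
  shortest-repr JSON serialization preserves them exactly.
- The mean over identical samples short-circuits (exact idempotence).
- Mann–Whitney AUCs are computed from tie-averaged ranks.
- The tiny LM trains in float32; gradient checks run in float64.
- Stage seeds are spawned from the single experiment seed via
  `numpy.random.SeedSequence` children (31-bit), fixed order; per-example
  sampling seeds derive from the sampling stage seed and the example index,
  so k-sample draws are independent across examples but fully reproducible.

## Problem sizes used by the shipped experiments

The learning-skill experiments train the tiny backend (2 layers, d_model
64, 12 epochs, batch 32) on cohorts of 1,200–2,000 patients with k = 30
samples per test example; the text-channel equivalence check uses 100
patients with k = 30; generator-fidelity checks use 500–1,000 patients;
codec checks use 1,000 random examples. These sizes give stable estimates
for every reported quantity while keeping a full run in the minutes range
on a single CPU core.

## Known limitations

- The tiny backend's completions imitate the sparse training targets, so
  per-sample forecasts are partial; aggregation and the oracle analysis
  handle this explicitly, but per-sample metrics over the full grid are not
  available.
- The linear reference uses only last-value/recency/static features; it is
  a reference point, not a tuned competitor.
- `correlation_preservation` needs at least three targets to produce a
  value.
- The explanation parser does word-boundary dictionary matching; variable
  names that contain other registry names (e.g. ratios) can double-match.
- The paper-scale deep baselines, significance testing between models, and
  real-data ingestion pipelines are out of scope by design.
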