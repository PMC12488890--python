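"""Serialization of forecast examples to prompt/target text and back.

The input prompt has four sections — patient history, patient information,
forecast dates, and the task instruction — with one history line per time
bin listing only the observed variable=value pairs (missing entries are
simply absent, no imputation).  Targets are encoded as a JSON object mapping
each variable to its dated forecasts; decoding tolerantly locates the first
JSON object in generated text and extracts whatever schema cells it can,
with full accounting.

Two input perturbations used in robustness studies live here as well:
character-level misspellings (swap / insert / delete / replace over ASCII
letters and digits) and random masking of history observations on top of the
data's intrinsic missingness.
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from twinforecast.data_model import (
    ForecastExample,
    Observation,
    TaskConfig,
    VariableRegistry,
    VALUE_DECIMALS,
)

_ALPHABET = string.ascii_letters + string.digits


# ---------------------------------------------------------------------------
# Template and schema
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PromptTemplate:
    """Deterministic rendering configuration for prompts and targets."""

    unit_label: str = "week"
    history_header: str = "Patient history:"
    statics_header: str = "Patient information:"
    dates_header: str = "Forecast dates:"
    task_header: str = "Task:"
    decimals: int = VALUE_DECIMALS

    @classmethod
    def for_task(cls, task: TaskConfig) -> "PromptTemplate":
        return cls(unit_label=task.unit_label)

    def format_value(self, value) -> str:
        if isinstance(value, (int, float)):
            return f"{float(value):.{self.decimals}f}"
        return str(value)

    def offset_label(self, offset: int) -> str:
        return f"{self.unit_label} {offset}"

    def instruction(self, targets: Sequence[str]) -> str:
        names = ", ".join(targets)
        return (
            f"Predict the values of {names} at the forecast dates listed above. "
            'Respond with a JSON object of the form {"variable": {"'
            f"{self.unit_label}"
            ' 1": value, ...}} containing every forecast date for every variable.'
        )

    # -- prompt parsing helpers (used by the echo backend and tests) --------

    def parse_history_last_values(self, prompt: str) -> dict[str, float]:
        """Last rendered numeric value per variable in the history section."""
        lines = _section_lines(prompt, self.history_header,
                              (self.statics_header, self.dates_header, self.task_header))
        last: dict[str, float] = {}
        pat = re.compile(rf"^{re.escape(self.unit_label)} (-?\d+): (.*)$")
        for line in lines:
            m = pat.match(line)
            if not m:
                continue
            for part in m.group(2).split("; "):
                if " = " not in part:
                    continue
                var, val = part.split(" = ", 1)
                try:
                    last[var] = float(val)
                except ValueError:
                    continue
        return last

    def parse_forecast_offsets(self, prompt: str) -> list[int]:
        lines = _section_lines(prompt, self.dates_header, (self.task_header,))
        labels = ", ".join(lines).split(", ")
        offsets = []
        pat = re.compile(rf"^{re.escape(self.unit_label)} (-?\d+)$")
        for label in labels:
            m = pat.match(label.strip())
            if m:
                offsets.append(int(m.group(1)))
        return offsets

    def parse_instruction_targets(self, prompt: str) -> list[str]:
        lines = _section_lines(prompt, self.task_header, ())
        text = " ".join(lines)
        m = re.search(r"Predict the values of (.*?) at the forecast dates", text)
        if not m:
            return []
        return [t.strip() for t in m.group(1).split(",") if t.strip()]


def _section_lines(prompt: str, header: str, stop_headers: tuple[str, ...]) -> list[str]:
    lines = prompt.splitlines()
    out: list[str] = []
    active = False
    for line in lines:
        if line == header:
            active = True
            continue
        if line in stop_headers:
            if active:
                break
            continue
        if active:
            out.append(line)
    return out


@dataclass(frozen=True)
class ForecastSchema:
    """Ordered (target, horizon offset) cells expected in decoded output."""

    targets: tuple[str, ...]
    offsets: tuple[int, ...]
    unit_label: str = "week"

    def cells(self) -> list[tuple[str, int]]:
        return [(t, o) for t in self.targets for o in self.offsets]

    def offset_label(self, offset: int) -> str:
        return f"{self.unit_label} {offset}"

    def to_dict(self) -> dict:
        return {"targets": list(self.targets), "offsets": list(self.offsets),
                "unit_label": self.unit_label}

    @classmethod
    def from_dict(cls, d: dict) -> "ForecastSchema":
        return cls(tuple(d["targets"]), tuple(int(o) for o in d["offsets"]), d["unit_label"])


@dataclass
class EncodedExample:
    input_text: str
    target_text: str
    schema: ForecastSchema
    example: ForecastExample | None = None

    def to_dict(self) -> dict:
        return {"input": self.input_text, "target": self.target_text,
                "schema": self.schema.to_dict()}


@dataclass
class DecodedForecast:
    """Values extracted from one generated text, with parse accounting."""

    values: dict[str, dict[int, float]]
    parse_status: str  # ok | partial | failed
    n_expected: int
    n_extracted: int


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------


def encode_input(example: ForecastExample, template: PromptTemplate,
                 targets: Sequence[str] | None = None) -> str:
    """Render the four-section input prompt for one example.

    ``targets`` is the ordered list named in the task instruction; it
    defaults to the example's own target universe (truth plus baselines).
    """
    lines: list[str] = [template.history_header]
    by_time: dict[int, list[Observation]] = {}
    for obs in example.history:
        by_time.setdefault(int(obs.time), []).append(obs)
    for t in sorted(by_time):
        pairs = "; ".join(
            f"{o.variable} = {template.format_value(o.value)}" for o in by_time[t]
        )
        lines.append(f"{template.offset_label(t)}: {pairs}")
    lines.append(template.statics_header)
    statics = "; ".join(f"{k} = {template.format_value(v)}" for k, v in sorted(example.statics.items()))
    if statics:
        lines.append(statics)
    lines.append(template.dates_header)
    lines.append(", ".join(template.offset_label(o) for o in example.horizon_offsets))
    lines.append(template.task_header)
    if targets is None:
        targets = sorted(set(example.truth) | set(example.baseline_values))
    lines.append(template.instruction(targets))
    return "\n".join(lines)


def full_schema(example: ForecastExample, task: TaskConfig, template: PromptTemplate) -> ForecastSchema:
    return ForecastSchema(tuple(task.targets), tuple(example.horizon_offsets), template.unit_label)


def encode_target(example: ForecastExample, template: PromptTemplate,
                  target_order: Sequence[str] | None = None) -> str:
    """JSON target text containing exactly the observed future cells."""
    if example.n_truth_cells == 0:
        raise ValueError("example has no observed future target values")
    order = [t for t in (target_order or sorted(example.truth)) if t in example.truth]
    payload = {
        t: {template.offset_label(o): example.truth[t][o] for o in sorted(example.truth[t])}
        for t in order
    }
    return json.dumps(payload)


def encode_example(example: ForecastExample, task: TaskConfig,
                   template: PromptTemplate | None = None) -> EncodedExample:
    """Encode one example; the decode schema is the full targets-by-horizons grid."""
    template = template or PromptTemplate.for_task(task)
    return EncodedExample(
        input_text=encode_input(example, template, targets=task.targets),
        target_text=encode_target(example, template, target_order=task.targets),
        schema=full_schema(example, task, template),
        example=example,
    )


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"(-?\d+)\s*$")


def _first_json_object(text: str):
    decoder = json.JSONDecoder()
    for m in re.finditer(r"\{", text):
        try:
            obj, _ = decoder.raw_decode(text, m.start())
        except json.JSONDecodeError:
            # generation may have stopped mid-object: try closing open braces
            tail = text[m.start():].rstrip().rstrip(",")
            for n_close in (1, 2):
                try:
                    obj = json.loads(tail + "}" * n_close)
                except json.JSONDecodeError:
                    continue
                if isinstance(obj, dict):
                    return obj
            continue
        if isinstance(obj, dict):
            return obj
    return None


_PAIR_RE = re.compile(r'"([^"\n]{1,40})"\s*:\s*(-?\d+(?:\.\d+)?)')


def _regex_cells(text: str, schema: "ForecastSchema") -> dict[str, dict[int, float]]:
    """Salvage (target, offset, value) cells from malformed JSON-like text.

    Each quoted-label/number pair is attributed to the nearest preceding
    target-name mention; used only when strict JSON decoding finds nothing.
    """
    markers = []
    for target in schema.targets:
        for m in re.finditer(re.escape(f'"{target}"'), text):
            markers.append((m.start(), target))
    markers.sort()
    values: dict[str, dict[int, float]] = {}
    for m in _PAIR_RE.finditer(text):
        label, raw = m.group(1), m.group(2)
        lm = _LABEL_RE.search(label)
        if not lm:
            continue
        offset = int(lm.group(1))
        if offset not in schema.offsets:
            continue
        target = None
        for pos, name in markers:
            if pos < m.start():
                target = name
            else:
                break
        if target is None:
            continue
        try:
            val = float(raw)
        except ValueError:
            continue
        values.setdefault(target, {})[offset] = val
    return values


def decode_forecast(text: str, schema: ForecastSchema) -> DecodedForecast:
    """Extract schema cells from generated text; failures are data, not errors."""
    n_expected = len(schema.cells())
    obj = _first_json_object(text)
    values: dict[str, dict[int, float]] = {}
    n_extracted = 0
    if obj is not None:
        for target in schema.targets:
            sub = obj.get(target)
            if not isinstance(sub, dict):
                continue
            by_offset: dict[int, float] = {}
            for label, raw in sub.items():
                m = _LABEL_RE.search(str(label))
                if not m:
                    continue
                offset = int(m.group(1))
                if offset not in schema.offsets:
                    continue
                if isinstance(raw, bool) or not isinstance(raw, (int, float, str)):
                    continue
                try:
                    val = float(raw)
                except (TypeError, ValueError):
                    continue
                if not np.isfinite(val):
                    continue
                by_offset[offset] = val
            if by_offset:
                values[target] = by_offset
                n_extracted += len(by_offset)
    if n_extracted == 0:
        # strict decoding found nothing: salvage cells pairwise
        values = _regex_cells(text, schema)
        n_extracted = sum(len(c) for c in values.values())
    if n_extracted == n_expected and n_expected > 0:
        status = "ok"
    elif n_extracted > 0:
        status = "partial"
    else:
        status = "failed"
        values = {}
    return DecodedForecast(values=values, parse_status=status,
                           n_expected=n_expected, n_extracted=n_extracted)


# ---------------------------------------------------------------------------
# Input perturbations
# ---------------------------------------------------------------------------


def inject_misspellings(text: str, n: int, rng: np.random.Generator,
                        return_log: bool = False):
    """Apply ``n`` independent misspelling operations to the whole text.

    Each operation is drawn uniformly from {perturbation (adjacent-character
    swap), insertion, deletion, replacement}; positions are uniform over the
    current text and inserted/replacement characters are uniform over ASCII
    letters and digits.  Operations that need existing characters on an empty
    (or, for swaps, single-character) text are re-drawn as insertions.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    ops = ("perturbation", "insertion", "deletion", "replacement")
    chars = list(text)
    log = []
    for _ in range(n):
        op = ops[int(rng.integers(len(ops)))]
        if (not chars and op in ("deletion", "replacement")) or (len(chars) < 2 and op == "perturbation"):
            op = "insertion"
        if op == "insertion":
            pos = int(rng.integers(len(chars) + 1))
            ch = _ALPHABET[int(rng.integers(len(_ALPHABET)))]
            chars.insert(pos, ch)
            log.append({"op": op, "pos": pos, "char": ch})
        elif op == "deletion":
            pos = int(rng.integers(len(chars)))
            log.append({"op": op, "pos": pos, "char": chars.pop(pos)})
        elif op == "replacement":
            pos = int(rng.integers(len(chars)))
            ch = _ALPHABET[int(rng.integers(len(_ALPHABET)))]
            chars[pos] = ch
            log.append({"op": op, "pos": pos, "char": ch})
        else:  # perturbation: adjacent swap
            pos = int(rng.integers(len(chars) - 1))
            chars[pos], chars[pos + 1] = chars[pos + 1], chars[pos]
            log.append({"op": op, "pos": pos})
    out = "".join(chars)
    return (out, log) if return_log else out


def mask_observations(example: ForecastExample, fraction: float,
                      rng: np.random.Generator) -> ForecastExample:
    """Independently drop each history observation with the given probability.

    Truth and the evaluation constants (baseline values) are untouched: the
    mask degrades only what the model gets to see.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0.0:
        return example
    keep = rng.random(len(example.history)) >= fraction
    history = [obs for obs, k in zip(example.history, keep) if k]
    return replace(example, history=history)


# ---------------------------------------------------------------------------
# Chatbot prompts: zero-shot forecasting and explanation
# ---------------------------------------------------------------------------


def build_zero_shot_prompt(example: ForecastExample, template: PromptTemplate,
                           variable: str, offsets: Sequence[int],
                           registry: VariableRegistry) -> tuple[str, ForecastSchema]:
    """Prompt for a variable never used as a training target, same JSON contract."""
    if variable not in registry:
        raise KeyError(f"unknown variable {variable!r}")
    base = encode_input(example, template)
    labels = ", ".join(template.offset_label(o) for o in offsets)
    instruction = (
        f"New task: predict the values of {variable} at {labels}. "
        'Respond with a JSON object of the form {"'
        f"{variable}"
        '": {"'
        f"{template.offset_label(offsets[0])}"
        '": value, ...}}.'
    )
    schema = ForecastSchema((variable,), tuple(int(o) for o in offsets), template.unit_label)
    return base + "\n" + instruction, schema


def build_explanation_prompt(input_text: str, forecast_text: str) -> str:
    """Follow-up prompt asking which variables drove the forecast most."""
    return (
        input_text
        + "\nForecast:\n"
        + forecast_text
        + "\nQuestion:\nList the most important variables influencing the predicted "
        "trajectory, in order of importance."
    )


@dataclass
class ExplanationParse:
    variables: list[str]
    extracted: bool


def parse_explanation(text: str, registry: VariableRegistry) -> ExplanationParse:
    """Extract registry-variable mentions in order of first appearance.

    A response mentioning no registry variable counts as a failed extraction.
    """
    lowered = text.lower()
    hits: list[tuple[int, str]] = []
    for name in registry.names:
        pat = re.escape(name.lower())
        m = re.search(rf"(?<![A-Za-z]){pat}(?![A-Za-z])", lowered)
        if m:
            hits.append((m.start(), name))
    hits.sort()
    names = [name for _, name in hits]
    return ExplanationParse(variables=names, extracted=bool(names))


# ---------------------------------------------------------------------------
# Corpus I/O
# ---------------------------------------------------------------------------


def write_corpus(encoded: Sequence[EncodedExample], path) -> None:
    with open(path, "w") as fh:
        for ex in encoded:
            fh.write(json.dumps(ex.to_dict()) + "\n")


def read_corpus(path) -> list[EncodedExample]:
    out = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            out.append(EncodedExample(d["input"], d["target"], ForecastSchema.from_dict(d["schema"])))
    return out
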