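"""Deterministic echo backend: copy-forward through the text channel.

The echo backend reads the rendered prompt the way any other backend would,
finds the last observed value of each requested target in the history
section, and emits a schema-compliant JSON completion repeating that value at
every forecast date (falling back to the training-corpus median when a target
was never observed).  Sampling k draws yields k identical texts.  Because it
answers through the same prompt/JSON channel, an end-to-end run with this
backend must reproduce the native copy-forward baseline exactly — the
pipeline's text-channel equivalence invariant.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np

from twinforecast.data_model import round_value
from twinforecast.encoding import EncodedExample, PromptTemplate
from twinforecast.lm_backend.base import LMBackend


class EchoBackend(LMBackend):
    def __init__(self, template: PromptTemplate | None = None):
        self.template = template or PromptTemplate()
        self.medians: dict[str, float] = {}
        self.n_pairs: int = 0

    def fine_tune(self, pairs: Sequence[EncodedExample]) -> "EchoBackend":
        """No-op training; records per-target value medians from the corpus."""
        pools: dict[str, list[float]] = {}
        for pair in pairs:
            payload = json.loads(pair.target_text)
            for target, cells in payload.items():
                pools.setdefault(target, []).extend(float(v) for v in cells.values())
        self.medians = {t: round_value(np.median(vs)) for t, vs in pools.items() if vs}
        self.n_pairs = len(pairs)
        return self

    def generate(self, prompt: str, k: int, rng: np.random.Generator) -> list[str]:
        if k < 1:
            raise ValueError("k must be >= 1")
        t = self.template
        targets = t.parse_instruction_targets(prompt)
        offsets = [o for o in t.parse_forecast_offsets(prompt) if o > 0]
        last = t.parse_history_last_values(prompt)
        payload = {}
        for target in targets:
            value = last.get(target, self.medians.get(target, 0.0))
            payload[target] = {t.offset_label(o): value for o in offsets}
        text = json.dumps(payload)
        return [text] * k

    def save(self, directory) -> None:
        from pathlib import Path

        path = Path(directory)
        path.mkdir(parents=True, exist_ok=True)
        (path / "echo.json").write_text(
            json.dumps({"medians": self.medians, "n_pairs": self.n_pairs,
                        "unit_label": self.template.unit_label})
        )

    @classmethod
    def load(cls, directory) -> "EchoBackend":
        from pathlib import Path

        d = json.loads((Path(directory) / "echo.json").read_text())
        backend = cls(PromptTemplate(unit_label=d["unit_label"]))
        backend.medians = {k: float(v) for k, v in d["medians"].items()}
        backend.n_pairs = int(d["n_pairs"])
        return backend
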