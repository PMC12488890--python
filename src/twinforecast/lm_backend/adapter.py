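"""Adapter for external instruction-tuned LLMs.

The forecasting pipeline is model-agnostic: any text-in/text-out model can
stand behind the backend contract.  This adapter carries no weights; it
delegates generation to a user-supplied completion callable (an API client,
a local server, or a canned-response fake in tests) and treats fine-tuning
as external to the process.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from twinforecast.lm_backend.base import LMBackend

#: completion_fn(prompt, k, seed) -> list of k completion texts
CompletionFn = Callable[[str, int, int], list[str]]


class ExternalLLMAdapter(LMBackend):
    def __init__(self, completion_fn: CompletionFn | None = None):
        self.completion_fn = completion_fn
        self.n_pairs = 0

    def fine_tune(self, pairs: Sequence) -> "ExternalLLMAdapter":
        """External models are tuned out of process; the corpus size is recorded."""
        self.n_pairs = len(pairs)
        return self

    def generate(self, prompt: str, k: int, rng: np.random.Generator) -> list[str]:
        if self.completion_fn is None:
            raise RuntimeError("no completion function configured on the adapter")
        seed = int(rng.integers(2**31))
        texts = list(self.completion_fn(prompt, k, seed))
        if len(texts) != k:
            raise RuntimeError(f"adapter returned {len(texts)} completions, expected {k}")
        return texts
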