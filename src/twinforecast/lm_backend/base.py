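"""The generative-model contract shared by all backends."""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class BackendConfig:
    """Shared backend knobs.

    ``max_len`` bounds the tokenized (input + target) sequence; pairs that
    exceed it are handled per ``truncation``: "error" rejects the pair with
    its index, "left" drops the oldest input tokens.  Sampling uses
    temperature / nucleus (top-p) decoding.  Training hyperparameters apply
    to trainable backends only.
    """

    max_len: int = 512
    temperature: float = 1.0
    top_p: float = 0.9
    max_new_tokens: int = 160
    truncation: str = "error"  # error | left
    # training hyperparameters (trainable backends)
    epochs: int = 8
    learning_rate: float = 3e-3
    batch_size: int = 32
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive for stochastic sampling")
        if not 0 < self.top_p <= 1:
            raise ValueError("top_p must lie in (0, 1]")
        if self.truncation not in ("error", "left"):
            raise ValueError(f"unknown truncation policy {self.truncation!r}")


class LMBackend(ABC):
    """Fine-tune on input->target text pairs; sample k completions."""

    @abstractmethod
    def fine_tune(self, pairs: Sequence) -> "LMBackend":
        """Train on encoded (input, target) pairs; returns self."""

    @abstractmethod
    def generate(self, prompt: str, k: int, rng: np.random.Generator) -> list[str]:
        """Return exactly k completions for the prompt."""
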