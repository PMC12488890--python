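"""Tiny trainable causal-LM backend.

Fine-tunes a small numpy transformer on encoded (input, target) text pairs
with the next-token cross-entropy loss masked to the output text, then
samples completions with temperature / top-p decoding.  The point is the
mechanism — learning clinical dynamics through a pure text channel — not
scale: with number-valued word pieces and short prompts this trains on a
single CPU in minutes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from twinforecast.encoding import EncodedExample
from twinforecast.lm_backend.base import BackendConfig, LMBackend
from twinforecast.lm_backend.nn import TinyGPT
from twinforecast.lm_backend.tokenizer import Tokenizer


class TinyLMBackend(LMBackend):
    def __init__(self, config: BackendConfig | None = None):
        self.config = config or BackendConfig()
        self.tokenizer: Tokenizer | None = None
        self.model: TinyGPT | None = None
        #: per-epoch mean training loss, recorded during fine_tune
        self.history: list[float] = []

    # ----------------------------------------------------------- training

    def _sequence(self, pair: EncodedExample, tok: Tokenizer, index: int) -> tuple[list[int], int]:
        """Token ids [bos] input [sep] target [eos] and the sep position."""
        cfg = self.config
        inp = tok.encode(pair.input_text)
        tgt = tok.encode(pair.target_text)
        budget = cfg.max_len + 1 - (len(tgt) + 3)  # room left for input tokens
        if len(inp) > budget:
            if cfg.truncation == "error":
                raise ValueError(
                    f"pair {index} exceeds max_len {cfg.max_len} "
                    f"({len(inp) + len(tgt) + 3} tokens)"
                )
            if budget <= 0:
                raise ValueError(f"pair {index}: target alone exceeds max_len")
            inp = inp[-budget:]  # drop the oldest history tokens
        ids = [tok.bos_id] + inp + [tok.sep_id] + tgt + [tok.eos_id]
        return ids, 1 + len(inp)

    def fine_tune(self, pairs: Sequence[EncodedExample]) -> "TinyLMBackend":
        if not pairs:
            raise ValueError("fine_tune requires a nonempty corpus")
        cfg = self.config
        tok = Tokenizer.fit(
            [p.input_text for p in pairs] + [p.target_text for p in pairs]
        )
        self.tokenizer = tok
        seqs = [self._sequence(p, tok, i) for i, p in enumerate(pairs)]
        self.model = TinyGPT(
            len(tok), d_model=cfg.d_model, n_layers=cfg.n_layers,
            n_heads=cfg.n_heads, max_len=cfg.max_len, seed=cfg.seed,
        )
        rng = np.random.default_rng(cfg.seed)
        self.history = []
        for _ in range(cfg.epochs):
            order = rng.permutation(len(seqs))
            losses = []
            for start in range(0, len(seqs), cfg.batch_size):
                batch = [seqs[j] for j in order[start:start + cfg.batch_size]]
                x, y, mask = self._collate(batch, tok.pad_id)
                loss, grads, _ = self.model.loss_and_grads(x, y, mask)
                self.model.adam_step(grads, lr=cfg.learning_rate)
                losses.append(loss)
            self.history.append(float(np.mean(losses)))
        return self

    @staticmethod
    def _collate(batch: list[tuple[list[int], int]], pad_id: int):
        width = max(len(ids) for ids, _ in batch) - 1
        B = len(batch)
        x = np.full((B, width), pad_id, dtype=np.int64)
        y = np.full((B, width), pad_id, dtype=np.int64)
        mask = np.zeros((B, width), dtype=np.float64)
        for row, (ids, sep_pos) in enumerate(batch):
            n = len(ids) - 1
            x[row, :n] = ids[:-1]
            y[row, :n] = ids[1:]
            mask[row, sep_pos:n] = 1.0  # predict target tokens and eos only
        return x, y, mask

    def mean_token_loss(self, pairs: Sequence[EncodedExample]) -> float:
        """Masked per-token loss of the current model on a corpus."""
        if self.model is None or self.tokenizer is None:
            raise RuntimeError("backend is not fine-tuned")
        tok = self.tokenizer
        total, count = 0.0, 0.0
        for start in range(0, len(pairs), self.config.batch_size):
            chunk = [
                self._sequence(p, tok, i)
                for i, p in enumerate(pairs[start:start + self.config.batch_size])
            ]
            x, y, mask = self._collate(chunk, tok.pad_id)
            loss, _, _ = self.model.loss_and_grads(x, y, mask)
            n = float(mask.sum())
            total += loss * n
            count += n
        return total / max(count, 1.0)

    # ----------------------------------------------------------- sampling

    def generate(self, prompt: str, k: int, rng: np.random.Generator) -> list[str]:
        if k < 1:
            raise ValueError("k must be >= 1")
        if self.model is None or self.tokenizer is None:
            raise RuntimeError("backend is not fine-tuned")
        cfg = self.config
        tok = self.tokenizer
        inp = tok.encode(prompt)
        cap = cfg.max_len - 3  # room for bos, sep and at least one new token
        if len(inp) > cap:
            if cfg.truncation == "error":
                raise ValueError(f"prompt of {len(inp)} tokens exceeds max_len {cfg.max_len}")
            inp = inp[-cap:]
        ids = [tok.bos_id] + inp + [tok.sep_id]
        outs = self.model.generate(
            ids, k, rng, max_new=cfg.max_new_tokens, eos_id=tok.eos_id,
            temperature=cfg.temperature, top_p=cfg.top_p,
        )
        return [tok.decode(o) for o in outs]

    # ------------------------------------------------------------ persist

    def save(self, directory) -> None:
        import dataclasses
        import json
        from pathlib import Path

        if self.model is None or self.tokenizer is None:
            raise RuntimeError("backend is not fine-tuned")
        path = Path(directory)
        path.mkdir(parents=True, exist_ok=True)
        self.model.save(path / "model.npz")
        (path / "tokenizer.json").write_text(json.dumps(self.tokenizer.to_dict()))
        (path / "backend.json").write_text(
            json.dumps({"config": dataclasses.asdict(self.config), "history": self.history})
        )

    @classmethod
    def load(cls, directory) -> "TinyLMBackend":
        import json
        from pathlib import Path

        path = Path(directory)
        meta = json.loads((path / "backend.json").read_text())
        backend = cls(BackendConfig(**meta["config"]))
        backend.history = list(meta["history"])
        backend.tokenizer = Tokenizer.from_dict(
            json.loads((path / "tokenizer.json").read_text())
        )
        backend.model = TinyGPT.load(path / "model.npz")
        return backend
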