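"""A tiny causal transformer in pure numpy.

Decoder-only, pre-LayerNorm, ReLU MLP, learned positional embeddings.
Forward, backward (hand-derived, gradient-checked in the test suite), Adam,
and KV-cached nucleus sampling are all implemented here; at the ~0.1-1M
parameter scale this trains on a CPU in minutes, which is all the text
channel mechanism needs.
"""

from __future__ import annotations

import math

import numpy as np

_EPS = 1e-5


def _layernorm_forward(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv)


def _layernorm_backward(dy, g, cache):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    mean1 = dxhat.mean(-1, keepdims=True)
    mean2 = (dxhat * xhat).mean(-1, keepdims=True)
    dx = inv * (dxhat - mean1 - xhat * mean2)
    return dx, dg, db


class TinyGPT:
    """Minimal GPT-style causal language model over a fixed vocabulary."""

    def __init__(self, vocab_size: int, d_model: int = 64, n_layers: int = 2,
                 n_heads: int = 2, max_len: int = 512, seed: int = 0,
                 dtype=np.float32):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.V, self.d, self.L, self.H = vocab_size, d_model, n_layers, n_heads
        self.dh = d_model // n_heads
        self.max_len = max_len
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        p = {}
        scale = 0.02
        p["tok_emb"] = scale * rng.standard_normal((vocab_size, d_model))
        p["pos_emb"] = scale * rng.standard_normal((max_len, d_model))
        for i in range(n_layers):
            p[f"l{i}.ln1.g"] = np.ones(d_model)
            p[f"l{i}.ln1.b"] = np.zeros(d_model)
            p[f"l{i}.attn.Wqkv"] = scale * rng.standard_normal((d_model, 3 * d_model))
            p[f"l{i}.attn.bqkv"] = np.zeros(3 * d_model)
            p[f"l{i}.attn.Wo"] = scale * rng.standard_normal((d_model, d_model))
            p[f"l{i}.attn.bo"] = np.zeros(d_model)
            p[f"l{i}.ln2.g"] = np.ones(d_model)
            p[f"l{i}.ln2.b"] = np.zeros(d_model)
            p[f"l{i}.mlp.W1"] = scale * rng.standard_normal((d_model, 4 * d_model))
            p[f"l{i}.mlp.b1"] = np.zeros(4 * d_model)
            p[f"l{i}.mlp.W2"] = scale * rng.standard_normal((4 * d_model, d_model))
            p[f"l{i}.mlp.b2"] = np.zeros(d_model)
        p["lnf.g"] = np.ones(d_model)
        p["lnf.b"] = np.zeros(d_model)
        p["Wout"] = scale * rng.standard_normal((d_model, vocab_size))
        p["bout"] = np.zeros(vocab_size)
        self.params = {k: v.astype(self.dtype) for k, v in p.items()}
        p = self.params
        self._adam_m = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_t = 0

    @property
    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())

    # ------------------------------------------------------------------ fwd

    def forward(self, x: np.ndarray, kv_cache: list | None = None,
                need_cache: bool = False):
        """Logits for token ids ``x`` (B, T).

        With ``kv_cache`` (a list of per-layer {"k","v"} dicts, mutated in
        place) the call continues a cached sequence; positions are offset by
        the cached length.  ``need_cache`` retains activations for backward.
        """
        p = self.params
        B, T = x.shape
        past = 0 if kv_cache is None or not kv_cache else kv_cache[0]["k"].shape[2]
        if past + T > self.max_len:
            raise ValueError(f"sequence length {past + T} exceeds max_len {self.max_len}")
        h = p["tok_emb"][x] + p["pos_emb"][past:past + T]
        cache = {"x": x, "layers": []} if need_cache else None
        scale = 1.0 / math.sqrt(self.dh)
        for i in range(self.L):
            lc = {}
            a, ln1c = _layernorm_forward(h, p[f"l{i}.ln1.g"], p[f"l{i}.ln1.b"])
            qkv = a.reshape(-1, self.d) @ p[f"l{i}.attn.Wqkv"] + p[f"l{i}.attn.bqkv"]
            qkv = qkv.reshape(B, T, 3, self.H, self.dh).transpose(2, 0, 3, 1, 4)
            q, k, v = qkv[0], qkv[1], qkv[2]  # (B, H, T, dh)
            if kv_cache is not None:
                if len(kv_cache) <= i:
                    kv_cache.append({"k": k, "v": v})
                else:
                    kv_cache[i]["k"] = np.concatenate([kv_cache[i]["k"], k], axis=2)
                    kv_cache[i]["v"] = np.concatenate([kv_cache[i]["v"], v], axis=2)
                k_all, v_all = kv_cache[i]["k"], kv_cache[i]["v"]
            else:
                k_all, v_all = k, v
            S = k_all.shape[2]
            scores = (q @ k_all.transpose(0, 1, 3, 2)) * scale  # (B,H,T,S)
            # causal mask: query at absolute position past+t sees keys <= past+t
            qpos = past + np.arange(T)[:, None]
            kpos = np.arange(S)[None, :]
            scores = np.where(kpos <= qpos, scores, -np.inf)
            scores -= scores.max(-1, keepdims=True)
            att = np.exp(scores)
            att /= att.sum(-1, keepdims=True)
            o = (att @ v_all).transpose(0, 2, 1, 3).reshape(B, T, self.d)
            proj = o.reshape(-1, self.d) @ p[f"l{i}.attn.Wo"] + p[f"l{i}.attn.bo"]
            h1 = h + proj.reshape(B, T, self.d)
            m, ln2c = _layernorm_forward(h1, p[f"l{i}.ln2.g"], p[f"l{i}.ln2.b"])
            pre = m.reshape(-1, self.d) @ p[f"l{i}.mlp.W1"] + p[f"l{i}.mlp.b1"]
            f = np.maximum(pre, 0.0)
            proj2 = f @ p[f"l{i}.mlp.W2"] + p[f"l{i}.mlp.b2"]
            h2 = h1 + proj2.reshape(B, T, self.d)
            if need_cache:
                lc.update(a=a, ln1c=ln1c, q=q, k=k_all, v=v_all, att=att, o=o,
                          h_in=h, h_mid=h1, m=m, pre=pre, f=f, ln2c=ln2c)
                cache["layers"].append(lc)
            h = h2
        y, lnfc = _layernorm_forward(h, p["lnf.g"], p["lnf.b"])
        logits = y.reshape(-1, self.d) @ p["Wout"] + p["bout"]
        logits = logits.reshape(B, T, self.V)
        if need_cache:
            cache.update(h_final=h, y=y, lnfc=lnfc)
            return logits, cache
        return logits

    # ----------------------------------------------------------- loss/grad

    def loss_and_grads(self, x: np.ndarray, y_true: np.ndarray, mask: np.ndarray):
        """Masked next-token cross entropy and parameter gradients.

        ``mask`` selects the positions whose targets contribute to the loss
        (the output-text positions); gradients at unmasked positions are
        exactly zero by construction.  Returns (loss, grads, dlogits).
        """
        logits, cache = self.forward(x, need_cache=True)
        B, T, V = logits.shape
        mask = mask.astype(logits.dtype)
        mx = logits.max(-1, keepdims=True)
        ex = np.exp(logits - mx)
        Z = ex.sum(-1, keepdims=True)
        probs = ex / Z
        n = max(float(mask.sum()), 1.0)
        bi, ti = np.nonzero(mask)
        logp = (logits - mx - np.log(Z))[bi, ti, y_true[bi, ti]]
        loss = -float(logp.sum()) / n
        dlogits = probs * mask[..., None]
        dlogits[bi, ti, y_true[bi, ti]] -= 1.0
        dlogits /= n
        grads = self._backward(dlogits, cache)
        return loss, grads, dlogits

    def _backward(self, dlogits: np.ndarray, cache: dict) -> dict:
        p = self.params
        B, T, _ = dlogits.shape
        g = {k: np.zeros_like(v) for k, v in p.items()}
        dl2 = dlogits.reshape(-1, self.V)
        g["Wout"] = cache["y"].reshape(-1, self.d).T @ dl2
        g["bout"] = dl2.sum(0)
        dy = (dl2 @ p["Wout"].T).reshape(B, T, self.d)
        dh, g["lnf.g"], g["lnf.b"] = _layernorm_backward(dy, p["lnf.g"], cache["lnfc"])
        scale = 1.0 / math.sqrt(self.dh)
        for i in reversed(range(self.L)):
            lc = cache["layers"][i]
            # MLP block
            dproj2 = dh.reshape(-1, self.d)
            g[f"l{i}.mlp.W2"] = lc["f"].T @ dproj2
            g[f"l{i}.mlp.b2"] = dproj2.sum(0)
            df = dproj2 @ p[f"l{i}.mlp.W2"].T
            dpre = df * (lc["pre"] > 0)
            g[f"l{i}.mlp.W1"] = lc["m"].reshape(-1, self.d).T @ dpre
            g[f"l{i}.mlp.b1"] = dpre.sum(0)
            dm = (dpre @ p[f"l{i}.mlp.W1"].T).reshape(B, T, self.d)
            dln2, g[f"l{i}.ln2.g"], g[f"l{i}.ln2.b"] = _layernorm_backward(
                dm, p[f"l{i}.ln2.g"], lc["ln2c"])
            dh1 = dh + dln2
            # attention block
            dproj = dh1.reshape(-1, self.d)
            g[f"l{i}.attn.Wo"] = lc["o"].reshape(-1, self.d).T @ dproj
            g[f"l{i}.attn.bo"] = dproj.sum(0)
            do = (dproj @ p[f"l{i}.attn.Wo"].T).reshape(B, T, self.H, self.dh)
            do = do.transpose(0, 2, 1, 3)  # (B,H,T,dh)
            att, v, q, k = lc["att"], lc["v"], lc["q"], lc["k"]
            dv = att.transpose(0, 1, 3, 2) @ do
            datt = do @ v.transpose(0, 1, 3, 2)
            ds = att * (datt - (datt * att).sum(-1, keepdims=True))
            dq = (ds @ k) * scale
            dk = (ds.transpose(0, 1, 3, 2) @ q) * scale
            dqkv = np.stack([dq, dk, dv], axis=0)  # (3,B,H,T,dh)
            dqkv = dqkv.transpose(1, 3, 0, 2, 4).reshape(-1, 3 * self.d)
            g[f"l{i}.attn.Wqkv"] = lc["a"].reshape(-1, self.d).T @ dqkv
            g[f"l{i}.attn.bqkv"] = dqkv.sum(0)
            da = (dqkv @ p[f"l{i}.attn.Wqkv"].T).reshape(B, T, self.d)
            dln1, g[f"l{i}.ln1.g"], g[f"l{i}.ln1.b"] = _layernorm_backward(
                da, p[f"l{i}.ln1.g"], lc["ln1c"])
            dh = dh1 + dln1
        np.add.at(g["tok_emb"], cache["x"], dh)
        g["pos_emb"][:T] = dh.sum(0)
        return g

    # ---------------------------------------------------------------- adam

    def adam_step(self, grads: dict, lr: float, beta1: float = 0.9,
                  beta2: float = 0.999, eps: float = 1e-8, clip: float = 1.0) -> None:
        if clip is not None:
            norm = math.sqrt(sum(float((gv * gv).sum()) for gv in grads.values()))
            if norm > clip:
                grads = {k: v * (clip / norm) for k, v in grads.items()}
        self._adam_t += 1
        t = self._adam_t
        for key, gv in grads.items():
            m = self._adam_m[key]
            v = self._adam_v[key]
            m *= beta1
            m += (1 - beta1) * gv
            v *= beta2
            v += (1 - beta2) * gv * gv
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[key] -= lr * mhat / (np.sqrt(vhat) + eps)

    # ------------------------------------------------------------ sampling

    def generate(self, prompt_ids: list[int], k: int, rng: np.random.Generator,
                 max_new: int, eos_id: int, temperature: float = 1.0,
                 top_p: float = 0.9) -> list[list[int]]:
        """Sample k continuations of one prompt with a shared prefilled KV cache."""
        prompt = np.asarray(prompt_ids, dtype=np.int64)[None, :]
        max_new = min(max_new, self.max_len - prompt.shape[1])
        if max_new <= 0:
            return [[] for _ in range(k)]
        kv: list = []
        logits = self.forward(prompt, kv_cache=kv)
        for layer in kv:
            layer["k"] = np.repeat(layer["k"], k, axis=0)
            layer["v"] = np.repeat(layer["v"], k, axis=0)
        last = np.repeat(logits[:, -1, :], k, axis=0)  # (k, V)
        out = [[] for _ in range(k)]
        done = np.zeros(k, dtype=bool)
        for _ in range(max_new):
            nxt = self._sample(last, rng, temperature, top_p)
            nxt = np.where(done, eos_id, nxt)
            for row in range(k):
                if not done[row]:
                    out[row].append(int(nxt[row]))
            done |= nxt == eos_id
            if done.all():
                break
            last = self.forward(nxt[:, None], kv_cache=kv)[:, -1, :]
        return out

    @staticmethod
    def _sample(logits: np.ndarray, rng: np.random.Generator,
                temperature: float, top_p: float) -> np.ndarray:
        z = logits / temperature
        z -= z.max(-1, keepdims=True)
        probs = np.exp(z)
        probs /= probs.sum(-1, keepdims=True)
        if top_p < 1.0:
            order = np.argsort(-probs, axis=-1)
            sorted_p = np.take_along_axis(probs, order, axis=-1)
            csum = np.cumsum(sorted_p, axis=-1)
            cut = csum - sorted_p >= top_p  # tokens entirely beyond the nucleus
            sorted_p[cut] = 0.0
            sorted_p /= sorted_p.sum(-1, keepdims=True)
            trimmed = np.zeros_like(probs)
            np.put_along_axis(trimmed, order, sorted_p, axis=-1)
            probs = trimmed
        u = rng.random(probs.shape[0])
        csum = np.cumsum(probs, axis=-1)
        return (csum < u[:, None]).sum(-1).astype(np.int64)

    # ------------------------------------------------------------ persist

    def save(self, path) -> None:
        meta = np.array([self.V, self.d, self.L, self.H, self.max_len], dtype=np.int64)
        np.savez(path, __meta__=meta, **self.params)

    @classmethod
    def load(cls, path) -> "TinyGPT":
        data = np.load(path)
        V, d, L, H, max_len = (int(v) for v in data["__meta__"])
        model = cls(V, d, L, H, max_len, dtype=data["tok_emb"].dtype)
        for key in model.params:
            model.params[key] = data[key]
        return model
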