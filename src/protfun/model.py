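"""Dilated residual convolutional network for protein function prediction.

The model maps a one-hot encoded amino-acid sequence of arbitrary
length L to

* per-residue features ``F`` of shape (L, filters),
* a sequence embedding ``e`` = masked mean of ``F`` over positions, and
* per-label probabilities ``p = sigmoid(e @ W + b)`` over a fixed,
  ordered label vocabulary (multi-label, element-wise sigmoid).

Architecture: an initial kernel-size convolution lifts the 20-dim
one-hot input to ``filters`` channels, followed by ``num_res_layers``
pre-activation bottleneck residual blocks

    block(x) = x + P(ReLU(N(D(ReLU(N(x))))))

where ``D`` is a dilated convolution to ``filters * bottleneck_factor``
channels, ``P`` a width-restoring kernel-1 convolution, and ``N`` a
per-position layer normalisation (batch-size independent).  Block k
(1-indexed) uses dilation ``dilation_rate ** (k - first_dilated_layer + 1)``
for ``k >= first_dilated_layer`` and 1 before, so receptive fields grow
geometrically with depth.  All convolutions are zero-padded "same", and
padded batch positions are re-zeroed after every layer so that outputs
for a sequence are identical whether it is run alone or padded inside a
larger batch.

Because pooling is a plain mean and the output head is affine, the
per-residue class score ``W[:, c] . F_i`` averaged over positions plus
the bias reconstructs the logit exactly — the identity that makes
class-activation mapping (:mod:`protfun.interpret`) exact rather than
approximate.

Implemented directly on NumPy (float32) with hand-derived gradients;
see :mod:`protfun.train` for the optimiser.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

_LN_EPS = 1e-5


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the network.

    Defaults are the full-scale settings (5 residual layers, 1100
    filters, kernel 9, dilation rate 3, first dilated layer 2,
    bottleneck factor 0.5); desk-scale experiments shrink
    ``num_res_layers`` and ``filters``.
    """

    vocabulary: tuple[str, ...]
    num_res_layers: int = 5
    filters: int = 1100
    kernel_size: int = 9
    dilation_rate: int = 3
    first_dilated_layer: int = 2
    bottleneck_factor: float = 0.5
    norm: str = "layer"  # "layer" | "none"

    def __post_init__(self) -> None:
        if not self.vocabulary:
            raise ModelError("vocabulary must be non-empty")
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ModelError("vocabulary contains duplicates")
        for name in ("num_res_layers", "filters", "kernel_size", "dilation_rate",
                     "first_dilated_layer"):
            if getattr(self, name) < 1:
                raise ModelError(f"{name} must be positive")
        if self.kernel_size % 2 != 1:
            raise ModelError("kernel_size must be odd ('same' padding)")
        if not 0.0 < self.bottleneck_factor <= 1.0:
            raise ModelError("bottleneck_factor must be in (0, 1]")
        if self.norm not in ("layer", "none"):
            raise ModelError(f"unknown norm {self.norm!r}")
        object.__setattr__(self, "vocabulary", tuple(self.vocabulary))

    @property
    def bottleneck_filters(self) -> int:
        return max(1, int(round(self.filters * self.bottleneck_factor)))

    def dilation(self, layer: int) -> int:
        """Dilation of residual layer ``layer`` (1-indexed)."""
        if layer < self.first_dilated_layer:
            return 1
        return self.dilation_rate ** (layer - self.first_dilated_layer + 1)

    @property
    def receptive_field_radius(self) -> int:
        """Positions beyond this distance cannot influence a residue's features."""
        half = (self.kernel_size - 1) // 2
        return half + sum(
            half * self.dilation(k) for k in range(1, self.num_res_layers + 1)
        )

    def to_dict(self) -> dict:
        return {
            "vocabulary": list(self.vocabulary),
            "num_res_layers": self.num_res_layers,
            "filters": self.filters,
            "kernel_size": self.kernel_size,
            "dilation_rate": self.dilation_rate,
            "first_dilated_layer": self.first_dilated_layer,
            "bottleneck_factor": self.bottleneck_factor,
            "norm": self.norm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["vocabulary"] = tuple(d["vocabulary"])
        return cls(**d)


# ---------------------------------------------------------------------------
# sequence encoding


def encode_sequence(seq: str) -> np.ndarray:
    """One-hot encode a sequence as an (L, 20) float32 matrix.

    Alphabet columns are the 20 standard residues in alphabetical
    one-letter order.  Raises on non-standard residues, naming the
    offending position.
    """
    if not seq:
        raise ModelError("cannot encode an empty sequence")
    idx = np.empty(len(seq), dtype=np.int64)
    for i, aa in enumerate(seq):
        j = _AA_INDEX.get(aa)
        if j is None:
            raise ModelError(f"non-standard residue {aa!r} at position {i}")
        idx[i] = j
    out = np.zeros((len(seq), 20), dtype=np.float32)
    out[np.arange(len(seq)), idx] = 1.0
    return out


def decode_sequence(onehot: np.ndarray) -> str:
    """Invert :func:`encode_sequence`."""
    return "".join(ALPHABET[j] for j in onehot.argmax(axis=1))


def pad_batch(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Stack sequences into a zero-padded (B, Lmax, 20) batch plus mask."""
    if not seqs:
        raise ModelError("empty batch")
    lmax = max(len(s) for s in seqs)
    x = np.zeros((len(seqs), lmax, 20), dtype=np.float32)
    mask = np.zeros((len(seqs), lmax), dtype=np.float32)
    for i, s in enumerate(seqs):
        x[i, : len(s)] = encode_sequence(s)
        mask[i, : len(s)] = 1.0
    return x, mask


# ---------------------------------------------------------------------------
# outputs


@dataclass
class ModelOutputs:
    """Forward-pass results for a batch.

    ``features`` (B, L, filters) are the pre-pooling per-residue
    features; ``embedding`` (B, filters) their masked mean; ``logits``
    and ``probabilities`` are (B, |vocab|).
    """

    features: np.ndarray
    embedding: np.ndarray
    logits: np.ndarray
    probabilities: np.ndarray
    mask: np.ndarray


# ---------------------------------------------------------------------------
# primitive layers (forward + backward)


def _conv1d_forward(x, w, b, dilation, mask3):
    """'Same' zero-padded dilated 1-D convolution.

    x: (B, L, Cin) with masked positions zero; w: (K, Cin, Cout).
    Returns output masked to zero at padded positions, plus the padded
    input for the backward pass.
    """
    B, L, cin = x.shape
    K, _, cout = w.shape
    r = dilation * (K - 1) // 2
    xp = np.zeros((B, L + 2 * r, cin), dtype=x.dtype)
    xp[:, r : r + L] = x
    y2 = np.zeros((B * L, cout), dtype=x.dtype)
    for k in range(K):
        sl = xp[:, k * dilation : k * dilation + L].reshape(B * L, cin)
        y2 += sl @ w[k]
    y = (y2.reshape(B, L, cout) + b) * mask3
    return y, xp


def _conv1d_backward(dy, xp, w, dilation, mask3):
    """Gradients of _conv1d_forward.  dy must already be masked."""
    B, L, cout = dy.shape
    K, cin, _ = w.shape
    r = dilation * (K - 1) // 2
    dy2 = dy.reshape(B * L, cout)
    dw = np.empty_like(w)
    dxp = np.zeros_like(xp)
    for k in range(K):
        sl = xp[:, k * dilation : k * dilation + L].reshape(B * L, cin)
        dw[k] = sl.T @ dy2
        dxp[:, k * dilation : k * dilation + L] += (dy2 @ w[k].T).reshape(B, L, cin)
    db = dy2.sum(axis=0)
    dx = dxp[:, r : r + L] * mask3
    return dx, dw, db


def _layernorm_forward(x, g, b, mask3):
    """Per-position normalisation over channels; masked positions stay zero."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = np.mean(xc * xc, axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    y = (g * xhat + b) * mask3
    return y, (xhat, inv)


def _layernorm_backward(dy, g, cache, mask3):
    xhat, inv = cache
    dy = dy * mask3
    dg = (dy * xhat).sum(axis=(0, 1))
    db = dy.sum(axis=(0, 1))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2) * mask3
    return dx, dg, db


# ---------------------------------------------------------------------------
# the model


class Model:
    """A dilated residual CNN with deterministic seeded initialisation.

    Parameters are float32 arrays in ``self.params`` keyed by layer
    name; gradients returned by :meth:`forward_backward` use the same
    keys.  Use :func:`build_model` to construct one.
    """

    def __init__(self, config: ModelConfig, params: dict[str, np.ndarray]):
        self.config = config
        self.params = params

    # -- construction ----------------------------------------------------

    @classmethod
    def initialise(cls, config: ModelConfig, seed: int = 0) -> "Model":
        rng = np.random.default_rng(seed)
        F, Fb, K, V = (
            config.filters,
            config.bottleneck_filters,
            config.kernel_size,
            len(config.vocabulary),
        )

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(
                np.float32
            )

        p: dict[str, np.ndarray] = {}
        p["stem.W"] = he((K, 20, F), K * 20)
        p["stem.b"] = np.zeros(F, dtype=np.float32)
        for i in range(1, config.num_res_layers + 1):
            p[f"block{i}.norm1.g"] = np.ones(F, dtype=np.float32)
            p[f"block{i}.norm1.b"] = np.zeros(F, dtype=np.float32)
            p[f"block{i}.conv1.W"] = he((K, F, Fb), K * F)
            p[f"block{i}.conv1.b"] = np.zeros(Fb, dtype=np.float32)
            p[f"block{i}.norm2.g"] = np.ones(Fb, dtype=np.float32)
            p[f"block{i}.norm2.b"] = np.zeros(Fb, dtype=np.float32)
            p[f"block{i}.conv2.W"] = he((1, Fb, F), Fb)
            p[f"block{i}.conv2.b"] = np.zeros(F, dtype=np.float32)
        p["head.W"] = (rng.standard_normal((F, V)) / np.sqrt(F)).astype(np.float32)
        p["head.b"] = np.zeros(V, dtype=np.float32)
        return cls(config, p)

    @property
    def vocabulary(self) -> tuple[str, ...]:
        return self.config.vocabulary

    def num_parameters(self) -> int:
        return sum(int(a.size) for a in self.params.values())

    # -- forward ---------------------------------------------------------

    def _stack_forward(self, x, mask, want_cache: bool):
        """Run stem + residual stack; returns features and layer caches."""
        cfg = self.config
        use_ln = cfg.norm == "layer"
        mask3 = mask[:, :, None].astype(np.float32)
        x = x * mask3
        h, xp0 = _conv1d_forward(
            x, self.params["stem.W"], self.params["stem.b"], 1, mask3
        )
        caches = [("stem", xp0)] if want_cache else None
        for i in range(1, cfg.num_res_layers + 1):
            d = cfg.dilation(i)
            if use_ln:
                a1, ln1 = _layernorm_forward(
                    h, self.params[f"block{i}.norm1.g"],
                    self.params[f"block{i}.norm1.b"], mask3
                )
            else:
                a1, ln1 = h, None
            r1 = np.maximum(a1, 0.0)
            c1, xp1 = _conv1d_forward(
                r1, self.params[f"block{i}.conv1.W"],
                self.params[f"block{i}.conv1.b"], d, mask3
            )
            if use_ln:
                a2, ln2 = _layernorm_forward(
                    c1, self.params[f"block{i}.norm2.g"],
                    self.params[f"block{i}.norm2.b"], mask3
                )
            else:
                a2, ln2 = c1, None
            r2 = np.maximum(a2, 0.0)
            c2, xp2 = _conv1d_forward(
                r2, self.params[f"block{i}.conv2.W"],
                self.params[f"block{i}.conv2.b"], 1, mask3
            )
            if want_cache:
                caches.append((f"block{i}", a1, ln1, xp1, a2, ln2, xp2, d))
            h = (h + c2) * mask3
        return h, mask3, caches

    def forward(self, x: np.ndarray, mask: np.ndarray) -> ModelOutputs:
        """Forward pass on a padded batch (no caches kept)."""
        if x.ndim != 3 or x.shape[0] == 0:
            raise ModelError("expected a non-empty (B, L, 20) batch")
        feats, mask3, _ = self._stack_forward(
            x.astype(np.float32, copy=False), mask, want_cache=False
        )
        lengths = mask3.sum(axis=1)  # (B, 1)
        emb = feats.sum(axis=1) / lengths
        logits = emb @ self.params["head.W"] + self.params["head.b"]
        probs = _sigmoid(logits)
        return ModelOutputs(
            features=feats, embedding=emb, logits=logits,
            probabilities=probs, mask=mask,
        )

    def apply(self, seqs: Sequence[str]) -> ModelOutputs:
        """Encode, pad, and run a list of raw sequences."""
        x, mask = pad_batch(seqs)
        return self.forward(x, mask)

    def predict_proba(
        self, seqs: Sequence[str], max_batch_tokens: int = 50_000
    ) -> np.ndarray:
        """Probabilities (n, |vocab|), batching length-sorted sequences."""
        order = sorted(range(len(seqs)), key=lambda i: len(seqs[i]))
        out = np.zeros((len(seqs), len(self.vocabulary)), dtype=np.float32)
        batch: list[int] = []
        for i in order + [None]:
            flush = i is None or (
                batch
                and (len(batch) + 1) * len(seqs[i]) > max_batch_tokens
            )
            if flush and batch:
                probs = self.apply([seqs[j] for j in batch]).probabilities
                out[batch] = probs
                batch = []
            if i is not None:
                batch.append(i)
        return out

    # -- training pass ---------------------------------------------------

    def forward_backward(
        self, x: np.ndarray, mask: np.ndarray, targets: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
        """Loss, parameter gradients, and logits for one batch.

        ``targets`` is a (B, |vocab|) 0/1 matrix.  The loss is binary
        cross-entropy averaged over vocabulary and batch, computed from
        logits for numerical stability.
        """
        feats, mask3, caches = self._stack_forward(
            x.astype(np.float32, copy=False), mask, want_cache=True
        )
        B, L, F = feats.shape
        V = len(self.vocabulary)
        lengths = mask3.sum(axis=1)
        emb = feats.sum(axis=1) / lengths
        logits = emb @ self.params["head.W"] + self.params["head.b"]
        y = targets.astype(np.float32, copy=False)
        # stable BCE from logits
        loss = float(
            np.mean(
                np.maximum(logits, 0.0) - logits * y + np.log1p(np.exp(-np.abs(logits)))
            )
        )
        grads: dict[str, np.ndarray] = {}
        dz = (_sigmoid(logits) - y) / (B * V)
        grads["head.W"] = emb.T @ dz
        grads["head.b"] = dz.sum(axis=0)
        demb = dz @ self.params["head.W"].T
        dh = (demb[:, None, :] / lengths[:, None, :]) * mask3

        cfg = self.config
        use_ln = cfg.norm == "layer"
        for entry in reversed(caches[1:]):
            name, a1, ln1, xp1, a2, ln2, xp2, d = entry
            i = name[len("block"):]
            dc2 = dh  # gradient into the block output branch
            dr2, dw2, db2 = _conv1d_backward(
                dc2, xp2, self.params[f"block{i}.conv2.W"], 1, mask3
            )
            grads[f"block{i}.conv2.W"] = dw2
            grads[f"block{i}.conv2.b"] = db2
            da2 = dr2 * (a2 > 0)
            if use_ln:
                dc1, dg2, dbn2 = _layernorm_backward(
                    da2, self.params[f"block{i}.norm2.g"], ln2, mask3
                )
                grads[f"block{i}.norm2.g"] = dg2
                grads[f"block{i}.norm2.b"] = dbn2
            else:
                dc1 = da2
            dr1, dw1, db1 = _conv1d_backward(
                dc1, xp1, self.params[f"block{i}.conv1.W"], d, mask3
            )
            grads[f"block{i}.conv1.W"] = dw1
            grads[f"block{i}.conv1.b"] = db1
            da1 = dr1 * (a1 > 0)
            if use_ln:
                dh_branch, dg1, dbn1 = _layernorm_backward(
                    da1, self.params[f"block{i}.norm1.g"], ln1, mask3
                )
                grads[f"block{i}.norm1.g"] = dg1
                grads[f"block{i}.norm1.b"] = dbn1
            else:
                dh_branch = da1
            dh = dh + dh_branch  # residual shortcut
        _, xp0 = caches[0]
        _dx, dws, dbs = _conv1d_backward(dh, xp0, self.params["stem.W"], 1, mask3)
        grads["stem.W"] = dws
        grads["stem.b"] = dbs
        return loss, grads, logits

    # -- prediction ------------------------------------------------------

    def predict_labels(self, seq: str, threshold: float = 0.5) -> frozenset[str]:
        """Labels whose predicted probability is >= threshold."""
        if not 0.0 <= threshold <= 1.0:
            raise ModelError("threshold must be in [0, 1]")
        probs = self.apply([seq]).probabilities[0]
        return frozenset(
            lab for lab, p in zip(self.vocabulary, probs) if p >= threshold
        )

    # -- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a versioned checkpoint (zip of config JSON + npz params)."""
        path = Path(path)
        buf = io.BytesIO()
        np.savez(buf, **self.params)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr(
                "config.json",
                json.dumps({"format_version": 1, "config": self.config.to_dict()}),
            )
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("config.json"))
            if meta.get("format_version") != 1:
                raise ModelError("unsupported checkpoint version")
            config = ModelConfig.from_dict(meta["config"])
            with zf.open("params.npz") as fh:
                npz = np.load(io.BytesIO(fh.read()))
                params = {k: npz[k] for k in npz.files}
        return cls(config, params)


def build_model(config: ModelConfig, seed: int = 0) -> Model:
    """Construct a model with seeded He-style initialisation."""
    return Model.initialise(config, seed=seed)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def predict_labels(model: Model, seq: str, threshold: float = 0.5) -> frozenset[str]:
    """Functional alias for :meth:`Model.predict_labels`."""
    return model.predict_labels(seq, threshold)
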