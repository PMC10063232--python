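"""Class-activation mapping, domain ordering, and embedding probes.

Because the network pools per-residue features by a plain mean and maps
the pooled embedding to logits with a single affine layer, the logit of
class c decomposes exactly over residues:

    logit_c = mean_i ( W[:, c] . F_i ) + b_c

The per-residue term ``W[:, c] . F_i`` is the class-activation map
(CAM): it attributes the prediction to sequence positions without any
gradient computation.  For multi-functional proteins the raw maps are
sharpened by cross-class normalisation — subtracting, at each residue,
the mean score of the *other* predicted classes — and a centre of mass
of the (non-negative part of the) normalised map gives a coarse
location for each function, from which the N-to-C order of two
catalytic domains is predicted.

The pooled embedding itself is a general-purpose representation; a
small supervised probe (random forest by default) trained on
embeddings measures how much function information it carries beyond
the directly supervised labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import Model
from .ontology import LabelGraph


class InterpretError(ValueError):
    pass


@dataclass
class ActivationMap:
    """Per-residue, per-class contribution scores for one sequence.

    ``scores[i, c]`` is the dot product of residue i's pre-pooling
    feature vector with class c's output-head weights; averaging over
    residues and adding the class bias reconstructs the logit.
    """

    scores: np.ndarray  # (L, n_classes)
    classes: tuple[str, ...]
    accession: str = ""
    normalized: bool = False

    def column(self, label: str) -> np.ndarray:
        try:
            return self.scores[:, self.classes.index(label)]
        except ValueError:
            raise InterpretError(f"class {label!r} not in this map") from None


def cam(model: Model, seq: str, classes: Sequence[str]) -> ActivationMap:
    """Raw class-activation map for the given classes."""
    classes = tuple(classes)
    vocab_index = {lab: j for j, lab in enumerate(model.vocabulary)}
    unknown = [c for c in classes if c not in vocab_index]
    if unknown:
        raise InterpretError(f"classes not in model vocabulary: {unknown}")
    out = model.apply([seq])
    feats = out.features[0, : len(seq)]  # (L, filters)
    w = model.params["head.W"][:, [vocab_index[c] for c in classes]]
    return ActivationMap(scores=feats @ w, classes=classes)


def normalize_cam(amap: ActivationMap) -> ActivationMap:
    """Subtract, per residue, the mean score of all *other* classes.

    With exactly two classes this is the pairwise difference, making
    the two columns antisymmetric.  Undefined for a single class.
    """
    L, C = amap.scores.shape
    if C < 2:
        raise InterpretError("cross-class normalisation needs >= 2 classes")
    total = amap.scores.sum(axis=1, keepdims=True)
    mean_others = (total - amap.scores) / (C - 1)
    return ActivationMap(
        scores=amap.scores - mean_others,
        classes=amap.classes,
        accession=amap.accession,
        normalized=True,
    )


def center_of_mass(scores: np.ndarray) -> float:
    """Centre of mass of a per-residue score vector (0-based positions).

    Negative scores are clipped to zero; if no score is positive the
    raw scores shifted to non-negative are used instead.  A vector with
    no signal at all (constant) raises.
    """
    s = np.asarray(scores, dtype=np.float64)
    if s.ndim != 1 or len(s) == 0:
        raise InterpretError("scores must be a non-empty 1-D vector")
    w = np.clip(s, 0.0, None)
    if w.sum() == 0.0:
        w = s - s.min()
        if w.sum() == 0.0:
            raise InterpretError("no signal: all scores equal")
    idx = np.arange(len(s), dtype=np.float64)
    return float((idx * w).sum() / w.sum())


def predicted_leaf_classes(
    model: Model, seq: str, threshold: float = 0.5, graph: LabelGraph | None = None
) -> frozenset[str]:
    """Labels predicted at the threshold, reduced to the most specific ones."""
    labels = model.predict_labels(seq, threshold)
    if graph is not None and labels:
        labels = graph.most_specific(labels)
    return frozenset(labels)


def order_domains(
    model: Model,
    seq: str,
    classes: Sequence[str] | None = None,
    threshold: float = 0.5,
    graph: LabelGraph | None = None,
) -> tuple[str, str]:
    """Predict the N-to-C order of the two functional domains.

    If ``classes`` is not given, the candidate pair is the model's most
    specific predictions at the threshold; exactly two are required
    (the candidate-set restriction of the ordering experiment).  The
    classes are sorted by ascending centre of mass of their normalised
    activation maps; exact ties fall back to label id order.
    """
    if classes is None:
        classes = sorted(predicted_leaf_classes(model, seq, threshold, graph))
    classes = list(classes)
    if len(classes) != 2:
        raise InterpretError(
            f"domain ordering requires exactly 2 predicted classes, got {len(classes)}"
        )
    amap = normalize_cam(cam(model, seq, classes))
    coms = {c: center_of_mass(amap.column(c)) for c in classes}
    a, b = sorted(classes, key=lambda c: (coms[c], c))
    return a, b


def embed(model: Model, seq: str) -> np.ndarray:
    """Pooled embedding of one sequence (length = number of filters)."""
    return model.apply([seq]).embedding[0]


def embed_many(model: Model, seqs: Sequence[str], max_batch_tokens: int = 50_000) -> np.ndarray:
    """Embeddings for many sequences, batched by length."""
    order = sorted(range(len(seqs)), key=lambda i: len(seqs[i]))
    out = np.zeros((len(seqs), model.config.filters), dtype=np.float32)
    batch: list[int] = []
    for i in order + [None]:
        flush = i is None or (
            batch and (len(batch) + 1) * len(seqs[i]) > max_batch_tokens
        )
        if flush and batch:
            out[batch] = model.apply([seqs[j] for j in batch]).embedding
            batch = []
        if i is not None:
            batch.append(i)
    return out


def embedding_probe(
    embeddings: np.ndarray,
    labels: np.ndarray,
    train_mask: np.ndarray,
    classifier=None,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Fit a small supervised probe on embeddings; report held-out P/R/F1.

    ``labels`` is a binary vector for a property the embedding model
    was never supervised on; ``train_mask`` selects the (small) probe
    training portion, and metrics are computed on the remainder.  The
    default classifier is a seeded random forest.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import precision_recall_fscore_support

    embeddings = np.asarray(embeddings)
    labels = np.asarray(labels).astype(int)
    train_mask = np.asarray(train_mask, dtype=bool)
    if embeddings.shape[0] != labels.shape[0] or labels.shape[0] != train_mask.shape[0]:
        raise InterpretError("embeddings, labels and train_mask lengths differ")
    y_train = labels[train_mask]
    if len(np.unique(y_train)) < 2:
        raise InterpretError("probe training data contains a single class")
    clf = classifier or RandomForestClassifier(n_estimators=100, random_state=seed)
    clf.fit(embeddings[train_mask], y_train)
    pred = clf.predict(embeddings[~train_mask])
    p, r, f1, _ = precision_recall_fscore_support(
        labels[~train_mask], pred, average="binary", zero_division=0
    )
    return float(p), float(r), float(f1)
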