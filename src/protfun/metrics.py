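"""Evaluation: micro precision/recall curves, Fmax, bootstrap CIs, ensembles.

Predictions are maps ``accession -> {label: confidence}``; truth is
``accession -> set of labels`` (ancestor-closed).  All counting is
micro-averaged over example-label pairs: at a threshold t, a pair is
predicted iff its score is >= t, and precision/recall are computed
from the pooled TP/FP/FN counts.  The headline summary statistic is
Fmax, the maximum F1 = 2PR/(P+R) over all thresholds.  (F1 is
sometimes loosely described as a geometric mean of precision and
recall; the conventional harmonic mean is what is implemented here.)

A pair absent from an accession's score map is never predicted at any
threshold — this is how alignment-based predictors, which only score
labels transferred from a hit, are represented.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

PredictionSet = Mapping[str, Mapping[str, float]]
TruthSet = Mapping[str, frozenset]


class MetricsError(ValueError):
    pass


@dataclass
class PRCurve:
    """Micro precision/recall at every distinct confidence threshold.

    Arrays are aligned and ordered by decreasing threshold; ``tp``,
    ``fp`` give the pooled counts at each threshold and ``total_true``
    the number of true example-label pairs (so fn = total_true - tp).
    """

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    total_true: int


@dataclass
class FmaxResult:
    """The threshold sweep's best F1 and where it was attained."""

    fmax: float
    threshold: float
    precision: float
    recall: float
    ci: tuple[float, float] | None = None


def _flatten(
    preds: PredictionSet, truth: TruthSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Pairs as arrays: scores, is_true, accession index, per-acc true counts."""
    if not truth:
        raise MetricsError("empty truth")
    missing = sorted(set(preds) - set(truth))
    if missing:
        raise MetricsError(f"accessions missing from truth: {missing[:10]}")
    accs = sorted(preds)
    scores: list[float] = []
    is_true: list[bool] = []
    acc_idx: list[int] = []
    true_counts = np.zeros(len(accs), dtype=np.int64)
    for i, acc in enumerate(accs):
        tset = truth[acc]
        true_counts[i] = len(tset)
        for lab, s in preds[acc].items():
            if not np.isfinite(s):
                raise MetricsError(f"non-finite score for {acc}/{lab}")
            scores.append(float(s))
            is_true.append(lab in tset)
            acc_idx.append(i)
    return (
        np.asarray(scores, dtype=np.float64),
        np.asarray(is_true, dtype=np.float64),
        np.asarray(acc_idx, dtype=np.int64),
        true_counts,
        accs,
    )


_MAX_EXACT_PAIRS = 10**6


def pr_curve(preds: PredictionSet, truth: TruthSet) -> PRCurve:
    """Sweep every distinct score as a threshold and count micro TP/FP/FN.

    When the number of scored pairs exceeds one million the sweep falls
    back to a 501-point grid on [0, 1] to bound memory and time.
    """
    scores, is_true, _, true_counts, _ = _flatten(preds, truth)
    total_true = int(true_counts.sum())
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    t_sorted = is_true[order]
    tp_cum = np.cumsum(t_sorted)
    npred_cum = np.arange(1, len(s_sorted) + 1, dtype=np.float64)
    if len(s_sorted) <= _MAX_EXACT_PAIRS:
        # last index of each run of equal scores = counts with score >= t
        boundary = np.nonzero(np.diff(s_sorted) != 0)[0]
        last = np.concatenate([boundary, [len(s_sorted) - 1]])
        thresholds = s_sorted[last]
    else:
        grid = np.linspace(1.0, 0.0, 501)
        last_idx = np.searchsorted(-s_sorted, -grid, side="right") - 1
        keep = last_idx >= 0
        thresholds = grid[keep]
        last = last_idx[keep]
    tp = tp_cum[last]
    npred = npred_cum[last]
    fp = npred - tp
    precision = np.where(npred > 0, tp / np.maximum(npred, 1), 1.0)
    if total_true == 0:
        raise MetricsError("truth contains no example-label pairs")
    recall = tp / total_true
    return PRCurve(
        thresholds=thresholds,
        precision=precision,
        recall=recall,
        tp=tp.astype(np.int64),
        fp=fp.astype(np.int64),
        total_true=total_true,
    )


def _f1(p: np.ndarray, r: np.ndarray) -> np.ndarray:
    denom = p + r
    return np.where(denom > 0, 2 * p * r / np.where(denom > 0, denom, 1.0), 0.0)


def fmax(curve: PRCurve) -> FmaxResult:
    """Maximum F1 over the curve; F1 ties resolve to the higher threshold."""
    if len(curve.thresholds) == 0:
        raise MetricsError("empty curve")
    f1 = _f1(curve.precision, curve.recall)
    # thresholds are ordered descending, so argmax's first-hit rule
    # breaks ties toward the higher threshold
    i = int(np.argmax(f1))
    return FmaxResult(
        fmax=float(f1[i]),
        threshold=float(curve.thresholds[i]),
        precision=float(curve.precision[i]),
        recall=float(curve.recall[i]),
    )


def evaluate(preds: PredictionSet, truth: TruthSet) -> FmaxResult:
    """Convenience: Fmax of the full threshold sweep."""
    return fmax(pr_curve(preds, truth))


def bootstrap_ci(
    preds: PredictionSet,
    truth: TruthSet,
    statistic: Callable[[np.ndarray], np.ndarray] | None = None,
    reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for Fmax, resampling accessions.

    Accessions are drawn with replacement ``reps`` times; each
    resample's Fmax is computed with pair weights equal to the draw
    multiplicities, and the (1-level)/2 percentile interval is
    returned.  ``statistic`` may override the per-resample summary: it
    receives the vector of per-threshold F1 values and returns a
    scalar (the default takes the maximum).
    """
    if reps < 2:
        raise MetricsError("reps must be >= 2")
    scores, is_true, acc_idx, true_counts, accs = _flatten(preds, truth)
    n = len(accs)
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    t_sorted = is_true[order]
    a_sorted = acc_idx[order]
    boundary = np.nonzero(np.diff(s_sorted) != 0)[0]
    last = np.concatenate([boundary, [len(s_sorted) - 1]])
    rng = np.random.default_rng(seed)
    stats = np.empty(reps)
    reduce = statistic if statistic is not None else np.max
    for rep in range(reps):
        counts = np.bincount(rng.integers(0, n, size=n), minlength=n)
        w = counts[a_sorted].astype(np.float64)
        tp = np.cumsum(w * t_sorted)[last]
        npred = np.cumsum(w)[last]
        total_true = float(counts @ true_counts)
        precision = np.where(npred > 0, tp / np.maximum(npred, 1e-300), 1.0)
        recall = tp / total_true if total_true > 0 else np.zeros_like(tp)
        stats[rep] = reduce(_f1(precision, recall))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def ensemble_mean(prediction_sets: Sequence[PredictionSet]) -> dict[str, dict[str, float]]:
    """Element-wise mean of several CNN prediction sets.

    All members must cover identical accessions and, per accession,
    identical label sets; the ensemble confidence for a pair is the
    arithmetic mean of the members' probabilities.
    """
    if not prediction_sets:
        raise MetricsError("no prediction sets to ensemble")
    first = prediction_sets[0]
    accs = set(first)
    for ps in prediction_sets[1:]:
        if set(ps) != accs:
            raise MetricsError("prediction sets cover different accessions")
    out: dict[str, dict[str, float]] = {}
    for acc in accs:
        labels = set(first[acc])
        for ps in prediction_sets[1:]:
            if set(ps[acc]) != labels:
                raise MetricsError(f"label coverage differs for {acc!r}")
        out[acc] = {
            lab: float(np.mean([ps[acc][lab] for ps in prediction_sets]))
            for lab in labels
        }
    return out


def naive_baseline(
    train_records: Sequence, test_accessions: Sequence[str]
) -> dict[str, dict[str, float]]:
    """Training-frequency control: score(label) = train count / N, everywhere.

    Every test accession receives the identical score map, so this
    predictor encodes label prevalence and nothing about the sequence;
    any method worth its salt should beat it dramatically.
    """
    n = len(train_records)
    counts: dict[str, int] = {}
    for r in train_records:
        for lab in r.labels:
            counts[lab] = counts.get(lab, 0) + 1
    freq = {lab: c / n for lab, c in counts.items()} if n else {}
    return {acc: dict(freq) for acc in test_accessions}


# ---------------------------------------------------------------------------
# adapters and IO


def predictions_from_model(
    model, records: Sequence, max_batch_tokens: int = 50_000
) -> dict[str, dict[str, float]]:
    """Score every record against the full model vocabulary."""
    probs = model.predict_proba(
        [r.sequence for r in records], max_batch_tokens=max_batch_tokens
    )
    vocab = model.vocabulary
    return {
        r.accession: {lab: float(p) for lab, p in zip(vocab, probs[i])}
        for i, r in enumerate(records)
    }


def truth_from_records(records: Sequence) -> dict[str, frozenset]:
    return {r.accession: frozenset(r.labels) for r in records}


def write_predictions(preds: PredictionSet, path: str | Path) -> None:
    """Write predictions as accession<TAB>label<TAB>score."""
    with open(path, "w", encoding="utf-8") as fh:
        for acc in sorted(preds):
            for lab in sorted(preds[acc]):
                fh.write(f"{acc}\t{lab}\t{preds[acc][lab]:.8g}\n")


def read_predictions(path: str | Path) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            acc, lab, score = line.split("\t")
            out.setdefault(acc, {})[lab] = float(score)
    return out


def read_truth(path: str | Path) -> dict[str, frozenset]:
    """Read truth TSV accession<TAB>comma-separated labels (may be empty)."""
    out: dict[str, frozenset] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            acc, labs = line.split("\t")
            out[acc] = frozenset(x for x in labs.split(",") if x)
    return out


def write_truth(truth: TruthSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for acc in sorted(truth):
            fh.write(f"{acc}\t{','.join(sorted(truth[acc]))}\n")
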