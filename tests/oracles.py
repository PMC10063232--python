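"""Independent brute-force oracles used by the metric tests.

These deliberately re-derive quantities by direct counting/loops,
sharing no code with the implementation they check.
"""

from __future__ import annotations


def brute_force_pr(preds: dict, truth: dict) -> list[tuple[float, float, float]]:
    """(threshold, precision, recall) recounted from scratch per threshold.

    Thresholds are the distinct scores, descending.  At threshold t a
    pair is predicted iff its score >= t; precision is 1 when nothing
    is predicted.
    """
    pairs = [
        (score, lab in truth[acc])
        for acc, labmap in preds.items()
        for lab, score in labmap.items()
    ]
    total_true = sum(len(truth[acc]) for acc in preds)
    thresholds = sorted({s for s, _t in pairs}, reverse=True)
    out = []
    for t in thresholds:
        tp = sum(1 for s, is_true in pairs if s >= t and is_true)
        fp = sum(1 for s, is_true in pairs if s >= t and not is_true)
        precision = tp / (tp + fp) if tp + fp else 1.0
        recall = tp / total_true
        out.append((t, precision, recall))
    return out


def brute_force_fmax(preds: dict, truth: dict) -> float:
    best = 0.0
    for _t, p, r in brute_force_pr(preds, truth):
        if p + r > 0:
            best = max(best, 2 * p * r / (p + r))
    return best


def random_prediction_problem(rng, n_acc=20, n_lab=5):
    """A random prediction/truth pair over a small label alphabet."""
    labels = [f"L{j}" for j in range(n_lab)]
    preds, truth = {}, {}
    for i in range(n_acc):
        acc = f"P{i}"
        # quantised scores force ties so threshold handling is exercised
        preds[acc] = {
            lab: round(float(rng.random()), 2)
            for lab in labels
            if rng.random() < 0.8
        }
        truth[acc] = frozenset(lab for lab in labels if rng.random() < 0.4)
    return preds, truth
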