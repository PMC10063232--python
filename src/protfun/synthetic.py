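"""Seeded synthetic proteomes with planted, hierarchy-linked motifs.

Real benchmarks for function prediction need a curated database and
GPU-scale training.  For desk-scale development and testing we instead
generate a corpus in which ground truth is known by construction: each
leaf of a synthetic label tree owns a short amino-acid motif, and a
protein belongs to a leaf class exactly when (a mutated copy of) that
leaf's motif was planted in its otherwise-uniform random sequence.
Bifunctional proteins carry two motifs from two distinct leaves at
non-overlapping positions, giving ground truth for the domain-ordering
experiment; a configurable fraction of records carry no motif and no
labels (non-enzymes).

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import STANDARD_AA, AnnotatedRecord
from .ontology import LabelGraph, Namespace


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class MotifSpec:
    """A leaf label's planted motif and its per-position mutation rate."""

    label: str
    motif: str
    mutation_rate: float

    def __post_init__(self) -> None:
        if len(self.motif) < 5:
            raise SyntheticError("motif length must be >= 5")
        if not 0.0 <= self.mutation_rate < 0.5:
            raise SyntheticError("mutation_rate must be in [0, 0.5)")


@dataclass(frozen=True)
class TruthSpan:
    """A planted motif occurrence: leaf label + 0-based half-open span."""

    label: str
    start: int
    end: int


@dataclass
class SyntheticTruth:
    """Per-accession planted spans (ground-truth localisation)."""

    spans: dict[str, list[TruthSpan]]

    def __getitem__(self, accession: str) -> list[TruthSpan]:
        return self.spans[accession]


def make_ontology(
    levels: int = 4,
    branching: int | Sequence[int] = (2, 3, 4),
    seed: int = 0,
) -> LabelGraph:
    """Build a complete synthetic label tree.

    ``branching`` may be a single factor or one factor per non-root
    level; ``levels`` counts the root level.  Node ids follow an
    EC-like dotted scheme: root ``S:-``, then ``S:2``, ``S:2.1``,
    ``S:2.1.3`` ...  The default (2, 3, 4) tree has 24 leaves and 33
    nodes over 4 levels.
    """
    if levels < 2:
        raise SyntheticError("levels must be >= 2")
    if isinstance(branching, int):
        branching = (branching,) * (levels - 1)
    branching = tuple(int(b) for b in branching)
    if len(branching) != levels - 1:
        raise SyntheticError(
            f"need {levels - 1} branching factors for {levels} levels, "
            f"got {len(branching)}"
        )
    if any(b < 2 for b in branching):
        raise SyntheticError("branching factors must be >= 2")
    root = "S:-"
    edges: list[tuple[str, str]] = []
    frontier = [root]
    for b in branching:
        nxt = []
        for parent in frontier:
            stem = "S:" if parent == root else parent + "."
            for i in range(1, b + 1):
                child = f"{stem}{i}"
                edges.append((child, parent))
                nxt.append(child)
        frontier = nxt
    return LabelGraph(edges, namespace=Namespace.SYNTHETIC)


def make_motifs(
    graph: LabelGraph,
    motif_length: int = 40,
    mutation_rate: float = 0.05,
    seed: int = 0,
) -> list[MotifSpec]:
    """Draw one i.i.d.-uniform motif per leaf, in sorted leaf order."""
    rng = np.random.default_rng(seed)
    specs = []
    for leaf in sorted(graph.leaves):
        idx = rng.integers(0, 20, size=motif_length)
        motif = "".join(STANDARD_AA[i] for i in idx)
        specs.append(MotifSpec(label=leaf, motif=motif, mutation_rate=mutation_rate))
    return specs


def _mutate(motif: str, rate: float, rng: np.random.Generator) -> str:
    out = list(motif)
    for i, aa in enumerate(out):
        if rng.random() < rate:
            # substitute with a uniformly chosen *different* residue so the
            # realised substitution count is Binomial(len, rate)
            choices = STANDARD_AA.replace(aa, "")
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _place_spans(
    lengths: list[int], total: int, rng: np.random.Generator
) -> list[tuple[int, int]] | None:
    """Uniform-ish non-overlapping placement of motif spans; None if it fails."""
    for _restart in range(200):
        placed: list[tuple[int, int]] = []
        ok = True
        for mlen in lengths:
            if mlen > total:
                return None
            for _attempt in range(100):
                start = int(rng.integers(0, total - mlen + 1))
                if all(start >= e or start + mlen <= s for s, e in placed):
                    placed.append((start, start + mlen))
                    break
            else:
                ok = False
                break
        if ok:
            return placed
    return None


def make_corpus(
    graph: LabelGraph,
    n: int = 2000,
    length_range: tuple[int, int] = (100, 600),
    bifunctional_fraction: float = 0.1,
    mutation_rate: float = 0.05,
    seed: int = 0,
    nonenzyme_fraction: float = 0.2,
    motif_length: int = 40,
    motifs: Sequence[MotifSpec] | None = None,
) -> tuple[list[AnnotatedRecord], SyntheticTruth, list[MotifSpec]]:
    """Generate a labelled synthetic proteome with known motif spans.

    Record composition is deterministic: ``round(n * nonenzyme_fraction)``
    records carry no motif and no labels, ``round(n * bifunctional_fraction)``
    carry two motifs from two distinct leaves, and the rest carry one
    motif.  Bifunctional leaf pairs are drawn from a fixed set of
    recurrent "domain architectures" (consecutive disjoint pairs of
    the sorted leaves), emulating how real bifunctional enzymes
    concentrate in a few recurring architectures; the N-to-C order of
    the two domains is uniform.  Positions are uniform among
    non-overlapping placements; motifs are copied with i.i.d.
    per-position substitutions.  Pass ``motifs`` (for example the
    table returned by a previous call) to generate additional corpora
    over the same motif universe.
    """
    if n < 1:
        raise SyntheticError("n must be >= 1")
    lo, hi = length_range
    if motifs is None:
        motifs = make_motifs(graph, motif_length, mutation_rate, seed=seed + 1)
    m = max(len(s.motif) for s in motifs)
    if hi < 2 * m + 2:
        raise SyntheticError(
            f"max length {hi} cannot fit two motifs of length {m}"
        )
    if lo < m:
        raise SyntheticError(f"min length {lo} shorter than motif length {m}")
    by_label = {s.label: s for s in motifs}
    leaves = sorted(by_label)
    if len(leaves) < 2:
        raise SyntheticError("need at least two leaf motifs")

    architectures = [
        (leaves[i], leaves[i + 1]) for i in range(0, len(leaves) - 1, 2)
    ]
    n_non = round(n * nonenzyme_fraction)
    n_bif = round(n * bifunctional_fraction)
    if n_non + n_bif > n:
        raise SyntheticError("nonenzyme_fraction + bifunctional_fraction > 1")
    kinds = ["none"] * n_non + ["bi"] * n_bif + ["mono"] * (n - n_non - n_bif)

    rng = np.random.default_rng(seed)
    rng.shuffle(kinds)

    records: list[AnnotatedRecord] = []
    spans: dict[str, list[TruthSpan]] = {}
    width = max(6, len(str(n)))
    for i, kind in enumerate(kinds):
        acc = f"SYN{i:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        seq = list(STANDARD_AA[j] for j in rng.integers(0, 20, size=length))
        rec_spans: list[TruthSpan] = []
        if kind == "none":
            chosen: list[str] = []
        elif kind == "mono":
            chosen = [leaves[rng.integers(0, len(leaves))]]
        else:
            # bifunctional proteins recur in a limited set of domain
            # architectures (leaf pairs); N-to-C order stays 50/50
            pair = architectures[rng.integers(0, len(architectures))]
            chosen = list(pair) if rng.random() < 0.5 else list(pair[::-1])
        if kind == "bi" and length < 2 * m + 2:
            length = 2 * m + 2
            seq = list(STANDARD_AA[j] for j in rng.integers(0, 20, size=length))
        # joint rejection sampling: a greedy first placement can make the
        # second motif infeasible in short sequences, so restart the whole
        # record's placement rather than only resampling the last motif
        placed = _place_spans(
            [len(by_label[lab].motif) for lab in chosen], length, rng
        )
        if placed is None:
            raise SyntheticError(
                f"could not place motifs {chosen} in length {length}"
            )
        for label, (start, end) in zip(chosen, placed):
            # the corpus-level mutation_rate governs planting noise, so a
            # motif table can be reused under a different noise condition
            seq[start:end] = _mutate(by_label[label].motif, mutation_rate, rng)
            rec_spans.append(TruthSpan(label=label, start=start, end=end))
        rec_spans.sort(key=lambda s: s.start)
        leaf_set = frozenset(chosen)
        records.append(
            AnnotatedRecord(
                accession=acc,
                sequence="".join(seq),
                leaf_labels=leaf_set,
                labels=graph.propagate(leaf_set),
            )
        )
        spans[acc] = rec_spans
    return records, SyntheticTruth(spans=spans), list(motifs)


# ---------------------------------------------------------------------------
# on-disk formats


def write_truth_table(truth: SyntheticTruth, path: str | Path) -> None:
    """Write planted spans as accession<TAB>label<TAB>start<TAB>end."""
    with open(path, "w", encoding="utf-8") as fh:
        for acc in sorted(truth.spans):
            for sp in truth.spans[acc]:
                fh.write(f"{acc}\t{sp.label}\t{sp.start}\t{sp.end}\n")


def read_truth_table(path: str | Path) -> SyntheticTruth:
    spans: dict[str, list[TruthSpan]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            acc, label, start, end = line.split("\t")
            spans.setdefault(acc, []).append(
                TruthSpan(label=label, start=int(start), end=int(end))
            )
    return SyntheticTruth(spans=spans)


def write_motif_table(motifs: Sequence[MotifSpec], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in motifs:
            fh.write(f"{s.label}\t{s.motif}\t{s.mutation_rate}\n")


def read_motif_table(path: str | Path) -> list[MotifSpec]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            label, motif, rate = line.split("\t")
            out.append(MotifSpec(label=label, motif=motif, mutation_rate=float(rate)))
    return out
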