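"""Corpus construction, filtering, and train/dev/test splitting.

A corpus pairs amino-acid sequences (FASTA) with leaf-label annotations
(TSV) over a :class:`~protfun.ontology.LabelGraph`.  Records are
ancestor-closed at build time, filtered to the 20 standard residues and
non-fragments, and split either uniformly at random (80/10/10 by a
salted hash of the accession) or by sequence-similarity cluster so that
no cluster straddles folds — the remote-homology setting in which a
test protein has no close relative in training.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .ontology import LabelGraph, OntologyError

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

FOLDS = ("train", "dev", "test")


class CorpusError(ValueError):
    """Inconsistent corpus inputs (missing accession, unknown label, ...)."""


@dataclass(frozen=True)
class ProteinRecord:
    """A raw sequence record with its leaf annotations."""

    accession: str
    sequence: str
    leaf_labels: frozenset[str] = frozenset()
    is_fragment: bool = False


@dataclass(frozen=True)
class AnnotatedRecord:
    """A record whose label set has been ancestor-closed."""

    accession: str
    sequence: str
    leaf_labels: frozenset[str]
    labels: frozenset[str]
    is_fragment: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DatasetSplit:
    """Assignment of accessions to train/dev/test folds."""

    fold_of: Mapping[str, str]
    provenance: str  # "random" | "clustered"
    seed: int

    def accessions(self, fold: str) -> list[str]:
        return sorted(a for a, f in self.fold_of.items() if f == fold)

    def subset(self, records: Sequence[AnnotatedRecord], fold: str) -> list[AnnotatedRecord]:
        return [r for r in records if self.fold_of[r.accession] == fold]

    def counts(self) -> dict[str, int]:
        c = Counter(self.fold_of.values())
        return {f: c.get(f, 0) for f in FOLDS}


# ---------------------------------------------------------------------------
# reading / writing


def read_label_table(path: str | Path) -> dict[str, tuple[bool, frozenset[str]]]:
    """Read the label TSV: accession<TAB>is_fragment(0/1)<TAB>comma-sep leaves.

    An empty third column means a record with no labels (a non-enzyme).
    """
    out: dict[str, tuple[bool, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise CorpusError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            acc, frag, labs = parts
            if frag not in ("0", "1"):
                raise CorpusError(f"{path}:{lineno}: is_fragment must be 0 or 1")
            if acc in out:
                raise CorpusError(f"{path}:{lineno}: duplicate accession {acc!r}")
            leaf = frozenset(x for x in labs.split(",") if x)
            out[acc] = (frag == "1", leaf)
    return out


def read_corpus(
    fasta: str | Path,
    labels: str | Path | Mapping[str, tuple[bool, frozenset[str]]],
    graph: LabelGraph,
) -> list[AnnotatedRecord]:
    """Pair a FASTA with a label table and ancestor-close every label set.

    Every accession in the label table must appear in the FASTA; labels
    absent from the ontology are rejected (silent drops would corrupt
    evaluation downstream).  Record order follows the FASTA file.
    """
    if not isinstance(labels, Mapping):
        labels = read_label_table(labels)
    records: list[AnnotatedRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta), "fasta"):
        acc = rec.id
        seen.add(acc)
        is_fragment, leaf = labels.get(acc, (False, frozenset()))
        try:
            closed = graph.propagate(leaf)
        except OntologyError as exc:
            raise CorpusError(f"record {acc!r}: {exc}") from exc
        records.append(
            AnnotatedRecord(
                accession=acc,
                sequence=str(rec.seq),
                leaf_labels=leaf,
                labels=closed,
                is_fragment=is_fragment,
            )
        )
    missing = sorted(set(labels) - seen)
    if missing:
        raise CorpusError(f"labelled accessions missing from FASTA: {missing}")
    return records


def write_fasta(records: Iterable[ProteinRecord | AnnotatedRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns, accession as id."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f">{r.accession}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")


def write_label_table(records: Iterable[ProteinRecord | AnnotatedRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            labs = ",".join(sorted(r.leaf_labels))
            fh.write(f"{r.accession}\t{int(r.is_fragment)}\t{labs}\n")


def read_split_table(path: str | Path, provenance: str = "random", seed: int = 0) -> DatasetSplit:
    fold_of: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            acc, fold = line.split("\t")
            if fold not in FOLDS:
                raise CorpusError(f"{path}:{lineno}: unknown fold {fold!r}")
            fold_of[acc] = fold
    return DatasetSplit(fold_of=fold_of, provenance=provenance, seed=seed)


def write_split_table(split: DatasetSplit, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for acc in sorted(split.fold_of):
            fh.write(f"{acc}\t{split.fold_of[acc]}\n")


def read_cluster_table(path: str | Path) -> dict[str, str]:
    """Read accession<TAB>cluster-id pairs (a UniRef50-style table)."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            acc, clu = line.split("\t")
            out[acc] = clu
    return out


# ---------------------------------------------------------------------------
# filtering


@dataclass
class RejectionReport:
    """Counts of records removed per rejection reason."""

    nonstandard_residue: int = 0
    fragment: int = 0
    empty_sequence: int = 0

    @property
    def total(self) -> int:
        return self.nonstandard_residue + self.fragment + self.empty_sequence


def filter_records(records: Sequence) -> tuple[list, RejectionReport]:
    """Remove records with non-standard residues, fragments, empty sequences.

    Mirrors the standard dataset-construction step of keeping only the
    20 canonical amino acids and dropping fragment entries.  Total and
    idempotent: filtering an already-filtered list is a no-op.
    """
    kept = []
    report = RejectionReport()
    for r in records:
        if not r.sequence:
            report.empty_sequence += 1
        elif not _STANDARD_SET.issuperset(r.sequence):
            report.nonstandard_residue += 1
        elif r.is_fragment:
            report.fragment += 1
        else:
            kept.append(r)
    return kept, report


# ---------------------------------------------------------------------------
# splits


def _unit_hash(accession: str, seed: int) -> float:
    """Deterministic, order-independent hash of (seed, accession) in [0, 1)."""
    digest = hashlib.sha256(f"{seed}:{accession}".encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


def random_split(
    records: Sequence,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Random train/dev/test split by salted hash of the accession.

    The fold of a record is a deterministic function of (accession,
    seed) alone, so the assignment is stable under reordering and
    subsetting of the corpus.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise CorpusError(f"fractions must sum to 1, got {fractions}")
    t1 = fractions[0]
    t2 = fractions[0] + fractions[1]
    fold_of: dict[str, str] = {}
    for r in records:
        acc = r if isinstance(r, str) else r.accession
        u = _unit_hash(acc, seed)
        fold_of[acc] = "train" if u < t1 else ("dev" if u < t2 else "test")
    return DatasetSplit(fold_of=fold_of, provenance="random", seed=seed)


def clustered_split(
    records: Sequence,
    clusters: Mapping[str, str],
    seed: int = 0,
) -> DatasetSplit:
    """Cluster-respecting split with approximately equal fold sizes.

    All members of a cluster share one fold (the UniRef50-style
    remote-homology protocol).  Clusters are sorted by size descending
    (ties broken by a seeded hash of the cluster id) and greedily
    assigned to the currently smallest fold, which fills the three folds
    near-equally.
    """
    accs = [r if isinstance(r, str) else r.accession for r in records]
    missing = sorted(a for a in accs if a not in clusters)
    if missing:
        raise CorpusError(f"accessions without a cluster id: {missing[:10]}")
    members: dict[str, list[str]] = {}
    for a in accs:
        members.setdefault(clusters[a], []).append(a)
    order = sorted(
        members, key=lambda c: (-len(members[c]), _unit_hash(c, seed))
    )
    sizes = {f: 0 for f in FOLDS}
    fold_of: dict[str, str] = {}
    for clu in order:
        fold = min(FOLDS, key=lambda f: (sizes[f], FOLDS.index(f)))
        for a in members[clu]:
            fold_of[a] = fold
        sizes[fold] += len(members[clu])
    return DatasetSplit(fold_of=fold_of, provenance="clustered", seed=seed)


# ---------------------------------------------------------------------------
# statistics


def split_stats(split: DatasetSplit, records: Sequence[AnnotatedRecord]) -> dict:
    """Per-fold counts, vocabulary sizes, and the impossible test set.

    "Impossible" test labels are labels that occur on test records but
    never on a train record; no classifier trained on this split can
    recall the corresponding test example-label pairs.
    """
    by_fold = {f: split.subset(records, f) for f in FOLDS}
    label_sets = {
        f: set().union(*(r.labels for r in recs)) if recs else set()
        for f, recs in by_fold.items()
    }
    pair_counts = {f: sum(len(r.labels) for r in recs) for f, recs in by_fold.items()}
    impossible_labels = label_sets["test"] - label_sets["train"]
    impossible_pairs = sum(
        len(r.labels & impossible_labels) for r in by_fold["test"]
    )
    return {
        "sequences": {f: len(by_fold[f]) for f in FOLDS},
        "labels": {f: len(label_sets[f]) for f in FOLDS},
        "example_label_pairs": pair_counts,
        "impossible_test_labels": len(impossible_labels),
        "impossible_test_label_ids": sorted(impossible_labels),
        "impossible_test_pairs": impossible_pairs,
    }
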