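"""Nearest-neighbour label transfer by sequence alignment, and the
bit-score x probability ensemble.

The alignment baseline annotates a query with all labels of its
highest-scoring train-set sequence, using the hit's bit-score as the
confidence for every transferred label.  Two search backends are
provided: a built-in Smith-Waterman (BLOSUM62, affine gaps open 11 /
extend 1, via Biopython's pairwise aligner) and external ``blastp``
when installed.  Raw Smith-Waterman scores are converted to bit-scores
with the Karlin-Altschul transform S' = (lambda*S - ln K) / ln 2 using
the standard BLOSUM62 constants lambda = 0.267, K = 0.041.

The ensemble rescales each transferred label's bit-score by the CNN's
(mean ensemble) predicted probability for that label, sharpening
BLAST's precision where the network is unconfident.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

# default Karlin-Altschul constants for BLOSUM62
LAMBDA = 0.267
KAPPA = 0.041


class AlignError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentHit:
    """Best train-set match for a query."""

    query: str
    subject: str
    bit_score: float


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST-style affine gaps: 11 to open (plus 1 for the first residue), 1 to extend
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


def bit_score(raw_score: float, lam: float = LAMBDA, k: float = KAPPA) -> float:
    """Karlin-Altschul bit-score of a raw alignment score."""
    return (lam * raw_score - math.log(k)) / math.log(2.0)


def top_hit(query, train_db: Sequence) -> AlignmentHit | None:
    """Highest-bit-score subject for one query (built-in backend).

    ``query`` and the database entries are records with ``accession``
    and ``sequence`` attributes.  Ties in score break toward the
    lexicographically smallest subject accession; queries with no
    positive-scoring alignment return ``None``.
    """
    if not train_db:
        raise AlignError("empty training database")
    aligner = _make_aligner()
    best_score = 0.0
    best_acc: str | None = None
    for rec in sorted(train_db, key=lambda r: r.accession):
        s = aligner.score(query.sequence, rec.sequence)
        if s > best_score:
            best_score = s
            best_acc = rec.accession
    if best_acc is None:
        return None
    return AlignmentHit(
        query=query.accession, subject=best_acc, bit_score=bit_score(best_score)
    )


def _top_hits_builtin(queries: Sequence, train_db: Sequence) -> dict[str, AlignmentHit]:
    return {
        q.accession: hit for q in queries if (hit := top_hit(q, train_db)) is not None
    }


def _top_hits_blastp(queries: Sequence, train_db: Sequence) -> dict[str, AlignmentHit]:
    if shutil.which("blastp") is None or shutil.which("makeblastdb") is None:
        raise AlignError("blastp/makeblastdb not found on PATH")
    from .corpus import write_fasta

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        write_fasta(train_db, tmp / "db.fa")
        write_fasta(queries, tmp / "q.fa")
        subprocess.run(
            ["makeblastdb", "-in", str(tmp / "db.fa"), "-dbtype", "prot"],
            check=True, capture_output=True,
        )
        proc = subprocess.run(
            [
                "blastp", "-query", str(tmp / "q.fa"), "-db", str(tmp / "db.fa"),
                "-outfmt", "6 qseqid sseqid bitscore",
                "-max_target_seqs", "5", "-evalue", "1e6", "-seg", "no",
            ],
            check=True, capture_output=True, text=True,
        )
    hits: dict[str, AlignmentHit] = {}
    for line in proc.stdout.splitlines():
        q, s, b = line.split("\t")
        b = float(b)
        cur = hits.get(q)
        if cur is None or b > cur.bit_score or (b == cur.bit_score and s < cur.subject):
            hits[q] = AlignmentHit(query=q, subject=s, bit_score=b)
    return hits


def top_hits(
    queries: Sequence, train_db: Sequence, backend: str = "builtin"
) -> dict[str, AlignmentHit]:
    """Top hit per query accession; queries with no hit are absent."""
    if backend == "builtin":
        return _top_hits_builtin(queries, train_db)
    if backend == "blastp":
        return _top_hits_blastp(queries, train_db)
    raise AlignError(f"unknown backend {backend!r}")


def transfer_labels(
    hit: AlignmentHit | None, train_labels: Mapping[str, frozenset]
) -> dict[str, float]:
    """All labels of the hit subject, each scored with the hit bit-score."""
    if hit is None:
        return {}
    labels = train_labels.get(hit.subject)
    if labels is None:
        raise AlignError(f"no labels recorded for subject {hit.subject!r}")
    return {lab: hit.bit_score for lab in labels}


def blast_predictions(
    queries: Sequence, train_records: Sequence, backend: str = "builtin"
) -> dict[str, dict[str, float]]:
    """Label-transfer prediction set for a batch of queries."""
    train_labels = {r.accession: r.labels for r in train_records}
    hits = top_hits(queries, train_records, backend=backend)
    return {
        q.accession: transfer_labels(hits.get(q.accession), train_labels)
        for q in queries
    }


def combine(
    blast: Mapping[str, Mapping[str, float]],
    cnn_mean: Mapping[str, Mapping[str, float]],
    union: bool = False,
) -> dict[str, dict[str, float]]:
    """Rescale transferred bit-scores by CNN probabilities.

    Per query, each label in the transferred (BLAST) set gets
    ``bit_score * cnn_probability`` (probability 0 when the CNN does
    not score the label).  With ``union=True`` labels the CNN scores
    at >= 0.5 but the top hit lacks are admitted as well, scored
    ``bit_score * probability`` using the query's top-hit bit-score
    (or the bare probability when the query had no hit).
    """
    out: dict[str, dict[str, float]] = {}
    for acc, transferred in blast.items():
        cnn = cnn_mean.get(acc, {})
        entry = {lab: s * cnn.get(lab, 0.0) for lab, s in transferred.items()}
        if union:
            top_bit = max(transferred.values(), default=1.0)
            for lab, p in cnn.items():
                if p >= 0.5 and lab not in entry:
                    entry[lab] = top_bit * p
        out[acc] = entry
    return out


# ---------------------------------------------------------------------------
# approximate clustering (small synthetic corpora only)


def approximate_clusters(
    records: Sequence, identity_threshold: float = 0.5
) -> dict[str, str]:
    """Single-linkage clusters at a sequence-identity threshold.

    A lightweight stand-in for UniRef-style cluster tables when testing
    on synthetic corpora: identity is approximated as
    ``1 - edit_distance / max(len)`` and clusters are connected
    components of the >= threshold graph.  Quadratic in the number of
    records — intended for small corpora only; real cluster tables are
    consumed, never computed, at scale.
    """
    import edlib

    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i].sequence, records[j].sequence
            d = edlib.align(a, b)["editDistance"]
            if 1.0 - d / max(len(a), len(b)) >= identity_threshold:
                parent[find(i)] = find(j)
    clusters: dict[str, str] = {}
    for i, rec in enumerate(records):
        clusters[rec.accession] = f"C{find(i)}"
    return clusters
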