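"""Corpus IO, filtering, and train/dev/test split behaviour."""

import numpy as np
import pytest

from protfun.corpus import (
    AnnotatedRecord,
    CorpusError,
    ProteinRecord,
    STANDARD_AA,
    clustered_split,
    filter_records,
    random_split,
    read_corpus,
    read_label_table,
    split_stats,
    write_fasta,
    write_label_table,
)
from protfun.ontology import Namespace, parse_ontology

EC_CHAIN = [
    ("EC:3.2.1.2", "EC:3.2.1.-"),
    ("EC:3.2.1.-", "EC:3.2.-.-"),
    ("EC:3.2.-.-", "EC:3.-.-.-"),
]


@pytest.fixture
def ec_graph():
    return parse_ontology(EC_CHAIN, Namespace.EC_LIKE)


def _write_corpus(tmp_path, rows):
    """rows: list of (accession, sequence, is_fragment, 'lab1,lab2')."""
    fasta = tmp_path / "c.fa"
    labels = tmp_path / "l.tsv"
    with open(fasta, "w") as fh:
        for acc, seq, _f, _l in rows:
            fh.write(f">{acc}\n{seq}\n")
    with open(labels, "w") as fh:
        for acc, _s, frag, labs in rows:
            fh.write(f"{acc}\t{frag}\t{labs}\n")
    return fasta, labels


class TestReadCorpus:
    def test_two_records_read_in_file_order(self, tmp_path, ec_graph):
        fasta, labels = _write_corpus(tmp_path, [
            ("P1", "ACDEF", 0, "EC:3.2.1.2"),
            ("P2", "GHIKL", 0, ""),
        ])
        recs = read_corpus(fasta, labels, ec_graph)
        assert [r.accession for r in recs] == ["P1", "P2"]

    def test_leaf_annotation_closes_to_four_labels(self, tmp_path, ec_graph):
        fasta, labels = _write_corpus(tmp_path, [("P1", "ACDEF", 0, "EC:3.2.1.2")])
        (rec,) = read_corpus(fasta, labels, ec_graph)
        assert len(rec.labels) == 4
        assert rec.leaf_labels == {"EC:3.2.1.2"}

    def test_empty_label_field_means_non_enzyme(self, tmp_path, ec_graph):
        fasta, labels = _write_corpus(tmp_path, [("P1", "ACDEF", 0, "")])
        (rec,) = read_corpus(fasta, labels, ec_graph)
        assert rec.labels == frozenset()

    def test_labelled_accession_missing_from_fasta_errors(self, tmp_path, ec_graph):
        fasta, labels = _write_corpus(tmp_path, [("P1", "ACDEF", 0, "")])
        with open(labels, "a") as fh:
            fh.write("GHOST\t0\tEC:3.2.1.2\n")
        with pytest.raises(CorpusError, match="GHOST"):
            read_corpus(fasta, labels, ec_graph)

    def test_unknown_label_rejected_not_dropped(self, tmp_path, ec_graph):
        fasta, labels = _write_corpus(tmp_path, [("P1", "ACDEF", 0, "EC:1.1.1.1")])
        with pytest.raises(CorpusError, match="EC:1.1.1.1"):
            read_corpus(fasta, labels, ec_graph)

    def test_duplicate_accession_in_table_rejected(self, tmp_path, ec_graph):
        fasta, labels = _write_corpus(tmp_path, [("P1", "ACDEF", 0, "")])
        with open(labels, "a") as fh:
            fh.write("P1\t0\t\n")
        with pytest.raises(CorpusError, match="duplicate"):
            read_label_table(labels)

    def test_fasta_label_round_trip(self, tmp_path, ec_graph):
        fasta, labels = _write_corpus(tmp_path, [
            ("P1", "ACDEF" * 30, 0, "EC:3.2.1.2"),
            ("P2", "GHIKL", 1, ""),
        ])
        recs = read_corpus(fasta, labels, ec_graph)
        write_fasta(recs, tmp_path / "out.fa")
        write_label_table(recs, tmp_path / "out.tsv")
        recs2 = read_corpus(tmp_path / "out.fa", tmp_path / "out.tsv", ec_graph)
        assert [(r.accession, r.sequence, r.labels, r.is_fragment) for r in recs] \
            == [(r.accession, r.sequence, r.labels, r.is_fragment) for r in recs2]


class TestFilter:
    def test_standard_alphabet_kept(self):
        recs = [ProteinRecord("P1", STANDARD_AA)]
        kept, report = filter_records(recs)
        assert len(kept) == 1 and report.total == 0

    def test_nonstandard_residue_rejected(self):
        kept, report = filter_records([ProteinRecord("P1", "ACDXF")])
        assert kept == [] and report.nonstandard_residue == 1

    def test_planted_selenocysteine_records_counted_exactly(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(100):
            seq = "".join(STANDARD_AA[j] for j in rng.integers(0, 20, 50))
            if i % 10 == 0:  # 10 planted U-containing sequences
                seq = seq[:25] + "U" + seq[26:]
            recs.append(ProteinRecord(f"P{i}", seq))
        kept, report = filter_records(recs)
        assert len(kept) == 90
        assert report.nonstandard_residue == 10

    def test_fragments_rejected_and_counted(self):
        kept, report = filter_records([
            ProteinRecord("P1", "ACDEF", is_fragment=True),
            ProteinRecord("P2", "ACDEF"),
        ])
        assert [r.accession for r in kept] == ["P2"]
        assert report.fragment == 1

    def test_filtering_is_idempotent(self):
        recs = [ProteinRecord("P1", "ACDEF"), ProteinRecord("P2", "ACUEF")]
        kept, _ = filter_records(recs)
        kept2, report2 = filter_records(kept)
        assert kept2 == kept and report2.total == 0


class TestRandomSplit:
    def test_fold_sizes_near_80_10_10_at_n_10000(self):
        accs = [f"P{i}" for i in range(10_000)]
        split = random_split(accs, seed=3)
        counts = split.counts()
        assert abs(counts["train"] - 8000) <= 100
        assert abs(counts["dev"] - 1000) <= 100
        assert abs(counts["test"] - 1000) <= 100

    def test_same_seed_reproduces_assignment(self):
        accs = [f"P{i}" for i in range(500)]
        assert random_split(accs, seed=9).fold_of == random_split(accs, seed=9).fold_of

    def test_degenerate_fractions_put_everything_in_train(self):
        accs = [f"P{i}" for i in range(50)]
        split = random_split(accs, fractions=(1.0, 0.0, 0.0), seed=0)
        assert set(split.fold_of.values()) == {"train"}

    def test_assignment_stable_under_reordering(self):
        accs = [f"P{i}" for i in range(300)]
        a = random_split(accs, seed=5).fold_of
        b = random_split(accs[::-1], seed=5).fold_of
        assert a == b

    def test_bad_fractions_rejected(self):
        with pytest.raises(CorpusError, match="sum to 1"):
            random_split(["P1"], fractions=(0.5, 0.2, 0.2), seed=0)

    def test_folds_partition_the_accessions(self):
        accs = [f"P{i}" for i in range(200)]
        split = random_split(accs, seed=1)
        assert sorted(split.fold_of) == sorted(accs)


class TestClusteredSplit:
    def test_three_singletons_one_per_fold(self):
        clusters = {"A": "c1", "B": "c2", "C": "c3"}
        split = clustered_split(["A", "B", "C"], clusters, seed=0)
        assert sorted(split.fold_of.values()) == ["dev", "test", "train"]

    def test_clusters_never_straddle_folds(self):
        rng = np.random.default_rng(11)
        accs, clusters = [], {}
        for c in range(40):
            for m in range(int(rng.geometric(0.3))):
                acc = f"P{c}_{m}"
                accs.append(acc)
                clusters[acc] = f"c{c}"
        split = clustered_split(accs, clusters, seed=2)
        for c in set(clusters.values()):
            folds = {split.fold_of[a] for a in accs if clusters[a] == c}
            assert len(folds) == 1

    def test_geometric_cluster_sizes_fill_folds_within_5_percent(self):
        rng = np.random.default_rng(4)
        accs, clusters = [], {}
        for c in range(300):
            for m in range(int(rng.geometric(0.25))):
                acc = f"P{c}_{m}"
                accs.append(acc)
                clusters[acc] = f"c{c}"
        split = clustered_split(accs, clusters, seed=0)
        counts = split.counts()
        target = len(accs) / 3
        for fold in ("train", "dev", "test"):
            assert abs(counts[fold] - target) <= 0.05 * target

    def test_missing_cluster_id_errors(self):
        with pytest.raises(CorpusError, match="without a cluster"):
            clustered_split(["A", "B"], {"A": "c1"}, seed=0)


class TestSplitStats:
    @staticmethod
    def _records(ec_graph, spec):
        """spec: list of (accession, leaf or None)."""
        out = []
        for acc, leaf in spec:
            leaves = frozenset([leaf]) if leaf else frozenset()
            out.append(AnnotatedRecord(acc, "ACDEF", leaves,
                                       ec_graph.propagate(leaves)))
        return out

    def test_label_absent_from_train_is_impossible(self, ec_graph):
        recs = self._records(ec_graph, [("P1", None), ("P2", "EC:3.2.1.2")])
        split = type(random_split(["x"], seed=0))(
            fold_of={"P1": "train", "P2": "test"}, provenance="random", seed=0
        )
        stats = split_stats(split, recs)
        assert stats["impossible_test_labels"] == 4
        assert stats["impossible_test_pairs"] == 4

    def test_identical_vocabularies_have_zero_impossible(self, ec_graph):
        recs = self._records(ec_graph, [("P1", "EC:3.2.1.2"), ("P2", "EC:3.2.1.2")])
        split = type(random_split(["x"], seed=0))(
            fold_of={"P1": "train", "P2": "test"}, provenance="random", seed=0
        )
        assert split_stats(split, recs)["impossible_test_labels"] == 0

    def test_impossible_counts_match_set_difference_oracle(self, study):
        stats = split_stats(study.split, study.records)
        train_labels = set()
        test_labels = set()
        for r in study.records:
            fold = study.split.fold_of[r.accession]
            if fold == "train":
                train_labels |= r.labels
            elif fold == "test":
                test_labels |= r.labels
        impossible = test_labels - train_labels
        assert stats["impossible_test_labels"] == len(impossible)
        pairs = sum(
            len(r.labels & impossible)
            for r in study.records
            if study.split.fold_of[r.accession] == "test"
        )
        assert stats["impossible_test_pairs"] == pairs
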