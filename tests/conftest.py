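"""Shared fixtures: the synthetic study corpus and the desk-scale trained model.

The heavy fixtures are session-scoped so the 5000-step training run
happens once and is shared by every test that needs a model that has
actually learned the planted motifs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import protfun as pf
from protfun.train import desk_scale_config, train

STUDY_SEED = 1


@dataclass
class Study:
    """The synthetic study: corpus, ground truth, motif table, folds."""

    graph: pf.LabelGraph
    records: list
    truth: pf.SyntheticTruth
    motifs: list
    split: pf.DatasetSplit

    def fold(self, name: str) -> list:
        return self.split.subset(self.records, name)


@pytest.fixture(scope="session")
def graph() -> pf.LabelGraph:
    """4-level synthetic label tree with 24 leaves (33 labels)."""
    return pf.make_ontology(levels=4, branching=(2, 3, 4))


@pytest.fixture(scope="session")
def study(graph) -> Study:
    """n=2000 corpus, lengths 100-600, 5% motif mutation, 80/10/10 split."""
    records, truth, motifs = pf.make_corpus(graph, n=2000, seed=STUDY_SEED)
    split = pf.random_split(records, seed=STUDY_SEED)
    return Study(graph=graph, records=records, truth=truth, motifs=motifs, split=split)


@pytest.fixture(scope="session")
def trained_model(study) -> pf.Model:
    """2-residual-layer, 64-filter model trained 5000 steps on the train fold."""
    config = pf.ModelConfig(
        vocabulary=tuple(study.graph.sorted_labels()),
        num_res_layers=2,
        filters=64,
    )
    model = pf.build_model(config, seed=STUDY_SEED)
    train(model, study.fold("train"), desk_scale_config(seed=STUDY_SEED))
    return model
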