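"""Label hierarchies and ancestor closure of leaf annotations.

Function vocabularies such as Enzyme Commission (EC) numbers and Gene
Ontology (GO) terms are hierarchical: EC numbers form a four-level tree
(EC:3.2.1.2 is-a EC:3.2.1.- is-a EC:3.2.-.- is-a EC:3.-.-.-), while GO
terms form a directed acyclic graph in which a term may have many
parents.  Annotation databases record only the most specific (leaf)
labels; multi-label classifiers need every ancestral label made
explicit, otherwise the model is asked to predict "not DNA binding" for
a sequence-specific DNA binder.  This module represents the hierarchy
and performs that ancestor closure ("label inheritance").

Only ``is_a`` edges are modelled; other ontology relations (``part_of``
etc.) are out of scope.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx


class Namespace(enum.Enum):
    """Flavour of a label vocabulary.

    EC-like graphs are trees (every non-root label has exactly one
    parent); GO-like graphs are general DAGs; SYNTHETIC graphs are the
    planted-motif hierarchies produced by :mod:`protfun.synthetic` and
    follow tree semantics.
    """

    EC_LIKE = "ec"
    GO_LIKE = "go"
    SYNTHETIC = "synthetic"


class OntologyError(ValueError):
    """Structural problem in a label graph (cycle, bad edge, unknown label)."""


@dataclass(frozen=True)
class Label:
    """A single function label: an identifier plus its namespace."""

    id: str
    namespace: Namespace = Namespace.SYNTHETIC

    def __post_init__(self) -> None:
        if not self.id:
            raise OntologyError("label id must be non-empty")


class LabelGraph:
    """Rooted acyclic ``is_a`` hierarchy of function labels.

    Edges are directed child -> parent.  EC-like graphs must be forests
    (single parent per node); GO-like graphs may have multiple parents.

    Parameters
    ----------
    edges
        Iterable of ``(child_id, parent_id)`` pairs.
    namespace
        Vocabulary flavour; controls the single-parent check.
    extra_labels
        Label ids to include even if they take part in no edge.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        namespace: Namespace = Namespace.SYNTHETIC,
        extra_labels: Iterable[str] = (),
    ) -> None:
        self.namespace = namespace
        g = nx.DiGraph()
        seen: set[tuple[str, str]] = set()
        for child, parent in edges:
            if not child or not parent:
                raise OntologyError("edge endpoints must be non-empty ids")
            if child == parent:
                raise OntologyError(f"self-loop on {child!r}")
            if (child, parent) in seen:
                continue  # exact duplicate rows are harmless
            seen.add((child, parent))
            g.add_edge(child, parent)
        for lab in extra_labels:
            g.add_node(lab)
        if not nx.is_directed_acyclic_graph(g):
            cycle = [u for u, _v in nx.find_cycle(g)]
            raise OntologyError(f"cycle detected among labels: {cycle}")
        if namespace is not Namespace.GO_LIKE:
            for node in g.nodes:
                nparents = g.out_degree(node)
                if nparents > 1:
                    parents = sorted(g.successors(node))
                    raise OntologyError(
                        f"{node!r} has {nparents} parents {parents}; "
                        f"{namespace.value} graphs must be trees"
                    )
        self._g = g

    # -- basic queries ---------------------------------------------------

    def __contains__(self, label: str) -> bool:
        return label in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        """(child, parent) pairs."""
        return frozenset(self._g.edges)

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(n for n in self._g.nodes if self._g.out_degree(n) == 0)

    @property
    def leaves(self) -> frozenset[str]:
        return frozenset(n for n in self._g.nodes if self._g.in_degree(n) == 0)

    def parents(self, label: str) -> frozenset[str]:
        self._check(label)
        return frozenset(self._g.successors(label))

    def children(self, label: str) -> frozenset[str]:
        self._check(label)
        return frozenset(self._g.predecessors(label))

    def _check(self, label: str) -> None:
        if label not in self._g:
            raise OntologyError(f"unknown label {label!r}")

    # -- closure ---------------------------------------------------------

    def ancestors(self, label: str) -> frozenset[str]:
        """Transitive ``is_a`` closure of *label*, excluding the label itself."""
        self._check(label)
        return frozenset(nx.descendants(self._g, label))

    def propagate(self, leaf_labels: Iterable[str]) -> frozenset[str]:
        """Ancestor-close a set of labels.

        Returns ``leaf_labels`` together with every ancestor of each
        member.  The result is ancestor-closed and the operation is
        idempotent.
        """
        out: set[str] = set()
        for lab in leaf_labels:
            self._check(lab)
            out.add(lab)
            out.update(nx.descendants(self._g, lab))
        return frozenset(out)

    def most_specific(self, labels: Iterable[str]) -> frozenset[str]:
        """Drop every label that is an ancestor of another label in the set."""
        labels = set(labels)
        for lab in labels:
            self._check(lab)
        redundant = set()
        for lab in labels:
            redundant.update(nx.descendants(self._g, lab) & labels)
        return frozenset(labels - redundant)

    def depth(self, label: str) -> int:
        """Length of the longest path from *label* up to a root."""
        self._check(label)
        anc = nx.descendants(self._g, label)
        if not anc:
            return 0
        sub = self._g.subgraph(anc | {label})
        return max(
            len(p) - 1
            for root in (anc | {label})
            if sub.out_degree(root) == 0
            for p in nx.all_simple_paths(sub, label, root)
        )

    # -- ordering --------------------------------------------------------

    def sorted_labels(self) -> list[str]:
        """Deterministic label ordering (lexicographic) for model vocabularies."""
        return sorted(self._g.nodes)


def parse_ontology(
    edge_table, namespace: Namespace = Namespace.SYNTHETIC
) -> LabelGraph:
    """Build a :class:`LabelGraph` from a two-column child/parent edge table.

    ``edge_table`` may be a path to a headerless two-column TSV, or any
    iterable of ``(child, parent)`` pairs (including a DataFrame's
    ``itertuples``-compatible rows).  Cycles and, for tree namespaces,
    multi-parent nodes are rejected.
    """
    if isinstance(edge_table, (str, Path)):
        edges = _read_edge_tsv(Path(edge_table))
    else:
        edges = [(str(c), str(p)) for c, p in edge_table]
    return LabelGraph(edges, namespace=namespace)


def _read_edge_tsv(path: Path) -> list[tuple[str, str]]:
    edges: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise OntologyError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            edges.append((parts[0], parts[1]))
    return edges


def write_edge_tsv(graph: LabelGraph, path: str | Path) -> None:
    """Write the canonical child<TAB>parent edge list, sorted, no header."""
    with open(path, "w", encoding="utf-8") as fh:
        for child, parent in sorted(graph.edges):
            fh.write(f"{child}\t{parent}\n")


def ancestors(graph: LabelGraph, label: str) -> frozenset[str]:
    """Functional alias for :meth:`LabelGraph.ancestors`."""
    return graph.ancestors(label)


def propagate(graph: LabelGraph, leaf_labels: Iterable[str]) -> frozenset[str]:
    """Functional alias for :meth:`LabelGraph.propagate`."""
    return graph.propagate(leaf_labels)
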