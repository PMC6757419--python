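"""Typed in-memory containers shared across the package.

All matrices follow one orientation convention: rows index miRNAs, columns
index diseases.  Label lists are ordered and duplicate-free; positional
index i of ``mirna_ids`` labels row i everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "DiseaseDAGSet",
    "TransferWeights",
    "ScoreMatrix",
    "LabelMismatchError",
    "IsolatedNodeError",
]

SIMILARITY_KINDS = frozenset(
    {
        "functional",
        "semantic1",
        "semantic2",
        "semantic",
        "gip_mirna",
        "gip_disease",
        "integrated_mirna",
        "integrated_disease",
    }
)

#: kinds whose diagonal must be exactly 1
_UNIT_DIAGONAL_KINDS = frozenset(
    {"semantic1", "semantic2", "semantic", "gip_mirna", "gip_disease"}
)


class LabelMismatchError(ValueError):
    """Raised when two labelled objects that must share labels do not."""


class IsolatedNodeError(ValueError):
    """Raised when nodes with zero (weighted) degree block the projection."""

    def __init__(self, message: str, nodes: list[str] | None = None):
        super().__init__(message)
        self.nodes = nodes or []


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate {what} labels: {dupes}")


@dataclass
class AssociationMatrix:
    """Binary miRNA-disease adjacency matrix A (nm x nd).

    ``values[i, j] == 1`` records a known association between miRNA
    ``mirna_ids[i]`` and disease ``disease_ids[j]``.
    """

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mirna_ids = list(self.mirna_ids)
        self.disease_ids = list(self.disease_ids)
        nm, nd = self.values.shape
        if nm < 1 or nd < 1:
            raise ValueError("association matrix must be at least 1x1")
        if len(self.mirna_ids) != nm or len(self.disease_ids) != nd:
            raise ValueError("label lists do not match matrix shape")
        _check_unique(self.mirna_ids, "miRNA")
        _check_unique(self.disease_ids, "disease")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association entries must be 0 or 1")

    @property
    def nm(self) -> int:
        return self.values.shape[0]

    @property
    def nd(self) -> int:
        return self.values.shape[1]

    def mirna_degrees(self) -> np.ndarray:
        """Per-miRNA association counts (row sums of A)."""
        return self.values.sum(axis=1)

    def disease_degrees(self) -> np.ndarray:
        """Per-disease association counts (column sums of A)."""
        return self.values.sum(axis=0)

    def isolated_nodes(self) -> list[str]:
        """Labels of miRNAs/diseases with no association at all."""
        out = [m for m, k in zip(self.mirna_ids, self.mirna_degrees()) if k == 0]
        out += [d for d, k in zip(self.disease_ids, self.disease_degrees()) if k == 0]
        return out

    def with_masked(self, pairs: Iterable[tuple[int, int]]) -> "AssociationMatrix":
        """Copy with the given (row, col) entries zeroed (held-out folds)."""
        values = self.values.copy()
        for i, j in pairs:
            values[i, j] = 0.0
        return AssociationMatrix(values, self.mirna_ids, self.disease_ids)

    def positive_pairs(self) -> np.ndarray:
        """(n_assoc, 2) array of (row, col) indices of known associations."""
        return np.argwhere(self.values == 1.0)


@dataclass
class SimilarityMatrix:
    """Labelled symmetric similarity matrix with entries in [0, 1]."""

    values: np.ndarray
    ids: list[str]
    kind: str = "functional"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = list(self.ids)
        if self.kind not in SIMILARITY_KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match labels")
        _check_unique(self.ids, "similarity")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise ValueError("similarity matrix is not symmetric within 1e-12")
        if self.values.min() < -1e-12 or self.values.max() > 1.0 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")
        if self.kind in _UNIT_DIAGONAL_KINDS and not np.allclose(
            np.diag(self.values), 1.0, atol=1e-12
        ):
            raise ValueError(f"{self.kind} similarity requires a unit diagonal")

    @property
    def n(self) -> int:
        return len(self.ids)

    def reorder(self, ids: list[str]) -> "SimilarityMatrix":
        """Permute rows/columns to the given label order (must be a permutation)."""
        if set(ids) != set(self.ids) or len(ids) != len(self.ids):
            raise LabelMismatchError("reorder labels are not a permutation")
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return SimilarityMatrix(self.values[np.ix_(idx, idx)], list(ids), self.kind)

    def expand_to(
        self, ids: list[str], kind: str | None = None
    ) -> tuple["SimilarityMatrix", np.ndarray]:
        """Embed into a larger label universe.

        Returns the expanded matrix (missing entries 0, missing diagonal 1 so
        the result stays a valid similarity) together with the boolean
        availability mask: ``mask[i, j]`` is True iff both labels were present
        in the original matrix.  The mask is what the integration step uses,
        so the fill values never leak into results.
        """
        missing = set(self.ids) - set(ids)
        if missing:
            raise LabelMismatchError(f"labels absent from target universe: {sorted(missing)}")
        n = len(ids)
        values = np.zeros((n, n))
        np.fill_diagonal(values, 1.0)
        present = np.array([s in set(self.ids) for s in ids])
        pos = {s: i for i, s in enumerate(self.ids)}
        idx_new = np.flatnonzero(present)
        idx_old = np.array([pos[ids[i]] for i in idx_new])
        values[np.ix_(idx_new, idx_new)] = self.values[np.ix_(idx_old, idx_old)]
        mask = np.outer(present, present)
        return SimilarityMatrix(values, list(ids), kind or self.kind), mask


@dataclass
class DiseaseDAGSet:
    """One ancestor DAG per disease.

    Each graph stores child->parent edges over term identifiers; the disease's
    own term (named after the disease id) is the unique leaf of interest, and
    every term of ``terms(disease)`` is reachable from it by parent edges.
    """

    graphs: dict[str, nx.DiGraph] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for disease, g in self.graphs.items():
            if disease not in g:
                raise ValueError(f"disease {disease!r} term is absent from its own DAG")
            if not nx.is_directed_acyclic_graph(g):
                raise ValueError(f"cycle detected in DAG for disease {disease!r}")

    @property
    def diseases(self) -> list[str]:
        return list(self.graphs)

    def __contains__(self, disease: str) -> bool:
        return disease in self.graphs

    def graph(self, disease: str) -> nx.DiGraph:
        try:
            return self.graphs[disease]
        except KeyError:
            raise KeyError(f"no DAG for disease {disease!r}") from None

    def terms(self, disease: str) -> set[str]:
        """T(S): the disease's own term plus every ancestor reachable from it."""
        g = self.graph(disease)
        return {disease} | nx.descendants(g, disease)

    def term_counts(self) -> Mapping[str, int]:
        """How many disease DAGs contain each term (over reachable terms)."""
        counts: dict[str, int] = {}
        for disease in self.graphs:
            for t in self.terms(disease):
                counts[t] = counts.get(t, 0) + 1
        return counts


@dataclass
class TransferWeights:
    """Edge weights of the bipartite network, both directions.

    ``wr[j, i]`` weights the edge from miRNA j towards disease i (miRNA
    recommendation power); ``wd[j, i]`` weights the edge from disease i
    towards miRNA j.  Both are nm x nd and lie in [0, 1] for binary A.
    """

    wr: np.ndarray
    wd: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.wr = np.asarray(self.wr, dtype=float)
        self.wd = np.asarray(self.wd, dtype=float)
        shape = (len(self.mirna_ids), len(self.disease_ids))
        if self.wr.shape != shape or self.wd.shape != shape:
            raise ValueError("transfer weight shapes do not match labels")


SCORE_STAGES = ("initial", "disease_based", "mirna_based", "final")


@dataclass
class ScoreMatrix:
    """Real-valued nm x nd recommendation scores at a named pipeline stage."""

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]
    stage: str = "final"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.stage not in SCORE_STAGES:
            raise ValueError(f"unknown score stage {self.stage!r}")
        shape = (len(self.mirna_ids), len(self.disease_ids))
        if self.values.shape != shape:
            raise ValueError("score matrix shape does not match labels")
        if not np.isfinite(self.values).all():
            raise ValueError("score matrix contains non-finite entries")
        if self.values.min() < -1e-12:
            raise ValueError("score matrix contains negative entries")

    def same_labels(self, other: "ScoreMatrix | AssociationMatrix") -> bool:
        return (
            self.mirna_ids == other.mirna_ids and self.disease_ids == other.disease_ids
        )
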