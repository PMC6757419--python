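"""Similarity matrices feeding the projection: DAG-based disease semantic
similarity (two models and their average), Gaussian interaction-profile (GIP)
kernels on both axes of the association matrix, and the integration rule that
prefers curated similarity where available and falls back to the kernel.

Disease semantic similarity follows the MeSH-DAG tradition: every disease S
is represented by the DAG of its ancestor terms, each ancestor contributes
either a depth-decayed value (model 1, decay ``delta`` per generation) or an
information-content value (model 2, rarer terms contribute more), and two
diseases are similar in proportion to the contributions of their shared
ancestors relative to their total semantic values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import squareform, pdist

from .containers import (
    AssociationMatrix,
    DiseaseDAGSet,
    IsolatedNodeError,
    LabelMismatchError,
    SimilarityMatrix,
)

__all__ = [
    "SemanticParams",
    "KernelParams",
    "semantic_contribution_m1",
    "semantic_contribution_m2",
    "semantic_value",
    "semantic_similarity",
    "gip_kernel",
    "integrate_similarity",
    "integrated_similarities",
]


@dataclass
class SemanticParams:
    """Parameters of the disease semantic similarity computation.

    delta
        Semantic contribution decay per parent step, in (0, 1].  Default 0.5,
        the convention of the MISIM functional-similarity method this model
        family descends from.
    model
        ``1`` (depth decay), ``2`` (information content) or ``"combined"``
        (elementwise mean of the two).
    """

    delta: float = 0.5
    model: int | str = "combined"

    def __post_init__(self) -> None:
        if not 0.0 < self.delta <= 1.0:
            raise ValueError("delta must lie in (0, 1]")
        if self.model not in (1, 2, "combined"):
            raise ValueError("model must be 1, 2 or 'combined'")


@dataclass
class KernelParams:
    """Raw GIP bandwidths (both default 1) and the bandwidth normalisation.

    ``bandwidth_form="divide"`` scales the raw bandwidth by the reciprocal of
    the mean squared profile norm (the standard GIP-kernel normalisation);
    ``"multiply"`` multiplies instead.
    """

    bandwidth_prime_d: float = 1.0
    bandwidth_prime_m: float = 1.0
    bandwidth_form: str = "divide"

    def __post_init__(self) -> None:
        if self.bandwidth_prime_d <= 0 or self.bandwidth_prime_m <= 0:
            raise ValueError("raw bandwidths must be positive")
        if self.bandwidth_form not in ("divide", "multiply"):
            raise ValueError("bandwidth_form must be 'divide' or 'multiply'")


def semantic_contribution_m1(
    dag_set: DiseaseDAGSet, disease: str, delta: float = 0.5
) -> dict[str, float]:
    """Model-1 contribution of every term in DAG(S) to disease S.

    The disease's own term contributes 1; any other term contributes
    ``delta`` times the largest contribution among its children inside the
    DAG, evaluated bottom-up from S.  Terms unreachable from S are excluded.
    """
    if not 0.0 < delta <= 1.0:
        raise ValueError("delta must lie in (0, 1]")
    g = dag_set.graph(disease)
    terms = dag_set.terms(disease)
    sub = g.subgraph(terms)
    contrib: dict[str, float] = {}
    # child->parent edges: topological order yields children before parents
    for t in nx.topological_sort(sub):
        if t == disease:
            contrib[t] = 1.0
        else:
            children = [c for c in sub.predecessors(t)]
            contrib[t] = delta * max(contrib[c] for c in children)
    return contrib


def semantic_contribution_m2(dag_set: DiseaseDAGSet, disease: str) -> dict[str, float]:
    """Model-2 (information-content) contributions for disease S.

    A term's contribution is -log of the fraction of disease DAGs that
    contain it, so terms shared by every disease contribute nothing and rare
    terms contribute most.  Natural log; any fixed base rescales all
    contributions identically, which cancels in the similarity ratio.
    """
    counts = dag_set.term_counts()
    n = len(dag_set.diseases)
    return {t: -np.log(counts[t] / n) for t in dag_set.terms(disease)}


def semantic_value(contrib: dict[str, float]) -> float:
    """DV(S): total contribution over all terms of the disease's DAG."""
    return float(sum(contrib.values()))


def _pairwise_semantic(
    contribs: dict[str, dict[str, float]], diseases: list[str]
) -> np.ndarray:
    dv = {d: semantic_value(contribs[d]) for d in diseases}
    n = len(diseases)
    values = np.eye(n)
    warned = False
    for a in range(n):
        ca = contribs[diseases[a]]
        for b in range(a + 1, n):
            cb = contribs[diseases[b]]
            shared = ca.keys() & cb.keys()
            denom = dv[diseases[a]] + dv[diseases[b]]
            if denom == 0.0:
                if not warned:
                    warnings.warn(
                        "zero semantic value pair (all terms ubiquitous); "
                        "similarity set to 0",
                        stacklevel=3,
                    )
                    warned = True
                s = 0.0
            else:
                s = sum(ca[t] + cb[t] for t in shared) / denom
            values[a, b] = values[b, a] = s
    # diagonal stays 1: self-similarity is defined as 1 even in the
    # degenerate model-2 case where every own term is ubiquitous (DV=0)
    return values


def semantic_similarity(
    dag_set: DiseaseDAGSet, params: SemanticParams | None = None
) -> SimilarityMatrix:
    """Disease-disease semantic similarity matrix (SS1, SS2 or combined)."""
    params = params or SemanticParams()
    diseases = dag_set.diseases
    if params.model in (1, "combined"):
        c1 = {d: semantic_contribution_m1(dag_set, d, params.delta) for d in diseases}
        ss1 = _pairwise_semantic(c1, diseases)
    if params.model in (2, "combined"):
        c2 = {d: semantic_contribution_m2(dag_set, d) for d in diseases}
        ss2 = _pairwise_semantic(c2, diseases)
    if params.model == 1:
        return SimilarityMatrix(ss1, diseases, "semantic1")
    if params.model == 2:
        return SimilarityMatrix(ss2, diseases, "semantic2")
    return SimilarityMatrix((ss1 + ss2) / 2.0, diseases, "semantic")


def gip_kernel(
    assoc: AssociationMatrix,
    axis: str = "disease",
    params: KernelParams | None = None,
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel similarity on one axis of A.

    Disease profiles are the columns of A, miRNA profiles the rows.  The
    kernel bandwidth is the raw bandwidth normalised by the mean squared
    profile norm (see :class:`KernelParams` for the form switch).
    """
    params = params or KernelParams()
    if axis == "disease":
        profiles = assoc.values.T
        ids = assoc.disease_ids
        raw = params.bandwidth_prime_d
        kind = "gip_disease"
    elif axis == "mirna":
        profiles = assoc.values
        ids = assoc.mirna_ids
        raw = params.bandwidth_prime_m
        kind = "gip_mirna"
    else:
        raise ValueError("axis must be 'disease' or 'mirna'")
    mean_sq = float(np.mean((profiles**2).sum(axis=1)))
    if mean_sq == 0.0:
        raise IsolatedNodeError("empty interaction profiles (all-zero association matrix)")
    bandwidth = raw / mean_sq if params.bandwidth_form == "divide" else raw * mean_sq
    n = len(ids)
    if n == 1:
        values = np.ones((1, 1))
    else:
        sq = squareform(pdist(profiles, metric="sqeuclidean"))
        values = np.exp(-bandwidth * sq)
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0
    return SimilarityMatrix(values, ids, kind)


def integrate_similarity(
    primary: SimilarityMatrix, gip: SimilarityMatrix, has_primary: np.ndarray
) -> SimilarityMatrix:
    """Elementwise selection: curated similarity where available, GIP kernel
    elsewhere.  ``has_primary[i, j]`` marks pairs with curated coverage."""
    if primary.ids != gip.ids:
        raise LabelMismatchError("primary and GIP similarity labels differ")
    has_primary = np.asarray(has_primary, dtype=bool)
    if has_primary.shape != primary.values.shape:
        raise ValueError("availability mask shape does not match the matrices")
    values = np.where(has_primary, primary.values, gip.values)
    kind = "integrated_disease" if gip.kind == "gip_disease" else "integrated_mirna"
    return SimilarityMatrix(values, primary.ids, kind)


def integrated_similarities(
    assoc: AssociationMatrix,
    fs: SimilarityMatrix | None = None,
    ss: SimilarityMatrix | None = None,
    params: KernelParams | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Build the integrated miRNA (MS) and disease (DS) similarity matrices.

    ``fs``/``ss`` may cover a subset of the association labels; the GIP
    kernels computed from ``assoc`` fill every pair lacking curated coverage.
    Passing neither yields pure-kernel similarities.
    """
    km = gip_kernel(assoc, "mirna", params)
    kd = gip_kernel(assoc, "disease", params)
    if fs is not None:
        fs_full, fs_mask = fs.expand_to(assoc.mirna_ids)
        ms = integrate_similarity(fs_full, km, fs_mask)
    else:
        ms = SimilarityMatrix(km.values, km.ids, "integrated_mirna")
    if ss is not None:
        ss_full, ss_mask = ss.expand_to(assoc.disease_ids)
        ds = integrate_similarity(ss_full, kd, ss_mask)
    else:
        ds = SimilarityMatrix(kd.values, kd.ids, "integrated_disease")
    return ms, ds
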