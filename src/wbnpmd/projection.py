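"""Weighted bipartite network projection.

The method scores unobserved miRNA-disease pairs by a two-step diffusion of
"resource" across the known association edges.  Three ingredients distinguish
it from plain network-based inference:

* **transfer weights** — each bipartite edge is weighted by how strongly the
  sending node's similarity neighbourhood supports the receiving node
  (similarity-weighted averages of the adjacency rows/columns);
* **popularity damping** — the initial resource placed on a known edge is
  scaled by ``k**beta`` with ``beta in (-1, 0]``, shrinking the influence of
  high-degree (popular) nodes;
* **two directions** — the diffusion is run once over the disease-based
  network (miRNA->disease->miRNA, weights ``wr``) and once over its exact
  mirror (weights ``wd``); the final score is the average of the two.

The two-step diffusion collapses to a node-to-node propagation matrix P whose
columns sum to one, so total resource is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    AssociationMatrix,
    IsolatedNodeError,
    LabelMismatchError,
    ScoreMatrix,
    SimilarityMatrix,
    TransferWeights,
)

__all__ = [
    "ProjectionParams",
    "transfer_weights",
    "initial_information",
    "propagation_matrix",
    "propagate",
    "final_scores",
    "predict",
    "drop_isolated",
]


@dataclass
class ProjectionParams:
    """beta: popularity-damping exponent in (-1, 0]; 0 is the undamped limit.
    direction: which diffusion(s) to run."""

    beta: float = -0.1
    direction: str = "both"

    def __post_init__(self) -> None:
        if not -1.0 < self.beta <= 0.0:
            raise ValueError("beta must lie in (-1, 0]")
        if self.direction not in ("disease_based", "mirna_based", "both"):
            raise ValueError("direction must be 'disease_based', 'mirna_based' or 'both'")


def _check_alignment(assoc: AssociationMatrix, ms: SimilarityMatrix, ds: SimilarityMatrix) -> None:
    if ms.ids != assoc.mirna_ids:
        raise LabelMismatchError("miRNA similarity labels do not match associations")
    if ds.ids != assoc.disease_ids:
        raise LabelMismatchError("disease similarity labels do not match associations")


def transfer_weights(
    assoc: AssociationMatrix, ms: SimilarityMatrix, ds: SimilarityMatrix
) -> TransferWeights:
    """Similarity-weighted edge weights in both directions.

    ``wr[j, i]`` is the MS-weighted fraction of miRNA j's neighbourhood
    associated with disease i; ``wd[j, i]`` the DS-weighted fraction of
    disease i's neighbourhood associated with miRNA j.  Self-similarity terms
    are included in the sums.
    """
    _check_alignment(assoc, ms, ds)
    ms_row = ms.values.sum(axis=1)
    if np.any(ms_row == 0.0):
        bad = [assoc.mirna_ids[i] for i in np.flatnonzero(ms_row == 0.0)]
        raise IsolatedNodeError(f"miRNA similarity rows sum to zero: {bad}", bad)
    ds_row = ds.values.sum(axis=1)
    if np.any(ds_row == 0.0):
        bad = [assoc.disease_ids[i] for i in np.flatnonzero(ds_row == 0.0)]
        raise IsolatedNodeError(f"disease similarity rows sum to zero: {bad}", bad)
    wr = (ms.values @ assoc.values) / ms_row[:, None]
    wd = (assoc.values @ ds.values) / ds_row[None, :]
    return TransferWeights(wr, wd, assoc.mirna_ids, assoc.disease_ids)


def _damping(k: np.ndarray, beta: float) -> np.ndarray:
    """k**beta with the 0**beta convention: zero-degree nodes get 0 (their
    A entries are all 0 anyway, so no resource is placed there)."""
    damp = np.zeros_like(k, dtype=float)
    nz = k > 0
    damp[nz] = np.power(k[nz], beta)
    return damp


def initial_information(
    assoc: AssociationMatrix, beta: float = -0.1, axis: str = "disease"
) -> ScoreMatrix:
    """Popularity-damped initial resource on the known association edges.

    ``axis="disease"`` (disease-based network) damps by the disease degree
    k_i; ``axis="mirna"`` by the miRNA degree k_j.  Entries with A=0 carry no
    resource regardless of degree.
    """
    if not -1.0 < beta <= 0.0:
        raise ValueError("beta must lie in (-1, 0]")
    if axis == "disease":
        k = assoc.disease_degrees()
        values = assoc.values * _damping(k, beta)[None, :]
    elif axis == "mirna":
        k = assoc.mirna_degrees()
        values = assoc.values * _damping(k, beta)[:, None]
    else:
        raise ValueError("axis must be 'disease' or 'mirna'")
    return ScoreMatrix(values, assoc.mirna_ids, assoc.disease_ids, "initial")


def _weighted_degrees(
    w: np.ndarray, mirna_ids: list[str], disease_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    dm = w.sum(axis=1)
    dd = w.sum(axis=0)
    bad = [mirna_ids[i] for i in np.flatnonzero(dm == 0.0)]
    bad += [disease_ids[j] for j in np.flatnonzero(dd == 0.0)]
    if bad:
        raise IsolatedNodeError(
            "isolated nodes in the weighted bipartite graph "
            f"(zero weighted degree): {bad}; drop them before predicting",
            bad,
        )
    return dm, dd


def propagation_matrix(weights: TransferWeights, direction: str) -> np.ndarray:
    """Node-to-node propagation matrix P of the two-step diffusion.

    Disease-based: nm x nm over miRNAs, built from ``wr``; miRNA-based:
    nd x nd over diseases, built from ``wd``.  Columns sum to one.
    """
    if direction == "disease_based":
        w = weights.wr
        dm, dd = _weighted_degrees(w, weights.mirna_ids, weights.disease_ids)
        # P[j, k] = (1/dm_k) * sum_i w[j,i] w[k,i] / dd_i
        return (w / dd[None, :]) @ (w / dm[:, None]).T
    if direction == "mirna_based":
        w = weights.wd
        dm, dd = _weighted_degrees(w, weights.mirna_ids, weights.disease_ids)
        # P[i, l] = (1/dd_l) * sum_j w[j,i] w[j,l] / dm_j
        return (w / dm[:, None]).T @ (w / dd[None, :])
    raise ValueError("direction must be 'disease_based' or 'mirna_based'")


def propagate(
    assoc: AssociationMatrix,
    weights: TransferWeights,
    s_ini: ScoreMatrix,
    direction: str = "disease_based",
) -> ScoreMatrix:
    """Run the two-step diffusion in one direction.

    Disease-based: S_M = P @ S_ini with P over miRNAs.  MiRNA-based (the
    mirror): S_D = S_ini @ P.T with P over diseases.
    """
    if s_ini.mirna_ids != assoc.mirna_ids or s_ini.disease_ids != assoc.disease_ids:
        raise LabelMismatchError("initial information labels do not match associations")
    p = propagation_matrix(weights, direction)
    if direction == "disease_based":
        values = p @ s_ini.values
        stage = "disease_based"
    else:
        values = s_ini.values @ p.T
        stage = "mirna_based"
    values = np.clip(values, 0.0, None)  # guard tiny negative round-off
    return ScoreMatrix(values, assoc.mirna_ids, assoc.disease_ids, stage)


def final_scores(s_m: ScoreMatrix, s_d: ScoreMatrix) -> ScoreMatrix:
    """Average the disease-based and miRNA-based recommendation scores."""
    if s_m.mirna_ids != s_d.mirna_ids or s_m.disease_ids != s_d.disease_ids:
        raise LabelMismatchError("score matrices carry different labels")
    return ScoreMatrix(
        (s_m.values + s_d.values) / 2.0, s_m.mirna_ids, s_m.disease_ids, "final"
    )


def predict(
    assoc: AssociationMatrix,
    ms: SimilarityMatrix,
    ds: SimilarityMatrix,
    params: ProjectionParams | None = None,
) -> ScoreMatrix:
    """Full projection: weights -> initial information -> both diffusions -> average.

    ``ms``/``ds`` are the integrated miRNA/disease similarities, label-aligned
    with ``assoc``.  Deterministic for fixed inputs.
    """
    params = params or ProjectionParams()
    weights = transfer_weights(assoc, ms, ds)
    if params.direction in ("disease_based", "both"):
        s_ini_d = initial_information(assoc, params.beta, axis="disease")
        s_m = propagate(assoc, weights, s_ini_d, "disease_based")
        if params.direction == "disease_based":
            return s_m
    if params.direction in ("mirna_based", "both"):
        s_ini_m = initial_information(assoc, params.beta, axis="mirna")
        s_d = propagate(assoc, weights, s_ini_m, "mirna_based")
        if params.direction == "mirna_based":
            return s_d
    return final_scores(s_m, s_d)


def drop_isolated(
    assoc: AssociationMatrix,
    ms: SimilarityMatrix | None = None,
    ds: SimilarityMatrix | None = None,
):
    """Remove miRNAs/diseases with no association, restricting similarities
    to the survivors.  Returns (assoc, ms, ds) with None passed through."""
    keep_m = assoc.mirna_degrees() > 0
    keep_d = assoc.disease_degrees() > 0
    if keep_m.all() and keep_d.all():
        return assoc, ms, ds
    mirnas = [m for m, k in zip(assoc.mirna_ids, keep_m) if k]
    diseases = [d for d, k in zip(assoc.disease_ids, keep_d) if k]
    sub = AssociationMatrix(
        assoc.values[np.ix_(keep_m, keep_d)], mirnas, diseases
    )
    if ms is not None:
        idx = np.flatnonzero(keep_m)
        ms = SimilarityMatrix(ms.values[np.ix_(idx, idx)], mirnas, ms.kind)
    if ds is not None:
        idx = np.flatnonzero(keep_d)
        ds = SimilarityMatrix(ds.values[np.ix_(idx, idx)], diseases, ds.kind)
    return sub, ms, ds
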