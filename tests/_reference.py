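"""Independent straight-from-the-definitions reference implementations.

Everything here is deliberately naive (explicit loops, memoization-free
recursion) and shares no code with the package: these functions are the
oracles the package's vectorised implementations are checked against.
"""

from __future__ import annotations

import math

import numpy as np


# --- semantic similarity -------------------------------------------------

def contribution_m1_recursive(edges: dict[str, set[str]], disease: str, term: str,
                              delta: float) -> float:
    """Memoization-free recursive depth-decay contribution.

    ``edges`` maps each term to its parents (child -> parents).
    """
    if term == disease:
        return 1.0
    children = [c for c, parents in edges.items() if term in parents]
    # restrict to children actually on a path from the disease
    vals = [
        delta * contribution_m1_recursive(edges, disease, c, delta)
        for c in children
        if reachable(edges, disease, c)
    ]
    return max(vals)


def reachable(edges: dict[str, set[str]], src: str, dst: str) -> bool:
    if src == dst:
        return True
    return any(reachable(edges, p, dst) for p in edges.get(src, ()))


def terms_of(edges: dict[str, set[str]], disease: str) -> set[str]:
    out = {disease}
    frontier = [disease]
    while frontier:
        t = frontier.pop()
        for p in edges.get(t, ()):
            if p not in out:
                out.add(p)
                frontier.append(p)
    return out


def semantic_sim_m1(edges_a, da, edges_b, db, delta) -> float:
    ta, tb = terms_of(edges_a, da), terms_of(edges_b, db)
    ca = {t: contribution_m1_recursive(edges_a, da, t, delta) for t in ta}
    cb = {t: contribution_m1_recursive(edges_b, db, t, delta) for t in tb}
    num = sum(ca[t] + cb[t] for t in ta & tb)
    return num / (sum(ca.values()) + sum(cb.values()))


def semantic_sim_m2(all_edges: dict[str, dict[str, set[str]]], da: str, db: str,
                    log=math.log) -> float:
    """Information-content similarity; ``log`` pluggable to check base invariance."""
    n = len(all_edges)
    term_sets = {d: terms_of(e, d) for d, e in all_edges.items()}
    counts: dict[str, int] = {}
    for ts in term_sets.values():
        for t in ts:
            counts[t] = counts.get(t, 0) + 1
    d2 = {t: -log(c / n) for t, c in counts.items()}
    ta, tb = term_sets[da], term_sets[db]
    num = sum(2 * d2[t] for t in ta & tb)
    den = sum(d2[t] for t in ta) + sum(d2[t] for t in tb)
    if den == 0.0:
        return 0.0
    return num / den


# --- GIP kernel ----------------------------------------------------------

def gip_loops(a: np.ndarray, axis: str, raw: float = 1.0) -> np.ndarray:
    profiles = a.T if axis == "disease" else a
    n = profiles.shape[0]
    mean_sq = sum(float(p @ p) for p in profiles) / n
    bw = raw / mean_sq
    k = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            diff = profiles[i] - profiles[j]
            k[i, j] = math.exp(-bw * float(diff @ diff))
    return k


# --- projection ----------------------------------------------------------

def transfer_weights_loops(a: np.ndarray, ms: np.ndarray, ds: np.ndarray):
    nm, nd = a.shape
    wr = np.zeros((nm, nd))
    wd = np.zeros((nm, nd))
    for j in range(nm):
        for i in range(nd):
            wr[j, i] = sum(ms[j, k] * a[k, i] for k in range(nm)) / sum(
                ms[j, k] for k in range(nm)
            )
            wd[j, i] = sum(ds[i, k] * a[j, k] for k in range(nd)) / sum(
                ds[i, k] for k in range(nd)
            )
    return wr, wd


def initial_information_loops(a: np.ndarray, beta: float, axis: str) -> np.ndarray:
    nm, nd = a.shape
    s = np.zeros((nm, nd))
    for j in range(nm):
        for i in range(nd):
            if a[j, i] == 1.0:
                k = a[:, i].sum() if axis == "disease" else a[j, :].sum()
                s[j, i] = k**beta
    return s


def propagate_disease_based_loops(wr: np.ndarray, s_ini: np.ndarray) -> np.ndarray:
    """First-step then second-step sums, written exactly as the definitions."""
    nm, nd = wr.shape
    dm = [wr[k, :].sum() for k in range(nm)]
    dd = [wr[:, i].sum() for i in range(nd)]
    s_m = np.zeros((nm, nd))
    for col in range(nd):  # diffusion runs once per initial-information column
        s_mid = [
            sum(wr[k, i] * s_ini[k, col] / dm[k] for k in range(nm)) for i in range(nd)
        ]
        for j in range(nm):
            s_m[j, col] = sum(wr[j, i] * s_mid[i] / dd[i] for i in range(nd))
    return s_m


def propagation_matrix_loops(wr: np.ndarray) -> np.ndarray:
    nm, nd = wr.shape
    dm = [wr[k, :].sum() for k in range(nm)]
    dd = [wr[:, i].sum() for i in range(nd)]
    p = np.zeros((nm, nm))
    for j in range(nm):
        for k in range(nm):
            p[j, k] = sum(wr[j, i] * wr[k, i] / dd[i] for i in range(nd)) / dm[k]
    return p


def propagate_mirna_based_loops(wd: np.ndarray, s_ini: np.ndarray) -> np.ndarray:
    """Exact mirror of the disease-based diffusion, over the disease side."""
    nm, nd = wd.shape
    dm = [wd[j, :].sum() for j in range(nm)]
    dd = [wd[:, i].sum() for i in range(nd)]
    s_d = np.zeros((nm, nd))
    for row in range(nm):
        s_mid = [
            sum(wd[j, i] * s_ini[row, i] / dd[i] for i in range(nd)) for j in range(nm)
        ]
        for i in range(nd):
            s_d[row, i] = sum(wd[j, i] * s_mid[j] / dm[j] for j in range(nm))
    return s_d


def unweighted_nbi_loops(a: np.ndarray) -> np.ndarray:
    """Classic two-step resource allocation on the unweighted bipartite graph.

    Each disease splits its resource equally among its miRNAs, then each
    miRNA splits what it gathered equally among its diseases; run on both
    sides and averaged, mirroring the two-direction scheme with all-ones
    similarities and no damping.
    """
    nm, nd = a.shape
    km = a.sum(axis=1)
    kd = a.sum(axis=0)
    s_m = np.zeros((nm, nd))
    for col in range(nd):
        s_mid = [sum(a[k, i] * a[k, col] / km[k] for k in range(nm)) for i in range(nd)]
        for j in range(nm):
            s_m[j, col] = sum(a[j, i] * s_mid[i] / kd[i] for i in range(nd))
    s_d = np.zeros((nm, nd))
    for row in range(nm):
        s_mid = [sum(a[j, i] * a[row, i] / kd[i] for i in range(nd)) for j in range(nm)]
        for i in range(nd):
            s_d[row, i] = sum(a[j, i] * s_mid[j] / km[j] for j in range(nm))
    return (s_m + s_d) / 2.0


# --- AUC -----------------------------------------------------------------

def auc_pair_counting(scores: np.ndarray, labels: np.ndarray) -> float:
    """Brute force over all positive-negative pairs, ties counted half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def wbnpmd_reference(a: np.ndarray, ms: np.ndarray, ds: np.ndarray, beta: float):
    """Full pipeline by loops; returns every intermediate keyed by name."""
    wr, wd = transfer_weights_loops(a, ms, ds)
    s_ini_d = initial_information_loops(a, beta, "disease")
    s_ini_m = initial_information_loops(a, beta, "mirna")
    p = propagation_matrix_loops(wr)
    s_m = propagate_disease_based_loops(wr, s_ini_d)
    s_d = propagate_mirna_based_loops(wd, s_ini_m)
    return {
        "wr": wr,
        "wd": wd,
        "s_ini_disease": s_ini_d,
        "s_ini_mirna": s_ini_m,
        "P": p,
        "S_M": s_m,
        "S_D": s_d,
        "S_fin": (s_m + s_d) / 2.0,
    }
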