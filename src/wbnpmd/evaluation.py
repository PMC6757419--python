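"""Cross-validated evaluation of the projection.

LOOCV treats every known association as a held-out test pair in turn; the
repeated k-fold protocol shuffles the known pairs into k near-equal groups
and holds each group out.  In both protocols everything downstream of the
adjacency matrix (GIP kernels, integrated similarities, transfer weights,
initial information) is recomputed from the masked matrix by default, so no
information about a held-out pair leaks into its own score; the
:class:`RecomputeFlags` let each stage be frozen to probe exactly that
leakage.

The pooled AUC compares each held-out positive (Mann-Whitney, ties counted
half) against every pair never observed in the full matrix, scored within the
positive's own fold; the global AUC is the mean of these per-positive
fractions.  With k = number of associations and one repetition, k-fold
reduces exactly to LOOCV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .containers import (
    AssociationMatrix,
    IsolatedNodeError,
    ScoreMatrix,
    SimilarityMatrix,
)
from .projection import (
    ProjectionParams,
    final_scores,
    initial_information,
    propagate,
    transfer_weights,
)
from .similarity import KernelParams, gip_kernel, integrate_similarity

__all__ = [
    "RocCurve",
    "CVResult",
    "RecomputeFlags",
    "roc_auc",
    "loocv",
    "kfold_cv",
    "beta_sweep",
    "top_k_candidates",
    "degree_product_scores",
]


@dataclass
class RocCurve:
    """ROC curve points, (0,0) to (1,1), with the thresholds that generate them."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds}
        )


@dataclass
class CVResult:
    """Outcome of one cross-validation run.

    ``records`` holds one row per held-out association (score, rank among the
    never-observed candidates, per-positive AUC fraction, failure flag).
    ``auc`` is the pooled AUC; for repeated k-fold, ``auc_mean``/``auc_sd``
    summarise the per-repetition AUCs.
    """

    protocol: str
    records: pd.DataFrame
    auc: float
    auc_mean: float | None = None
    auc_sd: float | None = None
    seed: int | None = None
    params: dict = field(default_factory=dict)
    failed_folds: int = 0

    def summary(self) -> dict:
        out = {
            "protocol": self.protocol,
            "auc": self.auc,
            "n_records": int(len(self.records)),
            "failed_folds": int(self.failed_folds),
            "seed": self.seed,
            "params": self.params,
        }
        if self.auc_mean is not None:
            out["auc_mean"] = self.auc_mean
            out["auc_sd"] = self.auc_sd
        return out


@dataclass
class RecomputeFlags:
    """Which A-dependent stages are recomputed from the masked matrix per fold."""

    gip: bool = True
    integrated: bool = True
    transfer_weights: bool = True
    initial_information: bool = True

    @classmethod
    def none(cls) -> "RecomputeFlags":
        return cls(False, False, False, False)


def roc_auc(scored: Sequence[tuple[float, int]]) -> tuple[RocCurve, float]:
    """ROC curve and AUC for (score, label) pairs.

    AUC uses the rank-sum (Mann-Whitney) formulation with tied scores counted
    half, the probability that a random positive outscores a random negative.
    """
    arr = np.asarray(scored, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a sequence of (score, label) pairs")
    scores, labels = arr[:, 0], arr[:, 1]
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs at least one positive and one negative label")
    ranks = rankdata(scores)  # average ranks: ties count half
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return RocCurve(fpr, tpr, thr), float(auc)


def _positive_fraction(score: float, negatives: np.ndarray) -> float:
    """Fraction of negatives outscored by one positive (ties half)."""
    return ((negatives < score).sum() + 0.5 * (negatives == score).sum()) / len(negatives)


class _FoldPipeline:
    """Shared per-fold scoring machinery for LOOCV and k-fold.

    Stages frozen by the flags reuse the full-matrix versions computed once
    here; recomputed stages start from the fold's masked adjacency matrix.
    """

    def __init__(
        self,
        assoc: AssociationMatrix,
        fs: SimilarityMatrix | None,
        ss: SimilarityMatrix | None,
        params: ProjectionParams,
        flags: RecomputeFlags,
        kernel_params: KernelParams | None = None,
        scorer: Callable[[AssociationMatrix], np.ndarray] | None = None,
    ) -> None:
        self.assoc = assoc
        self.params = params
        self.flags = flags
        self.kernel = kernel_params or KernelParams()
        self.scorer = scorer
        if scorer is not None:
            return
        # curated similarities expanded to the full label universe, with masks
        if fs is not None:
            self.fs_full, self.fs_mask = fs.expand_to(assoc.mirna_ids)
        else:
            self.fs_full, self.fs_mask = None, None
        if ss is not None:
            self.ss_full, self.ss_mask = ss.expand_to(assoc.disease_ids)
        else:
            self.ss_full, self.ss_mask = None, None
        # full-matrix stages, reused wherever a flag freezes recomputation
        self.km0 = gip_kernel(assoc, "mirna", self.kernel)
        self.kd0 = gip_kernel(assoc, "disease", self.kernel)
        self.ms0 = self._integrate_m(self.km0)
        self.ds0 = self._integrate_d(self.kd0)
        self.tw0 = transfer_weights(assoc, self.ms0, self.ds0)

    def _integrate_m(self, km: SimilarityMatrix) -> SimilarityMatrix:
        if self.fs_full is None:
            return SimilarityMatrix(km.values, km.ids, "integrated_mirna")
        return integrate_similarity(self.fs_full, km, self.fs_mask)

    def _integrate_d(self, kd: SimilarityMatrix) -> SimilarityMatrix:
        if self.ss_full is None:
            return SimilarityMatrix(kd.values, kd.ids, "integrated_disease")
        return integrate_similarity(self.ss_full, kd, self.ss_mask)

    def score(self, masked: AssociationMatrix) -> np.ndarray:
        """Score matrix for one fold's masked adjacency matrix."""
        if self.scorer is not None:
            return self.scorer(masked)
        f = self.flags
        km = gip_kernel(masked, "mirna", self.kernel) if f.gip else self.km0
        kd = gip_kernel(masked, "disease", self.kernel) if f.gip else self.kd0
        ms = self._integrate_m(km) if f.integrated else self.ms0
        ds = self._integrate_d(kd) if f.integrated else self.ds0
        tw = transfer_weights(masked, ms, ds) if f.transfer_weights else self.tw0
        a_ini = masked if f.initial_information else self.assoc
        s_ini_d = initial_information(a_ini, self.params.beta, "disease")
        s_m = propagate(masked, tw, s_ini_d, "disease_based")
        s_ini_m = initial_information(a_ini, self.params.beta, "mirna")
        s_d = propagate(masked, tw, s_ini_m, "mirna_based")
        return final_scores(s_m, s_d).values


def _run_folds(
    pipeline: _FoldPipeline,
    groups: list[np.ndarray],
    neg_mask: np.ndarray,
    fold_offset: int = 0,
) -> list[dict]:
    """Score every held-out group; one record per held-out positive."""
    assoc = pipeline.assoc
    records = []
    for fold, group in enumerate(groups, start=fold_offset):
        pairs = [tuple(p) for p in group]
        masked = assoc.with_masked(pairs)
        try:
            values = pipeline.score(masked)
        except IsolatedNodeError as err:
            for i, j in pairs:
                records.append(
                    {
                        "miRNA_id": assoc.mirna_ids[i],
                        "disease_id": assoc.disease_ids[j],
                        "fold": fold,
                        "score": np.nan,
                        "rank": np.nan,
                        "auc_fraction": np.nan,
                        "failed": True,
                    }
                )
            warnings.warn(f"fold {fold} failed: {err}", stacklevel=2)
            continue
        negatives = values[neg_mask]
        for i, j in pairs:
            s = values[i, j]
            records.append(
                {
                    "miRNA_id": assoc.mirna_ids[i],
                    "disease_id": assoc.disease_ids[j],
                    "fold": fold,
                    "score": s,
                    "rank": 1.0 + (negatives > s).sum() + 0.5 * (negatives == s).sum(),
                    "auc_fraction": _positive_fraction(s, negatives),
                    "failed": False,
                }
            )
    return records


def _pooled_auc(records: pd.DataFrame) -> float:
    ok = records.loc[~records["failed"], "auc_fraction"]
    if ok.empty:
        raise ValueError("all cross-validation folds failed")
    return float(ok.mean())


def loocv(
    assoc: AssociationMatrix,
    fs: SimilarityMatrix | None = None,
    ss: SimilarityMatrix | None = None,
    params: ProjectionParams | None = None,
    flags: RecomputeFlags | None = None,
    kernel_params: KernelParams | None = None,
    scorer: Callable[[AssociationMatrix], np.ndarray] | None = None,
) -> CVResult:
    """Leave-one-out cross-validation over the known associations.

    ``fs``/``ss`` are the curated miRNA functional and disease semantic
    similarities (each may cover a subset of the labels; GIP fills the rest).
    ``scorer`` substitutes an arbitrary scoring function of the masked matrix
    (used for baselines); default is the full projection pipeline.
    """
    params = params or ProjectionParams()
    flags = flags or RecomputeFlags()
    positives = assoc.positive_pairs()
    if len(positives) < 2:
        raise ValueError("LOOCV needs at least 2 known associations")
    pipeline = _FoldPipeline(assoc, fs, ss, params, flags, kernel_params, scorer)
    neg_mask = assoc.values == 0.0
    groups = [positives[i : i + 1] for i in range(len(positives))]
    records = pd.DataFrame(_run_folds(pipeline, groups, neg_mask))
    return CVResult(
        protocol="loocv",
        records=records,
        auc=_pooled_auc(records),
        params={"beta": params.beta, "flags": vars(flags)},
        failed_folds=int(records["failed"].sum()),
    )


def _repetition_seeds(seed: int, repeats: int) -> list[np.random.Generator]:
    """One independent generator per repetition, all derived from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(repeats)]


def kfold_cv(
    assoc: AssociationMatrix,
    fs: SimilarityMatrix | None = None,
    ss: SimilarityMatrix | None = None,
    params: ProjectionParams | None = None,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    flags: RecomputeFlags | None = None,
    kernel_params: KernelParams | None = None,
    scorer: Callable[[AssociationMatrix], np.ndarray] | None = None,
) -> CVResult:
    """Repeated k-fold cross-validation over the known associations.

    Each repetition shuffles the known pairs with its own generator derived
    from ``seed``, splits them into k groups whose sizes differ by at most
    one, and holds each group out in turn.  Reports the per-repetition pooled
    AUCs as mean +/- sd.
    """
    params = params or ProjectionParams()
    flags = flags or RecomputeFlags()
    if k < 2:
        raise ValueError("k must be at least 2")
    positives = assoc.positive_pairs()
    if len(positives) < k:
        raise ValueError("fewer known associations than folds")
    pipeline = _FoldPipeline(assoc, fs, ss, params, flags, kernel_params, scorer)
    neg_mask = assoc.values == 0.0
    all_records = []
    rep_aucs = []
    for rep, rng in enumerate(_repetition_seeds(seed, repeats)):
        perm = rng.permutation(len(positives))
        groups = np.array_split(positives[perm], k)
        recs = pd.DataFrame(_run_folds(pipeline, groups, neg_mask, fold_offset=0))
        recs["repetition"] = rep
        all_records.append(recs)
        rep_aucs.append(_pooled_auc(recs))
    records = pd.concat(all_records, ignore_index=True)
    rep_aucs_arr = np.array(rep_aucs)
    return CVResult(
        protocol="kfold",
        records=records,
        auc=float(rep_aucs_arr.mean()),
        auc_mean=float(rep_aucs_arr.mean()),
        auc_sd=float(rep_aucs_arr.std(ddof=1)) if repeats > 1 else 0.0,
        seed=seed,
        params={"beta": params.beta, "k": k, "repeats": repeats, "flags": vars(flags)},
        failed_folds=int(records["failed"].sum()),
    )


def beta_sweep(
    assoc: AssociationMatrix,
    fs: SimilarityMatrix | None = None,
    ss: SimilarityMatrix | None = None,
    betas: Sequence[float] = tuple(np.round(np.arange(-0.9, 0.01, 0.1), 10)),
    protocol: str = "loocv",
    params: ProjectionParams | None = None,
    **cv_kwargs,
) -> tuple[pd.DataFrame, float]:
    """AUC as a function of the damping exponent beta.

    Runs the chosen CV protocol once per beta and returns the (beta, auc)
    table together with the argmax beta.
    """
    params = params or ProjectionParams()
    rows = []
    for beta in betas:
        p = replace(params, beta=float(beta))
        if protocol == "loocv":
            res = loocv(assoc, fs, ss, p, **cv_kwargs)
        elif protocol == "kfold":
            res = kfold_cv(assoc, fs, ss, p, **cv_kwargs)
        else:
            raise ValueError("protocol must be 'loocv' or 'kfold'")
        rows.append((float(beta), res.auc))
    table = pd.DataFrame(rows, columns=["beta", "auc"])
    best = float(table.loc[table["auc"].idxmax(), "beta"])
    return table, best


def top_k_candidates(
    scores: ScoreMatrix, assoc: AssociationMatrix, disease: str, k: int
) -> list[tuple[str, float]]:
    """Top-k unobserved miRNAs for one disease, by descending score
    (lexicographic id tie-break).  Shorter than k if candidates run out."""
    if disease not in assoc.disease_ids:
        raise KeyError(f"unknown disease {disease!r}")
    if k < 1:
        raise ValueError("k must be at least 1")
    j = assoc.disease_ids.index(disease)
    candidates = [
        (assoc.mirna_ids[i], float(scores.values[i, j]))
        for i in range(assoc.nm)
        if assoc.values[i, j] == 0.0
    ]
    candidates.sort(key=lambda t: (-t[1], t[0]))
    return candidates[:k]


def degree_product_scores(masked: AssociationMatrix) -> np.ndarray:
    """Popularity-only baseline: score(m, d) = k_m * k_d of the fold's matrix."""
    return np.outer(masked.mirna_degrees(), masked.disease_degrees())
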