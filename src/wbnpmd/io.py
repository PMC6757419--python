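"""Readers and writers for the on-disk artifacts.

File dialects (all TSV, ``#`` comment lines allowed):

* association edge list — two columns ``miRNA_id<TAB>disease_id``.  The writer
  additionally emits ``#mirnas:`` / ``#diseases:`` directive comments that fix
  the full label universe and order; the reader honours them when present and
  otherwise falls back to first-appearance order, so plain external edge lists
  load unchanged.
* similarity matrix — labelled square matrix, row labels in the first column,
  column labels in the header row.
* disease DAG edge list — three columns ``disease_id<TAB>child<TAB>parent``;
  a root term is declared with parent ``-``.
* ranked predictions — ``disease_id<TAB>rank<TAB>miRNA_id<TAB>score``.
"""

from __future__ import annotations

import os
from typing import Iterator

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    AssociationMatrix,
    DiseaseDAGSet,
    LabelMismatchError,
    ScoreMatrix,
    SimilarityMatrix,
)

__all__ = [
    "read_association_table",
    "write_association_table",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_disease_dag",
    "write_disease_dag",
    "write_ranked_predictions",
    "ranked_predictions",
    "read_score_matrix",
    "write_score_matrix",
]

_HEADER_TOKENS = {"mirna", "mirna_id", "disease", "disease_id", "mir", "mirna_name"}


def _data_lines(path: str | os.PathLike) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, stripped content) skipping blanks/comments."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _directives(path: str | os.PathLike) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("#mirnas:"):
                out["mirnas"] = line[len("#mirnas:") :].strip().split("\t")
            elif line.startswith("#diseases:"):
                out["diseases"] = line[len("#diseases:") :].strip().split("\t")
    return out


def read_association_table(path: str | os.PathLike) -> AssociationMatrix:
    """Load a binary association matrix from a 2-column edge list.

    Duplicate rows collapse to a single association.  Label order is the
    first-appearance order of each identifier unless directive comments
    (written by :func:`write_association_table`) fix it explicitly.
    """
    pairs: list[tuple[str, str]] = []
    first = True
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) == 1:  # tolerate space/comma-separated external files
            for sep in (",", None):
                fields = line.split(sep)
                if len(fields) == 2:
                    break
        if len(fields) != 2:
            raise ValueError(
                f"{path}: line {lineno}: expected 2 fields, got {len(fields)}"
            )
        m, d = (f.strip() for f in fields)
        if first and m.lower() in _HEADER_TOKENS and d.lower() in _HEADER_TOKENS:
            first = False
            continue  # optional header row
        first = False
        pairs.append((m, d))
    if not pairs:
        raise ValueError(f"{path}: no association rows found")

    directives = _directives(path)
    mirnas = directives.get("mirnas")
    diseases = directives.get("diseases")
    if mirnas is None:
        mirnas = list(dict.fromkeys(m for m, _ in pairs))
    if diseases is None:
        diseases = list(dict.fromkeys(d for _, d in pairs))
    mi = {m: i for i, m in enumerate(mirnas)}
    di = {d: j for j, d in enumerate(diseases)}
    values = np.zeros((len(mirnas), len(diseases)))
    for m, d in pairs:
        if m not in mi or d not in di:
            raise ValueError(f"{path}: pair ({m}, {d}) outside the declared label universe")
        values[mi[m], di[d]] = 1.0
    return AssociationMatrix(values, mirnas, diseases)


def write_association_table(assoc: AssociationMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#mirnas:\t" + "\t".join(assoc.mirna_ids) + "\n")
        fh.write("#diseases:\t" + "\t".join(assoc.disease_ids) + "\n")
        for i, j in assoc.positive_pairs():
            fh.write(f"{assoc.mirna_ids[i]}\t{assoc.disease_ids[j]}\n")


def read_similarity_matrix(
    path: str | os.PathLike, kind: str = "functional"
) -> SimilarityMatrix:
    """Load a labelled square similarity matrix.

    Columns are re-ordered to the row-label order; asymmetries up to 1e-8 are
    averaged away, anything larger is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if len(rows) != len(cols):
        raise ValueError(f"{path}: similarity matrix is not square ({len(rows)}x{len(cols)})")
    if set(rows) != set(cols):
        raise LabelMismatchError(f"{path}: row and column labels differ")
    df.columns = cols
    df = df[rows]  # align column order to row order
    values = df.to_numpy(dtype=float)
    asym = np.abs(values - values.T).max()
    if asym > 1e-8:
        raise ValueError(f"{path}: similarity matrix asymmetry {asym:.3g} exceeds 1e-8")
    values = (values + values.T) / 2.0
    return SimilarityMatrix(values, rows, kind)


def write_similarity_matrix(sim: SimilarityMatrix, path: str | os.PathLike) -> None:
    pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids).to_csv(path, sep="\t")


def read_disease_dag(path: str | os.PathLike) -> DiseaseDAGSet:
    """Load per-disease ancestor DAGs from a 3-column edge list."""
    graphs: dict[str, nx.DiGraph] = {}
    seen_any = False
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 3:
            raise ValueError(
                f"{path}: line {lineno}: expected 3 fields, got {len(fields)}"
            )
        disease, child, parent = fields
        if seen_any is False and [f.lower() for f in fields[:2]] == ["disease_id", "child_term"]:
            continue  # optional header
        seen_any = True
        g = graphs.setdefault(disease, nx.DiGraph())
        g.add_node(child)
        if parent != "-":
            g.add_edge(child, parent)
    if not graphs:
        raise ValueError(f"{path}: no DAG rows found")
    for disease, g in graphs.items():
        if disease not in g:
            raise ValueError(
                f"{path}: disease {disease!r} term is absent from its own DAG"
            )
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(f"{path}: cycle detected in DAG for disease {disease!r}")
    return DiseaseDAGSet(graphs)


def write_disease_dag(dag_set: DiseaseDAGSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#disease_id\tchild_term\tparent_term\n")
        for disease in dag_set.diseases:
            g = dag_set.graph(disease)
            edges = sorted(g.edges())
            if not edges:
                fh.write(f"{disease}\t{disease}\t-\n")
                continue
            roots = sorted(n for n in g if g.out_degree(n) == 0)
            for child, parent in edges:
                fh.write(f"{disease}\t{child}\t{parent}\n")
            for root in roots:
                fh.write(f"{disease}\t{root}\t-\n")


def ranked_predictions(scores: ScoreMatrix, assoc: AssociationMatrix) -> pd.DataFrame:
    """Per-disease ranking of unobserved pairs, highest score first.

    Ties break lexicographically on the miRNA identifier so output is
    reproducible across platforms.
    """
    if not scores.same_labels(assoc):
        raise LabelMismatchError("scores and associations carry different labels")
    rows = []
    for j, disease in enumerate(assoc.disease_ids):
        candidates = [
            (assoc.mirna_ids[i], scores.values[i, j])
            for i in range(assoc.nm)
            if assoc.values[i, j] == 0.0
        ]
        candidates.sort(key=lambda t: (-t[1], t[0]))
        for rank, (mirna, score) in enumerate(candidates, start=1):
            rows.append((disease, rank, mirna, score))
    return pd.DataFrame(rows, columns=["disease_id", "rank", "miRNA_id", "score"])


def write_ranked_predictions(
    scores: ScoreMatrix, assoc: AssociationMatrix, path: str | os.PathLike
) -> None:
    ranked_predictions(scores, assoc).to_csv(path, sep="\t", index=False)


def read_score_matrix(path: str | os.PathLike, stage: str = "final") -> ScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ScoreMatrix(
        df.to_numpy(dtype=float),
        [str(r) for r in df.index],
        [str(c) for c in df.columns],
        stage,
    )


def write_score_matrix(scores: ScoreMatrix, path: str | os.PathLike) -> None:
    pd.DataFrame(
        scores.values, index=scores.mirna_ids, columns=scores.disease_ids
    ).to_csv(path, sep="\t")
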