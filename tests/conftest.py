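import networkx as nx
import numpy as np
import pytest

from wbnpmd import (
    AssociationMatrix,
    DiseaseDAGSet,
    SimilarityMatrix,
    generate_worked_example,
)


@pytest.fixture(scope="session")
def worked_example():
    return generate_worked_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_association(rng, nm, nd, p=0.35):
    """Binary matrix with no all-zero row or column (bounded resampling)."""
    for _ in range(200):
        values = (rng.random((nm, nd)) < p).astype(float)
        if values.sum(axis=1).all() and values.sum(axis=0).all():
            return AssociationMatrix(
                values, [f"m{i}" for i in range(nm)], [f"d{j}" for j in range(nd)]
            )
    raise RuntimeError("could not draw a valid association matrix")


def random_similarity(rng, ids, kind="integrated_mirna"):
    """Random symmetric matrix in [0, 1] with unit diagonal."""
    n = len(ids)
    raw = rng.random((n, n))
    values = (raw + raw.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, list(ids), kind)


def chain_dag_set():
    """dA = {A}; dB = {B -> A}: the smallest non-trivial semantic instance."""
    ga = nx.DiGraph()
    ga.add_node("dA")
    gb = nx.DiGraph()
    gb.add_edge("dB", "dA")
    return DiseaseDAGSet({"dA": ga, "dB": gb})


@pytest.fixture()
def chain_dags():
    return chain_dag_set()
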