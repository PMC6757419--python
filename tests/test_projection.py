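import numpy as np
import pytest

from wbnpmd import (
    AssociationMatrix,
    IsolatedNodeError,
    ProjectionParams,
    SimilarityMatrix,
    final_scores,
    initial_information,
    predict,
    propagate,
    propagation_matrix,
    transfer_weights,
)
from wbnpmd.containers import ScoreMatrix

from . import _reference as ref
from .conftest import random_association, random_similarity


def _identity_sim(ids, kind="integrated_mirna"):
    return SimilarityMatrix(np.eye(len(ids)), list(ids), kind)


def _ones_sim(ids, kind="integrated_mirna"):
    return SimilarityMatrix(np.ones((len(ids), len(ids))), list(ids), kind)


def _random_instance(rng, nm, nd):
    assoc = random_association(rng, nm, nd)
    ms = random_similarity(rng, assoc.mirna_ids, "integrated_mirna")
    ds = random_similarity(rng, assoc.disease_ids, "integrated_disease")
    return assoc, ms, ds


class TestTransferWeights:
    def test_identity_similarity_recovers_adjacency(self, rng):
        assoc = random_association(rng, 6, 4)
        tw = transfer_weights(
            assoc,
            _identity_sim(assoc.mirna_ids),
            _identity_sim(assoc.disease_ids, "integrated_disease"),
        )
        np.testing.assert_allclose(tw.wr, assoc.values, atol=1e-12)
        np.testing.assert_allclose(tw.wd, assoc.values, atol=1e-12)

    def test_all_ones_similarity_gives_degree_fractions(self, rng):
        assoc = random_association(rng, 6, 4)
        tw = transfer_weights(
            assoc,
            _ones_sim(assoc.mirna_ids),
            _ones_sim(assoc.disease_ids, "integrated_disease"),
        )
        np.testing.assert_allclose(
            tw.wr, np.tile(assoc.disease_degrees() / 6, (6, 1)), atol=1e-12
        )
        np.testing.assert_allclose(
            tw.wd, np.tile((assoc.mirna_degrees() / 4)[:, None], (1, 4)), atol=1e-12
        )

    def test_hand_value(self):
        assoc = AssociationMatrix(np.array([[1.0], [0.0]]), ["m1", "m2"], ["d1"])
        ms = SimilarityMatrix(
            np.array([[1.0, 0.5], [0.5, 1.0]]), ["m1", "m2"], "integrated_mirna"
        )
        ds = SimilarityMatrix(np.array([[1.0]]), ["d1"], "integrated_disease")
        tw = transfer_weights(assoc, ms, ds)
        assert tw.wr[1, 0] == pytest.approx(1 / 3, abs=1e-12)

    def test_matches_loop_reference(self, rng):
        assoc, ms, ds = _random_instance(rng, 7, 5)
        tw = transfer_weights(assoc, ms, ds)
        wr_ref, wd_ref = ref.transfer_weights_loops(assoc.values, ms.values, ds.values)
        np.testing.assert_allclose(tw.wr, wr_ref, atol=1e-12)
        np.testing.assert_allclose(tw.wd, wd_ref, atol=1e-12)

    def test_weights_bounded_in_unit_interval(self, rng):
        for _ in range(10):
            assoc, ms, ds = _random_instance(rng, 8, 6)
            tw = transfer_weights(assoc, ms, ds)
            for w in (tw.wr, tw.wd):
                assert w.min() >= -1e-12 and w.max() <= 1.0 + 1e-12


class TestInitialInformation:
    def test_beta_zero_recovers_adjacency(self, rng):
        assoc = random_association(rng, 6, 4)
        for axis in ("disease", "mirna"):
            s = initial_information(assoc, 0.0, axis)
            np.testing.assert_array_equal(s.values, assoc.values)

    def test_damped_hand_value(self):
        values = np.zeros((5, 1))
        values[:4, 0] = 1.0
        assoc = AssociationMatrix(values, [f"m{i}" for i in range(5)], ["d1"])
        s = initial_information(assoc, -0.1, "disease")
        assert s.values[0, 0] == pytest.approx(4**-0.1, abs=1e-12)
        assert s.values[4, 0] == 0.0  # A=0 stays 0 regardless of degree

    def test_matches_loop_reference(self, rng):
        assoc = random_association(rng, 7, 5)
        for axis in ("disease", "mirna"):
            s = initial_information(assoc, -0.3, axis)
            np.testing.assert_allclose(
                s.values, ref.initial_information_loops(assoc.values, -0.3, axis),
                atol=1e-12,
            )

    def test_damping_monotone_in_degree(self, rng):
        # higher-degree diseases place less resource per known edge
        assoc = random_association(rng, 12, 6)
        s = initial_information(assoc, -0.4, "disease")
        k = assoc.disease_degrees()
        per_edge = [
            s.values[:, j][assoc.values[:, j] == 1.0][0] for j in range(assoc.nd)
        ]
        for a in range(assoc.nd):
            for b in range(assoc.nd):
                if k[a] > k[b]:
                    assert per_edge[a] < per_edge[b] + 1e-12

    def test_beta_out_of_range_rejected(self, rng):
        assoc = random_association(rng, 3, 3)
        for bad in (-1.0, 0.1, -2.0):
            with pytest.raises(ValueError):
                initial_information(assoc, bad, "disease")


class TestPropagation:
    def test_propagation_matrix_columns_sum_to_one(self, rng):
        for _ in range(10):
            assoc, ms, ds = _random_instance(rng, 9, 6)
            tw = transfer_weights(assoc, ms, ds)
            for direction in ("disease_based", "mirna_based"):
                p = propagation_matrix(tw, direction)
                np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-10)

    def test_uniform_weights_average_initial_information(self):
        assoc = AssociationMatrix(np.ones((2, 2)), ["m1", "m2"], ["d1", "d2"])
        ms = _ones_sim(["m1", "m2"])
        ds = _ones_sim(["d1", "d2"], "integrated_disease")
        tw = transfer_weights(assoc, ms, ds)  # all wr entries equal
        p = propagation_matrix(tw, "disease_based")
        np.testing.assert_allclose(p, 0.5, atol=1e-12)
        s_ini = ScoreMatrix(
            np.array([[0.2, 0.8], [0.6, 0.4]]), ["m1", "m2"], ["d1", "d2"], "initial"
        )
        s_m = propagate(assoc, tw, s_ini, "disease_based")
        np.testing.assert_allclose(s_m.values, [[0.4, 0.6], [0.4, 0.6]], atol=1e-12)

    def test_loop_form_equals_matrix_form(self, rng):
        # the summation form and the propagation-matrix form agree
        for _ in range(5):
            assoc, ms, ds = _random_instance(rng, 20, 15)
            tw = transfer_weights(assoc, ms, ds)
            s_ini_d = initial_information(assoc, -0.1, "disease")
            s_m = propagate(assoc, tw, s_ini_d, "disease_based")
            np.testing.assert_allclose(
                s_m.values,
                ref.propagate_disease_based_loops(tw.wr, s_ini_d.values),
                atol=1e-10,
            )
            s_ini_m = initial_information(assoc, -0.1, "mirna")
            s_d = propagate(assoc, tw, s_ini_m, "mirna_based")
            np.testing.assert_allclose(
                s_d.values,
                ref.propagate_mirna_based_loops(tw.wd, s_ini_m.values),
                atol=1e-10,
            )

    def test_mass_conservation(self, rng):
        for _ in range(10):
            assoc, ms, ds = _random_instance(rng, 10, 7)
            tw = transfer_weights(assoc, ms, ds)
            s_ini = initial_information(assoc, -0.2, "disease")
            s_m = propagate(assoc, tw, s_ini, "disease_based")
            assert s_m.values.sum() == pytest.approx(s_ini.values.sum(), abs=1e-10)

    def test_isolated_node_error_lists_ids(self):
        # identity similarity makes weighted degrees mirror raw degrees
        values = np.array([[1.0, 0.0], [1.0, 0.0]])
        assoc = AssociationMatrix(values, ["m1", "m2"], ["d1", "d2"])
        tw_ms = _identity_sim(["m1", "m2"])
        tw_ds = _identity_sim(["d1", "d2"], "integrated_disease")
        tw = transfer_weights(assoc, tw_ms, tw_ds)
        with pytest.raises(IsolatedNodeError, match="d2"):
            propagation_matrix(tw, "disease_based")


class TestFinalScores:
    def test_idempotent_average(self, rng):
        s = ScoreMatrix(rng.random((3, 2)), ["a", "b", "c"], ["x", "y"], "disease_based")
        s2 = ScoreMatrix(s.values, s.mirna_ids, s.disease_ids, "mirna_based")
        np.testing.assert_array_equal(final_scores(s, s2).values, s.values)

    def test_arithmetic_mean(self):
        a = ScoreMatrix(np.array([[0.4]]), ["m"], ["d"], "disease_based")
        b = ScoreMatrix(np.array([[0.6]]), ["m"], ["d"], "mirna_based")
        assert final_scores(a, b).values[0, 0] == pytest.approx(0.5)

    def test_zero_side_halves(self, rng):
        s = ScoreMatrix(rng.random((2, 2)), ["a", "b"], ["x", "y"], "mirna_based")
        z = ScoreMatrix(np.zeros((2, 2)), ["a", "b"], ["x", "y"], "disease_based")
        np.testing.assert_allclose(final_scores(z, s).values, s.values / 2)


class TestPredict:
    def test_deterministic(self, rng):
        assoc, ms, ds = _random_instance(rng, 8, 6)
        s1 = predict(assoc, ms, ds)
        s2 = predict(assoc, ms, ds)
        assert (s1.values == s2.values).all()

    def test_matches_full_loop_reference(self, rng):
        assoc, ms, ds = _random_instance(rng, 12, 9)
        out = predict(assoc, ms, ds, ProjectionParams(beta=-0.1))
        expect = ref.wbnpmd_reference(assoc.values, ms.values, ds.values, -0.1)
        np.testing.assert_allclose(out.values, expect["S_fin"], atol=1e-10)

    def test_permutation_equivariance(self, rng):
        assoc, ms, ds = _random_instance(rng, 8, 5)
        out = predict(assoc, ms, ds)
        perm = rng.permutation(8)
        assoc_p = AssociationMatrix(
            assoc.values[perm], [assoc.mirna_ids[i] for i in perm], assoc.disease_ids
        )
        ms_p = SimilarityMatrix(
            ms.values[np.ix_(perm, perm)], [ms.ids[i] for i in perm], ms.kind
        )
        out_p = predict(assoc_p, ms_p, ds)
        np.testing.assert_allclose(out_p.values, out.values[perm], atol=1e-12)

    def test_block_diagonal_inputs_give_zero_cross_scores(self):
        rng = np.random.default_rng(5)
        a1 = random_association(rng, 4, 3)
        a2 = random_association(rng, 3, 4)
        values = np.zeros((7, 7))
        values[:4, :3] = a1.values
        values[4:, 3:] = a2.values
        mids = [f"m{i}" for i in range(7)]
        dids = [f"d{j}" for j in range(7)]
        assoc = AssociationMatrix(values, mids, dids)
        ms_vals = np.zeros((7, 7))
        ms_vals[:4, :4] = random_similarity(rng, mids[:4]).values
        ms_vals[4:, 4:] = random_similarity(rng, mids[4:]).values
        ds_vals = np.zeros((7, 7))
        ds_vals[:3, :3] = random_similarity(rng, dids[:3]).values
        ds_vals[3:, 3:] = random_similarity(rng, dids[3:]).values
        ms = SimilarityMatrix(ms_vals, mids, "integrated_mirna")
        ds = SimilarityMatrix(ds_vals, dids, "integrated_disease")
        out = predict(assoc, ms, ds)
        assert np.abs(out.values[:4, 3:]).max() == 0.0
        assert np.abs(out.values[4:, :3]).max() == 0.0

    def test_unweighted_limit_equals_classic_resource_allocation(self, rng):
        # identity similarities collapse the transfer weights to the raw
        # adjacency, so beta=0 is exactly the classic two-step allocation
        assoc = random_association(rng, 10, 8)
        ms = _identity_sim(assoc.mirna_ids)
        ds = _identity_sim(assoc.disease_ids, "integrated_disease")
        out = predict(assoc, ms, ds, ProjectionParams(beta=0.0))
        np.testing.assert_allclose(
            out.values, ref.unweighted_nbi_loops(assoc.values), atol=1e-10
        )

    def test_uniform_similarity_averages_over_popularity(self, rng):
        # all-ones similarities make every miRNA's outgoing weight identical,
        # so the disease-based diffusion returns column means of S_ini
        assoc = random_association(rng, 6, 5)
        ms = _ones_sim(assoc.mirna_ids)
        ds = _ones_sim(assoc.disease_ids, "integrated_disease")
        tw = transfer_weights(assoc, ms, ds)
        p = propagation_matrix(tw, "disease_based")
        np.testing.assert_allclose(p, 1.0 / assoc.nm, atol=1e-12)

    def test_scores_nonnegative_finite(self, rng):
        for _ in range(5):
            assoc, ms, ds = _random_instance(rng, 9, 6)
            out = predict(assoc, ms, ds, ProjectionParams(beta=-0.6))
            assert np.isfinite(out.values).all()
            assert out.values.min() >= 0.0
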