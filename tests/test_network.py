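import numpy as np
import pytest

from wcna.network import (
    connectivity_difference,
    correlation_matrix,
    select_key_probes,
    square_ratio,
    threshold_adjacency,
)
from wcna.screening import InflectionConfig
from wcna.synthetic import oracle_chain, oracle_pearson


def _net(vecs, ids=None, cond="LD", tau=None):
    ids = ids or [f"p{i}" for i in range(len(vecs))]
    net = correlation_matrix(np.asarray(vecs, float), ids, cond)
    return threshold_adjacency(net, tau) if tau is not None else net


class TestCorrelationMatrix:
    def test_self_and_anti_correlation(self, rng):
        x = rng.normal(size=12)
        net = _net([x, x, -x])
        assert net.R[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert net.R[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_pairwise_pearson_loop(self, rng):
        vecs = rng.normal(size=(5, 12))
        net = _net(vecs)
        for i in range(5):
            for j in range(5):
                expected = 1.0 if i == j else oracle_pearson(list(vecs[i]), list(vecs[j]))
                assert net.R[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_unit_diagonal_bounded(self, rng):
        net = _net(rng.normal(size=(8, 12)))
        np.testing.assert_allclose(net.R, net.R.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(net.R), 1.0)
        assert np.all(np.abs(net.R) <= 1 + 1e-12)

    def test_degenerate_vector_gets_zero_correlation(self, rng, caplog):
        vecs = np.vstack([rng.normal(size=(2, 12)), np.full(12, 0.3)])
        with caplog.at_level("WARNING", logger="wcna.network"):
            net = _net(vecs, ids=["a", "b", "flat"])
        assert "flat" in caplog.text
        np.testing.assert_array_equal(net.R[2, :2], 0.0)
        assert net.R[2, 2] == 1.0

    def test_all_degenerate_is_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            correlation_matrix(np.ones((3, 12)), ["a", "b", "c"])


class TestThresholdAdjacency:
    def test_threshold_is_inclusive(self):
        # build vectors with an exactly-known correlation via direct R injection
        net = _net(np.random.default_rng(0).normal(size=(3, 12)))
        net.R[0, 1] = net.R[1, 0] = 0.7
        net.R[0, 2] = net.R[2, 0] = 0.69999
        net.R[1, 2] = net.R[2, 1] = -0.7
        out = threshold_adjacency(net, 0.7)
        assert out.L[0, 1] == 1  # r == tau counts
        assert out.L[0, 2] == 0
        assert out.L[1, 2] == 1  # |r| symmetric in sign
        np.testing.assert_array_equal(np.diag(out.L), 0)

    def test_tau_one_on_distinct_vectors_gives_empty_graph(self, rng):
        out = _net(rng.normal(size=(6, 12)), tau=1.0)
        assert out.L.sum() == 0
        np.testing.assert_array_equal(out.degrees, 0)

    def test_degrees_equal_brute_force_count(self, rng):
        vecs = rng.normal(size=(4, 12))
        out = _net(vecs, tau=0.5)
        for i in range(4):
            count = sum(
                1 for j in range(4)
                if j != i and 0.5 <= abs(oracle_pearson(list(vecs[i]), list(vecs[j]))) <= 1
            )
            assert out.degrees[i] == count

    def test_invalid_tau(self, rng):
        net = _net(rng.normal(size=(3, 12)))
        for tau in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError, match="tau"):
                threshold_adjacency(net, tau)

    def test_degree_monotonicity_in_tau(self, rng):
        net = _net(rng.normal(size=(10, 12)))
        prev = None
        for tau in np.linspace(0.05, 1.0, 20):
            deg = threshold_adjacency(net, float(tau)).degrees
            if prev is not None:
                assert np.all(deg <= prev)
            prev = deg


class TestConnectivityDifference:
    def test_identical_networks_give_zero(self, rng):
        a = _net(rng.normal(size=(5, 12)), tau=0.7)
        table = connectivity_difference(a, a)
        np.testing.assert_array_equal(table.m, 0)
        assert (table.n_negative, table.n_positive, table.n_zero) == (0, 0, 5)

    def test_sign_counts_partition_probes(self, rng):
        a = _net(rng.normal(size=(8, 12)), tau=0.4)
        b = _net(rng.normal(size=(8, 12)), cond="DD", tau=0.4)
        table = connectivity_difference(a, b)
        assert table.n_negative + table.n_positive + table.n_zero == 8

    def test_degree_sum_identity(self, rng):
        a = _net(rng.normal(size=(8, 12)), tau=0.4)
        b = _net(rng.normal(size=(8, 12)), cond="DD", tau=0.4)
        table = connectivity_difference(a, b)
        assert table.m.sum() == a.degrees.sum() - b.degrees.sum()

    def test_probe_order_mismatch_is_error(self, rng):
        a = _net(rng.normal(size=(3, 12)), ids=["a", "b", "c"], tau=0.7)
        b = _net(rng.normal(size=(3, 12)), ids=["c", "b", "a"], tau=0.7)
        with pytest.raises(ValueError, match="order"):
            connectivity_difference(a, b)


class TestSquareRatio:
    def test_all_negative(self):
        s_neg, s_pos = square_ratio(np.array([-3, -1, -2]))
        assert (s_neg, s_pos) == (1.0, 0.0)

    def test_hand_evaluation(self):
        s_neg, s_pos = square_ratio(np.array([-2, 1, 1]))
        assert s_neg == pytest.approx(4 / 6)
        assert s_pos == pytest.approx(2 / 6)

    def test_ratios_sum_to_one_with_zeros_ignored(self, rng):
        m = rng.integers(-20, 20, size=100)
        if (m != 0).any():
            s_neg, s_pos = square_ratio(m)
            assert s_neg + s_pos == pytest.approx(1.0, abs=1e-12)
            assert 0 <= s_neg <= 1 and 0 <= s_pos <= 1

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            square_ratio(np.zeros(5))


def _table_from_m(m):
    from wcna.network import ConnectivityDiffTable

    m = np.asarray(m)
    return ConnectivityDiffTable(
        probe_ids=[f"p{i}" for i in range(len(m))],
        condition_a="LD", condition_b="DD",
        degrees_a=np.maximum(m, 0), degrees_b=np.maximum(-m, 0), m=m,
    )


class TestSelectKeyProbes:
    def test_manual_thresholds_inclusive(self):
        table = _table_from_m([-30, -20, -19, -3, 0, 2, 10, 11, 25])
        out = select_key_probes(
            table,
            InflectionConfig(method="manual", manual_threshold=-19.88),
            InflectionConfig(method="manual", manual_threshold=10),
        )
        assert out.selected_negative == ["p0", "p1"]   # m <= -19.88 -> m <= -20
        assert out.selected_positive == ["p6", "p7", "p8"]  # m >= 10 inclusive

    def test_all_zero_differences_select_nothing(self, caplog):
        with caplog.at_level("WARNING", logger="wcna.network"):
            out = select_key_probes(_table_from_m(np.zeros(6, dtype=int)))
        assert out.selected_negative == [] and out.selected_positive == []

    def test_knee_method_finds_planted_negative_hubs(self):
        """5 clustered strong-negative hubs separated by a gap from a sloped background."""
        m = np.array([-24, -23, -22, -21, -20] + list(range(-15, 0, 2))
                     + [0] * 10 + [1, 2, 2, 3])
        out = select_key_probes(
            _table_from_m(m),
            InflectionConfig(smoothing_window=1),
            InflectionConfig(method="manual", manual_threshold=3),
        )
        assert out.selected_negative == ["p0", "p1", "p2", "p3", "p4"]

    def test_selected_sets_are_tails_of_sorted_differences(self, rng):
        m = rng.integers(-40, 40, size=60)
        out = select_key_probes(
            _table_from_m(m),
            InflectionConfig(method="manual", manual_threshold=-15),
            InflectionConfig(method="manual", manual_threshold=15),
        )
        assert {int(p[1:]) for p in out.selected_positive} == {
            i for i, v in enumerate(m) if v >= 15
        }
        assert {int(p[1:]) for p in out.selected_negative} == {
            i for i, v in enumerate(m) if v <= -15
        }


class TestWorkedExampleChain:
    def test_correlation_matrices_match_oracle(self, worked_example):
        we = worked_example
        for cond in ("LD", "DD"):
            net = correlation_matrix(we.frequency[cond], we.dataset.probe_ids, cond)
            np.testing.assert_allclose(net.R, we.R[cond], atol=1e-12)

    def test_degrees_and_differences_match_oracle(self, worked_example):
        we = worked_example
        nets = {}
        for cond in ("LD", "DD"):
            nets[cond] = threshold_adjacency(
                correlation_matrix(we.frequency[cond], we.dataset.probe_ids, cond), we.tau
            )
            np.testing.assert_array_equal(nets[cond].L, we.L[cond])
            np.testing.assert_array_equal(nets[cond].degrees, we.degrees[cond])
        table = connectivity_difference(nets["LD"], nets["DD"])
        np.testing.assert_array_equal(table.m, we.m)

    def test_worked_example_is_stable_across_runs(self, worked_example):
        from wcna.synthetic import make_worked_example

        again = make_worked_example()
        np.testing.assert_allclose(again.R["LD"], worked_example.R["LD"], atol=1e-12)
        np.testing.assert_array_equal(again.m, worked_example.m)


class TestChainVsOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_full_chain_matches_brute_force_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 9)
        va, vb = rng.normal(size=(2, n, 12))
        oracle = oracle_chain(va, vb, tau=0.7)
        ids = [f"p{i}" for i in range(n)]
        na = threshold_adjacency(correlation_matrix(va, ids, "a"), 0.7)
        nb = threshold_adjacency(correlation_matrix(vb, ids, "b"), 0.7)
        np.testing.assert_allclose(na.R, oracle["R_a"], atol=1e-12)
        np.testing.assert_array_equal(na.L, oracle["L_a"])
        np.testing.assert_array_equal(na.degrees, oracle["degrees_a"])
        table = connectivity_difference(na, nb)
        np.testing.assert_array_equal(table.m, oracle["m"])

    def test_label_permutation_invariance(self, rng):
        n = 6
        va, vb = rng.normal(size=(2, n, 12))
        ids = [f"p{i}" for i in range(n)]
        perm = rng.permutation(n)
        base = connectivity_difference(
            threshold_adjacency(correlation_matrix(va, ids, "a"), 0.7),
            threshold_adjacency(correlation_matrix(vb, ids, "b"), 0.7),
        )
        permuted = connectivity_difference(
            threshold_adjacency(correlation_matrix(va[perm], [ids[i] for i in perm], "a"), 0.7),
            threshold_adjacency(correlation_matrix(vb[perm], [ids[i] for i in perm], "b"), 0.7),
        )
        np.testing.assert_array_equal(permuted.m, base.m[perm])
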