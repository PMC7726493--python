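import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from toxconcord.diffexpr import (
    bh_adjust,
    call_de,
    de_table,
    log2_fold_changes,
    read_de_table,
    two_sample_test,
    write_de_table,
)
from toxconcord.synthetic import SimulationConfig, generate_expression
from conftest import build_matrix


def bh_bruteforce(p):
    """Independent oracle: adj_i = min over ranks j >= rank(i) of m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for pos, idx in enumerate(order):
        tail = [m * p[order[j]] / (j + 1) for j in range(pos, m)]
        adj[idx] = min(1.0, min(tail))
    return adj


class TestLog2FoldChanges:
    def test_equal_groups_give_zero(self):
        m = build_matrix({"control": np.full((3, 2), 5.0), "BPA": np.full((3, 2), 5.0)})
        assert (log2_fold_changes(m, "BPA", "control") == 0.0).all()

    def test_one_log2_unit_is_a_twofold_change(self):
        m = build_matrix({"control": np.full((1, 3), 5.0), "BPA": np.full((1, 3), 6.0)})
        fc = log2_fold_changes(m, "BPA", "control")
        assert fc.iloc[0] == pytest.approx(1.0)
        assert 2 ** fc.iloc[0] == pytest.approx(2.0)

    def test_fc_of_0585_is_linear_1_5(self):
        m = build_matrix({"control": np.full((1, 4), 7.0), "BPA": np.full((1, 4), 7.585)})
        assert 2 ** log2_fold_changes(m, "BPA", "control").iloc[0] == pytest.approx(1.5, abs=1e-3)

    def test_unknown_label_raises(self, two_group_matrix):
        with pytest.raises(KeyError, match="BPZ"):
            log2_fold_changes(two_group_matrix, "BPZ", "control")


class TestTwoSampleTest:
    def test_hand_computed_pooled_t(self, two_group_matrix):
        """{1,2,3} vs {4,5,6}: |t| = 3/0.8165 = 3.674, p = 0.0214 at 4 df."""
        res = two_sample_test(two_group_matrix, "BPA", "control")
        assert res["t_stat"].iloc[0] == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), abs=1e-3)
        assert res["p_raw"].iloc[0] == pytest.approx(0.0214, abs=5e-4)

    def test_identical_groups_give_t0_p1(self):
        m = build_matrix({"control": [[1.0, 2.0, 3.0]], "BPA": [[1.0, 2.0, 3.0]]})
        res = two_sample_test(m, "BPA", "control")
        assert res["t_stat"].iloc[0] == 0.0
        assert res["p_raw"].iloc[0] == 1.0

    def test_zero_variance_conventions(self):
        m = build_matrix({
            "control": np.array([[5.0, 5.0], [5.0, 5.0]]),
            "BPA": np.array([[5.0, 5.0], [6.0, 6.0]]),
        })
        res = two_sample_test(m, "BPA", "control")
        assert res["p_raw"].iloc[0] == 1.0  # no variance, no difference
        assert res["p_raw"].iloc[1] == 0.0  # no variance, clear difference
        assert res["t_stat"].iloc[1] == np.inf

    def test_requires_two_replicates_per_group(self):
        m = build_matrix({"control": [[1.0]], "BPA": [[2.0]]})
        with pytest.raises(ValueError, match="2 replicates"):
            two_sample_test(m, "BPA", "control")

    def test_null_raw_p_uniform(self):
        """KS test against U(0,1) not rejected at alpha=0.01 on a null sim."""
        from scipy import stats

        cfg = SimulationConfig(n_probes=20_000, shared_de_count=0,
                               private_de_count=0, seed=11)
        m, _ = generate_expression(cfg)
        res = two_sample_test(m, "BPF", "control")
        ks = stats.kstest(res["p_raw"], "uniform")
        assert ks.pvalue > 0.01

    def test_agrees_with_exact_permutation_p(self, rng):
        """Pooled-t p within 0.08 of the exact 4v4 permutation p.

        |t| is pivotal under the null, so its permutation distribution over
        the 35 distinct group splits is pooled across null probes to give
        the exact reference distribution.
        """
        n_probes = 200
        data = rng.normal(size=(n_probes, 8))
        m = build_matrix({"control": data[:, :4], "BPA": data[:, 4:]})
        res = two_sample_test(m, "BPA", "control")

        def abs_t(block_a, block_b):
            diff = block_b.mean(axis=1) - block_a.mean(axis=1)
            pooled = (block_a.var(axis=1, ddof=1) + block_b.var(axis=1, ddof=1)) / 2
            return np.abs(diff) / np.sqrt(pooled * (2 / 4))

        # enumerate the 35 distinct unordered group splits
        obs = abs_t(data[:, :4], data[:, 4:])
        splits = [s for s in itertools.combinations(range(8), 4) if 0 in s]
        assert len(splits) == 35
        null = []
        for group_a in splits:
            mask = np.zeros(8, dtype=bool)
            mask[list(group_a)] = True
            null.append(abs_t(data[:, mask], data[:, ~mask]))
        null = np.concatenate(null)
        p_perm = (null[None, :] >= obs[:, None] - 1e-12).mean(axis=1)
        assert np.max(np.abs(p_perm - res["p_raw"])) < 0.08


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.5], [0.5]),
            ([0.005, 0.1], [0.01, 0.1]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ],
    )
    def test_step_up_hand_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    @pytest.mark.parametrize("bad", [[-0.1], [1.2], [np.nan]])
    def test_out_of_range_inputs_rejected(self, bad):
        with pytest.raises(ValueError, match="0, 1"):
            bh_adjust(bad)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_agrees_with_bruteforce_min_over_tail(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_adjusted_at_least_raw_and_monotone_in_rank(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestCallDe:
    def test_up_call(self):
        de = pd.DataFrame({"log2fc": [1.0], "p_adj": [0.01]})
        assert call_de(de)["call"].iloc[0] == "up"

    def test_boundary_fold_change_is_ns(self):
        de = pd.DataFrame({"log2fc": [np.log2(1.5)], "p_adj": [0.001]})
        assert call_de(de)["call"].iloc[0] == "ns"

    def test_failed_fdr_gate_is_ns(self):
        de = pd.DataFrame({"log2fc": [-1.0], "p_adj": [0.2]})
        assert call_de(de)["call"].iloc[0] == "ns"

    def test_down_call_and_custom_thresholds(self):
        de = pd.DataFrame({"log2fc": [-1.1, -1.1], "p_adj": [0.04, 0.04]})
        assert (call_de(de, fc_threshold=2.0, alpha=0.05)["call"] == "down").all()
        assert (call_de(de, fc_threshold=2.0, alpha=0.01)["call"] == "ns").all()

    @pytest.mark.parametrize("kwargs", [{"fc_threshold": 1.0}, {"alpha": 0.0}])
    def test_invalid_thresholds_rejected(self, kwargs):
        de = pd.DataFrame({"log2fc": [0.0], "p_adj": [0.5]})
        with pytest.raises(ValueError):
            call_de(de, **kwargs)


class TestDeTable:
    def test_table_invariants_and_roundtrip(self, tmp_path):
        cfg = SimulationConfig(n_probes=500, shared_de_count=50, private_de_count=0,
                               effect_sd=0.5, effect_correlation=0.9, seed=13)
        m, _ = generate_expression(cfg)
        de = de_table(m, "BPA", "control")
        assert (de["p_adj"] >= de["p_raw"] - 1e-15).all()
        ups = de[de["call"] == "up"]
        assert ((2 ** ups["log2fc"] > 1.5) & (ups["p_adj"] < 0.05)).all()
        downs = de[de["call"] == "down"]
        assert ((2 ** downs["log2fc"] < 1 / 1.5) & (downs["p_adj"] < 0.05)).all()
        write_de_table(de, tmp_path / "de.tsv")
        back = read_de_table(tmp_path / "de.tsv")
        pd.testing.assert_frame_equal(back, de, check_exact=False)

    def test_recovery_sensitivity_and_fdr(self):
        """At effect ~1.5, sd 0.2, noise 0.25, 4 reps: sensitivity >= 0.9 and
        empirical FDR <= 0.1, averaged over 10 seeds."""
        sens, fdr = [], []
        for seed in range(10):
            cfg = SimulationConfig(n_probes=2000, shared_de_count=100,
                                   private_de_count=50, effect_mean=1.5,
                                   effect_sd=0.2, effect_correlation=1.0,
                                   noise_sd=0.25, n_replicates=4, seed=seed)
            m, truth = generate_expression(cfg)
            for compound in ("BPA", "BPF", "BPS"):
                de = de_table(m, compound, "control")
                true_set = set(truth.perturbed_probes(compound))
                called = set(de.index[de["call"] != "ns"])
                sens.append(len(called & true_set) / len(true_set))
                if called:
                    fdr.append(len(called - true_set) / len(called))
        assert np.mean(sens) >= 0.9
        assert np.mean(fdr) <= 0.1
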