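import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resilioprot.differential import (bh_adjust, call_differential,
                                      group_fold_change, pca_summary,
                                      run_differential, t_test_per_protein,
                                      volcano_table)
from resilioprot.preprocess import impute_missing, standardize
from resilioprot.synthetic_data import generate_dataset, null_spec

from conftest import make_table

GROUPS6 = {"R1": "resilient", "R2": "resilient", "R3": "resilient",
           "S1": "susceptible", "S2": "susceptible", "S3": "susceptible"}


def bh_stepup_bruteforce(p):
    """Literal step-up definition: q_i = min over p_(j) >= p_i of
    min(1, m * p_(j) / rank_j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = [(p[i], r + 1) for r, i in enumerate(order)]
    q = np.empty(m)
    for i in range(m):
        q[i] = min(min(1.0, m * pj / rank) for pj, rank in ranked if pj >= p[i])
    return q


class TestFoldChange:
    def test_equal_group_means_give_unit_fc(self):
        t = make_table([[5.0, 7.0, 6.0, 4.0, 6.0, 8.0]], GROUPS6)
        fc = group_fold_change(t, "resilient", "susceptible")
        assert fc.iloc[0] == pytest.approx(1.0)

    def test_ratio_of_group_means(self):
        t = make_table([[30.0, 30.0, 30.0, 10.0, 10.0, 10.0]], GROUPS6)
        fc = group_fold_change(t, "resilient", "susceptible")
        assert fc.iloc[0] == pytest.approx(3.0)

    def test_orientation_numerator_over_denominator(self):
        # a feature higher in resilient must give FC > 1 on the
        # resilient/susceptible orientation
        t = make_table([[20.0, 22.0, 21.0, 9.0, 10.0, 11.0]], GROUPS6)
        assert group_fold_change(t, "resilient", "susceptible").iloc[0] > 1
        assert group_fold_change(t, "susceptible", "resilient").iloc[0] < 1

    def test_swapping_groups_inverts_fc(self, two_group_labels):
        rng = np.random.default_rng(2)
        t = make_table(rng.uniform(1, 100, (10, 16)), two_group_labels)
        a = group_fold_change(t, "resilient", "susceptible")
        b = group_fold_change(t, "susceptible", "resilient")
        np.testing.assert_allclose(a.to_numpy(), 1.0 / b.to_numpy())


class TestTTest:
    def test_pooled_closed_form(self):
        # A=[1,2,3], B=[2,3,4]: pooled SD 1, t = -1/sqrt(2/3), df = 4
        t = make_table([[1.0, 2.0, 3.0, 2.0, 3.0, 4.0]], GROUPS6)
        res = t_test_per_protein(t, "resilient", "susceptible", variant="student")
        assert res["t"].iloc[0] == pytest.approx(-1.224744871, abs=1e-8)
        assert res["p"].iloc[0] == pytest.approx(0.2878641347, abs=1e-6)

    def test_identical_groups_give_p_one(self):
        t = make_table([[3.0, 3.0, 3.0, 3.0, 3.0, 3.0]], GROUPS6)
        res = t_test_per_protein(t, "resilient", "susceptible")
        assert res["t"].iloc[0] == 0.0 and res["p"].iloc[0] == 1.0

    def test_zero_variance_unequal_means_p_tiny(self):
        t = make_table([[5.0, 5.0, 5.0, 9.0, 9.0, 9.0]], GROUPS6)
        res = t_test_per_protein(t, "resilient", "susceptible")
        assert 0 < res["p"].iloc[0] < 1e-300

    def test_large_planted_effect_is_significant(self, two_group_labels):
        rng = np.random.default_rng(3)
        vals = rng.normal(100.0, 1.0, (1, 16))
        vals[0, :8] += 5.0  # 5-SD shift, n = 8+8
        res = t_test_per_protein(make_table(vals, two_group_labels),
                                 "resilient", "susceptible")
        assert res["p"].iloc[0] < 1e-4

    def test_welch_variant_differs_under_unequal_variance(self, two_group_labels):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(10, 5, (1, 8)),
                               rng.normal(12, 0.1, (1, 8))], axis=1)
        t = make_table(vals, two_group_labels)
        ps = t_test_per_protein(t, "resilient", "susceptible", "student")["p"]
        pw = t_test_per_protein(t, "resilient", "susceptible", "welch")["p"]
        assert ps.iloc[0] != pw.iloc[0]


class TestBhAdjust:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_domain_raises(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan, 0.1]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-8, 1.0, exclude_min=False), min_size=1,
                    max_size=30))
    def test_matches_bruteforce_stepup_definition(self, p):
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_stepup_bruteforce(p), atol=1e-12)
        assert (q >= np.asarray(p) - 1e-12).all()


class TestCallDifferential:
    @pytest.mark.parametrize("fc,p,q,expected", [
        (1.25, 0.01, 0.03, "up"),
        (1.25, 0.01, 0.07, "ns"),   # fails the FDR gate
        (1.0, 1e-6, 1e-5, "ns"),    # inside the FC dead zone
        (1.2, 0.01, 0.01, "up"),    # inclusive threshold
        (0.80, 0.01, 0.01, "down"),  # inclusive threshold
        (0.5, 0.2, 0.3, "ns"),
    ])
    def test_gate_logic(self, fc, p, q, expected):
        assert call_differential([fc], [p], [q])[0] == expected

    def test_invalid_thresholds_raise(self):
        with pytest.raises(ValueError):
            call_differential([1.0], [0.5], [0.5], fc_up=0.8, fc_down=1.2)


class TestRunDifferential:
    def test_q_at_least_p_and_call_consistency(self, two_group_labels):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(16, 0.5, (50, 16))
        vals[:5, :8] *= 3.0
        t = make_table(vals, two_group_labels)
        rec = run_differential(t, "resilient", "susceptible")
        assert (rec["q"] >= rec["p"] - 1e-12).all()
        up = rec[rec["call"] == "up"]
        assert ((up["fc"] >= 1.2) & (up["p"] < 0.05) & (up["q"] < 0.05)).all()
        down = rec[rec["call"] == "down"]
        assert ((down["fc"] <= 0.80) & (down["q"] < 0.05)).all()

    def test_calls_invariant_to_sample_order(self, two_group_labels):
        rng = np.random.default_rng(6)
        t = make_table(rng.lognormal(16, 0.5, (30, 16)), two_group_labels)
        rec1 = run_differential(t, "resilient", "susceptible")
        shuffled = list(t.sample_ids)
        rng.shuffle(shuffled)
        rec2 = run_differential(t.subset_samples(shuffled),
                                "resilient", "susceptible")
        assert list(rec1["call"]) == list(rec2["call"])
        np.testing.assert_allclose(rec1["p"], rec2["p"], rtol=1e-10)

    def test_null_data_false_positive_rate_controlled(self):
        # FDR control: on data with no planted effects the fraction of
        # q < 0.05 calls stays near zero over many seeds
        props = []
        for seed in range(50):
            table, _ = generate_dataset(null_spec(n_proteins=300,
                                                  missing_rate=0.0, seed=seed))
            rec = run_differential(table, "resilient", "susceptible")
            props.append((rec["q"] < 0.05).mean())
        assert np.mean(props) <= 0.01

    def test_volcano_coordinates(self, two_group_labels):
        rng = np.random.default_rng(7)
        t = make_table(rng.lognormal(16, 0.5, (10, 16)), two_group_labels)
        rec = run_differential(t, "resilient", "susceptible")
        v = volcano_table(rec, y="q")
        np.testing.assert_allclose(v["x_log2fc"], np.log2(rec["fc"]))
        np.testing.assert_allclose(v["y_neglog10"], -np.log10(rec["q"]))


class TestPcaSummary:
    def test_rank_one_case_pc1_explains_everything(self):
        t = make_table(np.array([[1.0, 1.0, 4.0], [2.0, 2.0, 8.0],
                                 [3.0, 3.0, 12.0]]),
                       {"A": "resilient", "B": "resilient", "C": "susceptible"})
        std = standardize(impute_missing(t))
        pca = pca_summary(std, n_components=2)
        assert pca.explained_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_explained_fractions_match_eigendecomposition(self, two_group_labels):
        rng = np.random.default_rng(8)
        t = make_table(rng.uniform(1, 100, (200, 16)), two_group_labels)
        std = standardize(t)
        pca = pca_summary(std, n_components=5)
        X = std.as_samples_by_features()
        Xc = X - X.mean(axis=0)
        evals = np.linalg.eigvalsh(Xc @ Xc.T)[::-1]  # dual covariance spectrum
        expected = evals / evals.sum()
        np.testing.assert_allclose(pca.explained_fraction, expected[:5],
                                   atol=1e-8)
        assert (np.diff(pca.explained_fraction) <= 1e-12).all()

    def test_component_count_clipped_with_warning(self, caplog):
        t = make_table(np.random.default_rng(9).uniform(1, 10, (5, 3)),
                       {"A": "resilient", "B": "resilient", "C": "susceptible"})
        std = standardize(t)
        with caplog.at_level("WARNING"):
            pca = pca_summary(std, n_components=10)
        assert pca.scores.shape[1] == 2
        assert "clipped" in caplog.text
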