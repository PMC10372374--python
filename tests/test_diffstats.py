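"""Two-way ANOVA vs independent oracles, pooled BH, fold changes, indices."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.anova import anova_lm

from liveromics import diffstats, synth
from liveromics.design import StudyDesign

from conftest import balanced_design


def _unbalanced_design():
    return StudyDesign().sample_table().query("role == 'biological'")


def _matrix(design, rng, n_features=5):
    cols = design["sample"].tolist()
    return pd.DataFrame(
        rng.normal(20, 1, (n_features, len(cols))),
        index=[f"F{i}" for i in range(n_features)],
        columns=cols,
    )


def _statsmodels_oracle(values: pd.Series, design: pd.DataFrame, typ):
    df = design.set_index("sample").loc[values.index].copy()
    df["y"] = values
    # Type III is only meaningful under sum-to-zero contrasts
    factor = "C({}, Sum)" if typ == 3 else "C({})"
    g, s = factor.format("group"), factor.format("sex")
    model = smf.ols(f"y ~ {g} * {s}", df).fit()
    tab = anova_lm(model, typ=typ)
    return {
        "group": tab.loc[g, "PR(>F)"],
        "sex": tab.loc[s, "PR(>F)"],
        "interaction": tab.loc[f"{g}:{s}", "PR(>F)"],
    }


class TestTwoWayAnova:
    @pytest.mark.parametrize("ss_type,typ", [("I", 1), ("II", 2), ("III", 3)])
    def test_matches_statsmodels_on_unbalanced_design(self, rng, ss_type, typ):
        design = _unbalanced_design()
        m = _matrix(design, rng, n_features=8)
        res = diffstats.two_way_anova(m, design, ss_type=ss_type)
        for f in m.index:
            oracle = _statsmodels_oracle(m.loc[f], design, typ)
            for eff in ("group", "sex", "interaction"):
                assert res.loc[f, f"p_{eff}"] == pytest.approx(
                    oracle[eff], abs=1e-10
                )

    def test_matches_statsmodels_on_balanced_design(self, rng):
        design = balanced_design(4)
        m = _matrix(design, rng, n_features=6)
        res = diffstats.two_way_anova(m, design, ss_type="II")
        for f in m.index:
            oracle = _statsmodels_oracle(m.loc[f], design, typ=2)
            for eff in ("group", "sex", "interaction"):
                assert res.loc[f, f"p_{eff}"] == pytest.approx(
                    oracle[eff], abs=1e-10
                )

    def test_balanced_design_all_ss_types_agree(self, rng):
        design = balanced_design(3)
        m = _matrix(design, rng)
        r1 = diffstats.two_way_anova(m, design, ss_type="I")
        r2 = diffstats.two_way_anova(m, design, ss_type="II")
        r3 = diffstats.two_way_anova(m, design, ss_type="III")
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(r2, r3)

    def test_identical_groups_give_p_one(self):
        design = balanced_design(2)
        # PHG cells copy PNG cells exactly: zero between-group SS
        vals = {"PHG_F": [1.0, 2.0], "PHG_M": [3.0, 4.0],
                "PNG_F": [1.0, 2.0], "PNG_M": [3.0, 4.0]}
        row = []
        for s in design["sample"]:
            cell = s.rsplit("_", 1)[0] + "_" + s[-2]
            row.append(vals[cell][int(s[-1])])
        m = pd.DataFrame([row], index=["f"], columns=design["sample"].tolist())
        res = diffstats.two_way_anova(m, design)
        assert res.loc["f", "p_group"] == pytest.approx(1.0)

    def test_constant_feature_warns_p_one(self):
        design = balanced_design(3)
        m = pd.DataFrame(
            [[5.0] * len(design)], index=["const"], columns=design["sample"]
        )
        with pytest.warns(UserWarning, match="constant"):
            res = diffstats.two_way_anova(m, design)
        assert (res.loc["const"] == 1.0).all()

    def test_affine_invariance(self, rng):
        design = _unbalanced_design()
        m = _matrix(design, rng)
        r1 = diffstats.two_way_anova(m, design)
        r2 = diffstats.two_way_anova(m * 3.7 + 11.0, design)
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-9)


class TestPoolBh:
    def test_single_p_unchanged(self):
        p = pd.DataFrame({"p_group": [0.03]}, index=["f"])
        q = diffstats.pool_bh(p)
        assert q.loc["f", "q_group"] == pytest.approx(0.03)

    def test_hand_step_up(self):
        # pooled (0.01, 0.02, 0.04) -> (0.03, 0.03, 0.04)
        p = pd.DataFrame(
            {"p_group": [0.01], "p_sex": [0.02], "p_interaction": [0.04]},
            index=["f"],
        )
        q = diffstats.pool_bh(p)
        assert q.loc["f"].tolist() == pytest.approx([0.03, 0.03, 0.04])

    def test_all_equal_stay_equal(self):
        p = pd.DataFrame(np.full((4, 3), 0.2),
                         columns=["p_group", "p_sex", "p_interaction"])
        q = diffstats.pool_bh(p)
        assert (q.to_numpy() == pytest.approx(0.2))

    def test_missing_p_excluded_from_m(self):
        p = pd.DataFrame(
            {"p_group": [0.01, np.nan], "p_sex": [0.02, 0.04],
             "p_interaction": [np.nan, np.nan]},
        )
        q = diffstats.pool_bh(p)
        flat = q.to_numpy().ravel()
        assert np.isnan(flat[[2, 3, 5]]).sum() == 3
        # m = 3 observed p-values: same step-up as the hand example
        assert sorted(flat[[0, 1, 4]]) == pytest.approx([0.03, 0.03, 0.04])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_adjusted_at_least_raw_and_monotone(self, ps):
        p = pd.DataFrame({"p_group": ps})
        q = diffstats.pool_bh(p)["q_group"].to_numpy()
        raw = np.array(ps)
        assert (q >= raw - 1e-12).all() and (q <= 1.0).all()
        order = np.argsort(raw)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestTukey:
    def test_identical_cells_p_one(self):
        design = balanced_design(3)
        vals = pd.Series(
            np.tile([1.0, 2.0, 3.0], 4), index=design["sample"].tolist()
        )
        res = diffstats.tukey_hsd(vals, design)
        assert res["p_adj"].tolist() == pytest.approx([1.0] * len(res))

    def test_shifted_cell_dominates(self, rng):
        design = balanced_design(4)
        d = design.set_index("sample")
        vals = pd.Series(rng.normal(0, 0.1, len(d)), index=d.index)
        shifted = (d["group"] == "PHG") & (d["sex"] == "F")
        vals[shifted] += 10
        res = diffstats.tukey_hsd(vals, design)
        involving = res[(res["cell_a"] == "PHG_F") | (res["cell_b"] == "PHG_F")]
        others = res[(res["cell_a"] != "PHG_F") & (res["cell_b"] != "PHG_F")]
        assert involving["p_adj"].max() < others["p_adj"].min()

    def test_q_statistic_matches_hand_computation(self):
        # balanced cells of 2; q = mean diff / sqrt(MSE/n)
        design = balanced_design(2)
        vals = pd.Series(
            [10.0, 12.0, 20.0, 22.0, 30.0, 32.0, 40.0, 42.0],
            index=design["sample"].tolist(),
        )
        res = diffstats.tukey_hsd(vals, design)
        from scipy.stats import studentized_range

        mse = 2.0  # each cell variance = 2 with ddof=1
        q_hand = abs(11.0 - 21.0) / np.sqrt(mse / 2)
        p_hand = studentized_range.sf(q_hand, 4, 4)
        pair = res[(res.cell_a == "PHG_F") & (res.cell_b == "PHG_M")]
        assert pair["p_adj"].iloc[0] == pytest.approx(p_hand, rel=1e-6)


class TestFoldChange:
    def test_identical_means_zero(self, rng):
        design = _unbalanced_design()
        m = _matrix(design, rng, 3)
        d = design.set_index("sample")
        m.loc[:, d.index[d["group"] == "PHG"]] = 7.0
        m.loc[:, d.index[d["group"] == "PNG"]] = 7.0
        assert diffstats.fold_change(m, design).tolist() == pytest.approx([0, 0, 0])

    def test_four_fold_is_plus_two(self):
        design = balanced_design(1)
        m = pd.DataFrame(
            [[8.0, 8.0, 2.0, 2.0]], index=["f"], columns=design["sample"]
        )
        assert diffstats.fold_change(m, design)["f"] == pytest.approx(2.0)

    def test_toy_arithmetic(self):
        rows = [
            ("a", "PHG", "F", "biological"), ("b", "PHG", "M", "biological"),
            ("c", "PNG", "F", "biological"), ("d", "PNG", "M", "biological"),
        ]
        design = pd.DataFrame(rows, columns=["sample", "group", "sex", "role"])
        m = pd.DataFrame([[2.0, 4.0, 1.0, 1.0]], index=["f"],
                         columns=["a", "b", "c", "d"])
        # log2(mean(2,4)/mean(1,1)) = log2 3
        assert diffstats.fold_change(m, design)["f"] == pytest.approx(np.log2(3))


class TestSignificance:
    def _table(self, q, l2fc):
        return pd.DataFrame(
            {"q_group": [q], "q_sex": [1.0], "q_interaction": [1.0],
             "l2fc": [l2fc]}
        )

    def test_inclusive_boundaries_flagged(self):
        out, _ = diffstats.call_significance(self._table(0.05, np.log2(1.5)))
        assert out["sig_group"].iloc[0]

    def test_sub_threshold_fold_not_flagged(self):
        out, _ = diffstats.call_significance(self._table(0.04, np.log2(1.4)))
        assert not out["sig_group"].iloc[0]

    def test_up_down_split(self):
        t = pd.DataFrame(
            {"q_group": [0.01, 0.01, 0.5], "q_sex": [1, 1, 1],
             "q_interaction": [1, 1, 1], "l2fc": [2.0, -2.0, 2.0]}
        )
        _, summary = diffstats.call_significance(t)
        assert summary["group"] == {"total": 2, "up": 1, "down": 1}


class TestClinicalIndices:
    def test_homa_ir_canonical(self):
        assert diffstats.homa_ir(10, 81) == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "ins,glc,expected", [(10, 100, 1 / 3), (1, 10, 1.0)]
    )
    def test_quicki_closed_forms(self, ins, glc, expected):
        assert diffstats.quicki(ins, glc) == pytest.approx(expected)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            diffstats.homa_ir(0, 81)
        with pytest.raises(ValueError):
            diffstats.quicki(10, -1)

    def test_quicki_cutoff_flag(self, study_design):
        c = synth.gen_clinical(study_design, seed=0)
        out = diffstats.clinical_indices(c)
        phg = out[out["group"] == "PHG"]
        # the synthetic default emulates decreased PHG insulin sensitivity
        assert phg["low_insulin_sensitivity"].mean() > 0.5


class TestGroupTTest:
    def test_identical_groups_p_one(self):
        assert diffstats.group_t_test([1, 2, 3, 1, 2, 3],
                                      ["a"] * 3 + ["b"] * 3) == pytest.approx(1.0)

    def test_two_point_toy_matches_hand_formula(self):
        from scipy import stats as ss

        vals = [1.0, 2.0, 4.0, 5.0]
        labels = ["a", "a", "b", "b"]
        # t = (mean_a - mean_b) / sqrt(s2p*(1/2+1/2)); s2p = 0.5
        t_hand = (1.5 - 4.5) / np.sqrt(0.5 * (0.5 + 0.5))
        p_hand = 2 * ss.t.sf(abs(t_hand), df=2)
        assert diffstats.group_t_test(vals, labels) == pytest.approx(p_hand)

    def test_label_swap_symmetry(self, rng):
        vals = rng.normal(0, 1, 12)
        labels = np.array(["a", "b"] * 6)
        swapped = np.where(labels == "a", "b", "a")
        assert diffstats.group_t_test(vals, labels) == pytest.approx(
            diffstats.group_t_test(vals, swapped)
        )


def test_null_fdr_controlled_under_global_null(study_design, design_table):
    """Pooled-BH flags under the global null stay near the nominal level."""
    spec = synth.EffectSpec(
        n_features=100, frac_group_affected=0, frac_sex_affected=0,
        frac_interaction_affected=0,
    )
    total_flags, total_tests = 0, 0
    for seed in range(50):
        m, _ = synth.gen_omics_matrix(study_design, spec, seed=seed)
        p = diffstats.two_way_anova(np.log2(m), design_table)
        q = diffstats.pool_bh(p)
        total_flags += int((q.to_numpy() <= 0.05).sum())
        total_tests += q.size
    assert total_flags / total_tests <= 0.05 + 0.01
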