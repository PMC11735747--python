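import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neonet.cohort import GROUP_ORDER
from neonet.group_inference import (
    ancova_group_effect,
    costwise_group_tests,
    fdr_bh,
    kendall_trend,
    nodal_group_maps,
    sex_effect_ancova,
    tukey_hsd,
)
from neonet.synthetic import sample_balanced_cohort

from _oracles import ancova_f, bh_stepup


def _covariate_cohort(n_per_group=20, seed=0, effect=0.0):
    """Balanced metadata with a response = covariates + optional group effect."""
    meta = sample_balanced_cohort(n_per_group=n_per_group, seed=seed)
    rng = np.random.default_rng(50_000 + seed)
    ordinal = meta["group"].cat.codes.to_numpy()
    y = (
        0.005 * meta["pma_scan"].to_numpy()
        + 0.02 * (meta["sex"] == "male").to_numpy()
        + 0.01 * meta["mean_dvars"].to_numpy()
        + effect * ordinal
        + rng.normal(0, 0.05, len(meta))
    )
    out = meta.assign(metric=y)
    out["group"] = out["group"].astype(str)
    return out


class TestAncova:
    def test_two_groups_no_covariates_equals_squared_t(self, rng):
        df = pd.DataFrame({
            "y": rng.normal(size=30),
            "group": ["a"] * 15 + ["b"] * 15,
        })
        res = ancova_group_effect(df, "y", covariates=())
        t = stats.ttest_ind(df["y"][:15], df["y"][15:])
        assert res.f_value == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-10)

    def test_response_equal_to_covariate_has_no_group_signal(self):
        df = _covariate_cohort(seed=3)
        df["metric"] = df["pma_scan"]
        res = ancova_group_effect(df, "metric", covariates=("pma_scan",))
        assert res.f_value == pytest.approx(0.0, abs=1e-18)
        assert res.p_value == pytest.approx(1.0)

    def test_fixed_table_matches_projection_oracle(self):
        # 12 rows, 3 groups, 1 covariate: the hand-built RSS route
        df = pd.DataFrame({
            "y": [1.2, 0.8, 1.5, 1.1, 2.3, 2.8, 2.1, 2.6, 3.9, 3.4, 4.1, 3.7],
            "group": list("aaaabbbbcccc"),
            "x": [0.1, 0.4, 0.2, 0.9, 0.5, 0.3, 0.8, 0.2, 0.6, 0.1, 0.7, 0.4],
        })
        res = ancova_group_effect(df, "y", covariates=("x",))
        n = len(df)
        x_full = np.column_stack([
            np.ones(n),
            (df["group"] == "b").astype(float),
            (df["group"] == "c").astype(float),
            df["x"],
        ])
        x_red = x_full[:, [0, 3]]
        assert res.f_value == pytest.approx(
            ancova_f(df["y"], x_full, x_red, df_num=2), abs=1e-10
        )

    def test_identical_response_gives_zero_f(self):
        df = _covariate_cohort(seed=4)
        df["metric"] = 1.0
        res = ancova_group_effect(df, "metric")
        assert res.f_value == 0.0 and res.p_value == 1.0

    def test_rank_deficient_design_names_columns(self):
        df = _covariate_cohort(seed=5)
        df["copy"] = df["pma_scan"]
        with pytest.raises(ValueError, match="copy"):
            ancova_group_effect(df, "metric", covariates=("pma_scan", "copy"))

    def test_covariate_affine_rescaling_leaves_f_unchanged(self):
        df = _covariate_cohort(seed=6)
        res1 = ancova_group_effect(df, "metric")
        df2 = df.assign(pma_scan=3.0 * df["pma_scan"] - 50.0,
                        mean_dvars=0.1 * df["mean_dvars"] + 7.0)
        res2 = ancova_group_effect(df2, "metric")
        assert res1.f_value == pytest.approx(res2.f_value, rel=1e-9)

    def test_too_small_groups_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "group": ["a", "a", "b"]})
        with pytest.raises(ValueError, match="2 groups"):
            ancova_group_effect(df, "y", covariates=())

    def test_null_pvalues_roughly_uniform(self):
        """Kolmogorov-Smirnov on 200 null replicates at alpha = 0.01."""
        pvals = []
        for rep in range(200):
            df = _covariate_cohort(n_per_group=10, seed=1000 + rep)
            pvals.append(ancova_group_effect(df, "metric").p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestTukey:
    def test_two_groups_reduces_to_t_test(self, rng):
        df = pd.DataFrame({
            "y": rng.normal(size=24),
            "group": ["a"] * 12 + ["b"] * 12,
        })
        res = ancova_group_effect(df, "y", covariates=())
        cmp_ = tukey_hsd(res)[0]
        t = stats.ttest_ind(df["y"][:12], df["y"][12:])
        assert cmp_.p_value == pytest.approx(t.pvalue, rel=1e-6)

    def test_null_rarely_rejects(self):
        hits = total = 0
        for rep in range(50):
            rng = np.random.default_rng(2000 + rep)
            df = pd.DataFrame({
                "y": rng.normal(size=60),
                "group": ["a"] * 20 + ["b"] * 20 + ["c"] * 20,
            })
            res = ancova_group_effect(df, "y", covariates=())
            for cmp_ in tukey_hsd(res):
                total += 1
                hits += cmp_.p_value < 0.05
        assert hits / total < 0.10

    def test_shifted_group_detected_and_localised(self):
        """One mean moved by 2 sd: only its two contrasts should reject."""
        correct = 0
        n_sims = 40
        for rep in range(n_sims):
            rng = np.random.default_rng(3000 + rep)
            y = np.concatenate([
                rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(2, 1, 30),
            ])
            df = pd.DataFrame({"y": y, "group": ["a"] * 30 + ["b"] * 30 + ["c"] * 30})
            res = ancova_group_effect(df, "y", covariates=())
            rejected = {frozenset((c.group_a, c.group_b))
                        for c in tukey_hsd(res) if c.p_value < 0.05}
            if rejected == {frozenset("ac"), frozenset("bc")}:
                correct += 1
        assert correct / n_sims >= 0.90

    def test_singleton_group_excluded_with_warning(self, rng):
        df = pd.DataFrame({
            "y": rng.normal(size=9).tolist() + [5.0],
            "group": ["a"] * 5 + ["b"] * 4 + ["c"],
        })
        res = ancova_group_effect(df, "y", covariates=())
        with pytest.warns(UserWarning, match="excluded"):
            cmps = tukey_hsd(res)
        assert all("c" not in (c.group_a, c.group_b) for c in cmps)


class TestFdrBH:
    def test_step_up_rule_by_hand(self):
        reject, p_star = fdr_bh([0.01, 0.02, 0.5], q=0.05)
        # p_(2) = 0.02 <= 2 * 0.05 / 3: reject the two smallest
        assert reject.tolist() == [True, True, False]
        assert p_star == pytest.approx(0.02)

    def test_all_ones_rejects_none(self):
        reject, p_star = fdr_bh(np.ones(10), q=0.05)
        assert not reject.any() and p_star is None

    def test_all_zeros_rejects_all(self):
        reject, _ = fdr_bh(np.zeros(10), q=0.05)
        assert reject.all()

    def test_empty_input(self):
        reject, p_star = fdr_bh([], q=0.05)
        assert reject.size == 0 and p_star is None

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_literal_definition_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 60))
        reject, _ = fdr_bh(p, q=0.05)
        np.testing.assert_array_equal(reject, bh_stepup(p, 0.05))

    def test_rejections_monotone_in_pvalues(self):
        rng = np.random.default_rng(77)
        p = rng.uniform(size=30)
        before, _ = fdr_bh(p, q=0.05)
        p2 = p.copy()
        p2[rng.integers(30)] *= 0.1
        after, _ = fdr_bh(p2, q=0.05)
        assert (after | ~before).all()  # nothing rejected before is lost

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5], q=0.05)


def _nodal_table(n_per_group, seed, effect_regions=(), effect=0.0, n_regions=12):
    """Synthetic single-cost nodal table with optional group effect in some regions."""
    meta = sample_balanced_cohort(n_per_group=n_per_group, seed=seed)
    rng = np.random.default_rng(60_000 + seed)
    ordinal = meta["group"].cat.codes.to_numpy()
    frames = []
    for r in range(n_regions):
        bump = effect * ordinal if r in effect_regions else 0.0
        frames.append(pd.DataFrame({
            "session_id": meta["session_id"],
            "cost": 0.3,
            "region": f"R{r:02d}",
            "strength": 1.0 + 0.01 * meta["pma_scan"].to_numpy() + bump
            + rng.normal(0, 0.05, len(meta)),
            "pma_scan": meta["pma_scan"].to_numpy(),
            "sex": meta["sex"].to_numpy(),
            "mean_dvars": meta["mean_dvars"].to_numpy(),
            "group": meta["group"].astype(str).to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)


class TestNodalMaps:
    def test_effect_regions_recovered_with_fdr_control(self):
        """Every true-effect region is found; false discoveries stay rare."""
        true = {"R00", "R01", "R02"}
        false_hits = total_hits = 0
        n_sims = 12
        for rep in range(n_sims):
            table = _nodal_table(40, seed=rep, effect_regions={0, 1, 2}, effect=0.05)
            result, _, _ = nodal_group_maps(table, "strength", q=0.01)
            rejected = set(result.loc[result["reject"], "region"])
            assert true <= rejected  # full power at this effect size
            total_hits += len(rejected)
            false_hits += len(rejected - true)
        assert false_hits / total_hits <= 0.10

    def test_null_table_rarely_rejects(self):
        any_reject = 0
        for rep in range(10):
            table = _nodal_table(15, seed=100 + rep)
            result, _, _ = nodal_group_maps(table, "strength")
            any_reject += result["reject"].any()
        assert any_reject <= 2

    def test_identical_response_gives_zero_f_map(self):
        table = _nodal_table(10, seed=7)
        table["strength"] = 2.5
        result, p_star, f_thr = nodal_group_maps(table, "strength")
        assert (result["f_value"] == 0).all()
        assert p_star is None and f_thr is None

    def test_f_threshold_is_smallest_rejected_f(self):
        table = _nodal_table(40, seed=3, effect_regions={0, 1}, effect=0.08)
        result, _, f_thr = nodal_group_maps(table, "strength")
        if result["reject"].any():
            assert f_thr == pytest.approx(result.loc[result["reject"], "f_value"].min())

    def test_multiple_costs_rejected(self):
        table = _nodal_table(5, seed=1)
        table.loc[:10, "cost"] = 0.4
        with pytest.raises(ValueError, match="single cost"):
            nodal_group_maps(table, "strength")


class TestCostwise:
    def _metric_table(self, seed, effect):
        meta = sample_balanced_cohort(n_per_group=15, seed=seed)
        rng = np.random.default_rng(70_000 + seed)
        ordinal = meta["group"].cat.codes.to_numpy()
        frames = []
        for cost in (0.1, 0.2, 0.3):
            base = 1 + cost
            frames.append(pd.DataFrame({
                "session_id": meta["session_id"], "cost": cost,
                "strength": base + effect * ordinal + rng.normal(0, 0.04, len(meta)),
                "clustering": base / 2 + effect * ordinal / 2
                + rng.normal(0, 0.02, len(meta)),
                "path_length": 3 - cost - effect * ordinal
                + rng.normal(0, 0.04, len(meta)),
                "global_efficiency": base / 4 + effect * ordinal / 4
                + rng.normal(0, 0.01, len(meta)),
                "pma_scan": meta["pma_scan"].to_numpy(),
                "sex": meta["sex"].to_numpy(),
                "mean_dvars": meta["mean_dvars"].to_numpy(),
                "group": meta["group"].astype(str).to_numpy(),
            }))
        return pd.concat(frames, ignore_index=True)

    def test_strong_effect_rejects_every_cell(self):
        out = costwise_group_tests(self._metric_table(seed=0, effect=0.05))
        assert len(out) == 12  # 3 costs x 4 metrics here
        assert out["reject"].all()

    def test_null_rejection_rate_controlled(self):
        total_rejects = 0
        for rep in range(8):
            out = costwise_group_tests(self._metric_table(seed=200 + rep, effect=0.0))
            total_rejects += out["reject"].sum()
        assert total_rejects / (8 * 12) < 0.10

    def test_single_cost_degenerates_to_four_tests(self):
        table = self._metric_table(seed=1, effect=0.05)
        out = costwise_group_tests(table[table["cost"] == 0.3])
        assert len(out) == 4

    def test_per_metric_correction_flag(self):
        out = costwise_group_tests(self._metric_table(seed=2, effect=0.05),
                                   correct_within_metric=True)
        assert set(out.columns) >= {"p_adjusted", "reject"}


def test_sex_effect_detected_in_preterm_slice():
    meta = sample_balanced_cohort(n_per_group=30, seed=9)
    rng = np.random.default_rng(11)
    y = 0.5 + 0.05 * (meta["sex"] == "male") + rng.normal(0, 0.05, len(meta))
    df = meta.assign(metric=y)
    out = sex_effect_ancova(df, "metric")
    assert out["sex_p"] < 0.01
    out_i = sex_effect_ancova(df, "metric", interaction=True)
    assert "sex_x_age_p" in out_i


def test_kendall_trend_directionality():
    values = [1.0, 2.0, 3.0, 4.1, 5.2, 5.9, 7.0]
    tau, p_up = kendall_trend(values, range(7), increasing=True)
    assert tau == pytest.approx(1.0)
    assert p_up < 0.01
    _, p_down = kendall_trend(values, range(7), increasing=False)
    assert p_down > 0.99
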