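import numpy as np
import pandas as pd
import pytest

from metachrom.survival import (
    cox_ph,
    logrank,
    median_split_gene,
    tf_relapse_screen,
    zscore_merge,
)


class TestZscoreMerge:
    def test_hand_zscore_with_sample_sd(self):
        merged, ds = zscore_merge({"d1": pd.DataFrame({"g": [1.0, 3.0]},
                                                      index=["a", "b"])})
        assert np.allclose(merged["g"], [-np.sqrt(0.5), np.sqrt(0.5)])
        assert list(ds) == ["d1", "d1"]

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        once, _ = zscore_merge({"d": df})
        twice, _ = zscore_merge({"d": once})
        assert np.allclose(once, twice, atol=1e-12)

    def test_per_dataset_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        data = {
            "d1": pd.DataFrame(rng.normal(5, 2, size=(20, 3)),
                               columns=list("abc"),
                               index=[f"x{i}" for i in range(20)]),
            "d2": pd.DataFrame(rng.normal(-3, 9, size=(15, 3)),
                               columns=list("abc"),
                               index=[f"y{i}" for i in range(15)]),
        }
        merged, ds = zscore_merge(data)
        for d in ("d1", "d2"):
            sub = merged[ds == d]
            assert np.allclose(sub.mean(), 0.0, atol=1e-6)
            assert np.allclose(sub.std(ddof=1), 1.0, atol=1e-6)

    def test_constant_gene_becomes_missing_with_warning(self):
        df = pd.DataFrame({"g": [2.0, 2.0, 2.0], "h": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="constant"):
            merged, _ = zscore_merge({"d": df})
        assert merged["g"].isna().all()
        assert not merged["h"].isna().any()


class TestMedianSplit:
    def test_split_and_tie_rule(self):
        cohort = pd.DataFrame({"g": [-1.0, 0.0, 1.0, 2.0]})
        assert median_split_gene(cohort, "g").tolist() == [
            "low", "low", "high", "high"]
        cohort = pd.DataFrame({"g": [1.0, 2.0, 2.0, 4.0]})
        assert median_split_gene(cohort, "g").tolist() == [
            "low", "low", "low", "high"]

    def test_constant_gene_is_an_error(self):
        with pytest.raises(ValueError):
            median_split_gene(pd.DataFrame({"g": [1.0, 1.0]}), "g")


def logrank_oracle(groups, time, event):
    """Textbook two-group log-rank: sum of (O - E) with hypergeometric
    variance at each distinct event time."""
    groups = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    a = sorted(set(groups))[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == a)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (groups == a)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 1, 1, 1, 1]
        g = ["a", "a", "a", "b", "b", "b"]
        chi2, p = logrank(g, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_computation(self):
        g = ["a", "a", "a", "b", "b", "b"]
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 1, 1, 1, 1, 1]
        chi2, _ = logrank(g, t, e)
        assert chi2 == pytest.approx(logrank_oracle(g, t, e), rel=1e-9)

    def test_matches_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = 40
            g = rng.choice(["a", "b"], n)
            t = rng.exponential(10, n).round(2) + 0.01
            e = rng.integers(0, 2, n)
            if e.sum() == 0 or len(set(g)) < 2:
                continue
            chi2, _ = logrank(g, t, e)
            assert chi2 == pytest.approx(logrank_oracle(g, t, e), rel=1e-6)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(6)
        n = 30
        g = rng.choice(["a", "b"], n)
        t = rng.exponential(10, n)
        e = rng.integers(0, 2, n)
        e[0] = 1
        chi1, _ = logrank(g, t, e)
        swapped = np.where(g == "a", "b", "a")
        chi2, _ = logrank(swapped, t, e)
        assert chi1 == pytest.approx(chi2, rel=1e-9)

    def test_matches_permutation_null(self):
        """Chi-square p agrees with a label-permutation p within MC error."""
        rng = np.random.default_rng(7)
        n = 60
        g = np.array(["a"] * 30 + ["b"] * 30)
        t = np.concatenate([rng.exponential(8, 30), rng.exponential(14, 30)])
        e = np.ones(n, dtype=int)
        chi_obs, p_chi = logrank(g, t, e)
        n_perm = 4000
        hits = 0
        for _ in range(n_perm):
            hits += logrank_oracle(rng.permutation(g), t, e) >= chi_obs
        p_perm = hits / n_perm
        mc_err = 3 * np.sqrt(max(p_perm, 1 / n_perm) / n_perm)
        assert abs(p_perm - p_chi) < max(0.02, mc_err + 0.01)

    def test_single_group_is_an_error(self):
        with pytest.raises(ValueError):
            logrank(["a", "a"], [1, 2], [1, 1])

    def test_no_events_is_an_error(self):
        with pytest.raises(ValueError):
            logrank(["a", "b"], [1, 2], [0, 0])


def exp_cohort(n, hr, seed, covariates=False):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    lam = 0.05 * hr ** x
    te = rng.exponential(1 / lam)
    tc = rng.uniform(0, 120, n)
    df = pd.DataFrame({
        "time": np.minimum(te, tc),
        "event": (te <= tc).astype(int),
        "x": x,
    })
    if covariates:
        df["age"] = rng.normal(58, 10, n)
        df["subtype"] = rng.choice(["LumA", "Basal"], n)
    return df


class TestCoxPH:
    def test_recovers_planted_hazard_ratio(self):
        df = exp_cohort(1000, 2.0, seed=3)
        res = cox_ph(df, "x")
        assert 1.7 < res.cox_hr < 2.3
        assert res.cox_ci[0] < res.cox_hr < res.cox_ci[1]

    def test_duplicating_patients_keeps_point_estimate(self):
        # exact under untied partial likelihood; duplication creates ties, so
        # agreement is up to the Efron tie correction
        df = exp_cohort(150, 2.0, seed=4)
        res1 = cox_ph(df, "x")
        res2 = cox_ph(pd.concat([df, df], ignore_index=True), "x")
        assert res1.cox_hr == pytest.approx(res2.cox_hr, rel=0.02)

    def test_label_exposure_encoded_high_vs_low(self):
        df = exp_cohort(300, 2.5, seed=5)
        labels = np.where(df["x"] == 1, "high", "low")
        res_lab = cox_ph(df, labels)
        res_num = cox_ph(df, "x")
        assert res_lab.cox_hr == pytest.approx(res_num.cox_hr, rel=1e-9)

    def test_covariate_adjustment_runs(self):
        df = exp_cohort(400, 2.0, seed=6, covariates=True)
        res = cox_ph(df, "x", ["age", "subtype"])
        assert res.cox_hr > 1.3 and res.cox_p < 0.05

    def test_constant_covariate_is_an_error(self):
        df = exp_cohort(100, 1.0, seed=7)
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_ph(df, "x", ["flat"])

    def test_too_few_events_is_an_error(self):
        df = exp_cohort(50, 1.0, seed=8, covariates=True)
        df["event"] = 0
        df.loc[df.index[0], "event"] = 1
        with pytest.raises(ValueError, match="reduced model"):
            cox_ph(df, "x", ["age", "subtype"])


class TestTfRelapseScreen:
    def make_cohort(self, n=300, seed=11):
        rng = np.random.default_rng(seed)
        risk = rng.normal(size=n)
        lam = 0.04 * np.exp(0.9 * (risk > 0))
        te = rng.exponential(1 / lam)
        tc = rng.uniform(0, 120, n)
        df = pd.DataFrame({
            "time": np.minimum(te, tc),
            "event": (te <= tc).astype(int),
            "TF_EFFECT": risk,
            "TF_NOISE": rng.normal(size=n),
            "age": rng.normal(58, 10, n),
        })
        return df

    def test_planted_tf_flagged_concordant_gained(self):
        cohort = self.make_cohort()
        out = tf_relapse_screen(
            cohort, ["TF_EFFECT", "TF_NOISE"], covariates=["age"],
            motif_direction={"TF_EFFECT": "gained", "TF_NOISE": "gained"},
        )
        assert out.loc["TF_EFFECT", "cox_hr"] > 1
        assert out.loc["TF_EFFECT", "cox_padj"] < 0.05
        assert bool(out.loc["TF_EFFECT", "concordant"])

    def test_null_tf_usually_insignificant(self):
        hits = 0
        for seed in range(8):
            cohort = self.make_cohort(seed=100 + seed)
            out = tf_relapse_screen(cohort, ["TF_NOISE"])
            hits += out.loc["TF_NOISE", "logrank_p"] < 0.05
        assert hits <= 2

    def test_empty_tf_list_gives_empty_table(self):
        cohort = self.make_cohort()
        out = tf_relapse_screen(cohort, [])
        assert len(out) == 0

    def test_per_tf_failure_recorded_not_raised(self):
        cohort = self.make_cohort()
        cohort["TF_FLAT"] = 1.0
        out = tf_relapse_screen(cohort, ["TF_EFFECT", "TF_FLAT"])
        assert out.loc["TF_FLAT", "error"] != ""
        assert np.isfinite(out.loc["TF_EFFECT", "cox_hr"])

    def test_site_specific_columns_required(self):
        cohort = self.make_cohort()
        with pytest.raises(KeyError):
            tf_relapse_screen(cohort, ["TF_EFFECT"], site="lung")
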