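import numpy as np
import pandas as pd
import pytest
from scipy import stats

import grimclock as gc
from grimclock.validation import adjust_pvalues, bicor_stratum

from conftest import bicor_direct


class TestBicor:
    def test_perfect_monotone_linear(self):
        assert gc.bicor([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_antisymmetry(self):
        assert gc.bicor([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_direct_formula_and_resists_outlier(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=200)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=200)
        x[0], y[0] = 40.0, -40.0  # gross outlier pair
        r = gc.bicor(x, y)
        assert r == pytest.approx(bicor_direct(x, y), abs=1e-10)
        pearson = stats.pearsonr(x, y)[0]
        assert abs(r - 0.5) < abs(pearson - 0.5)

    def test_affine_equivariance(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        r = gc.bicor(x, y)
        assert gc.bicor(3.0 * x + 2.0, y) == pytest.approx(r, abs=1e-12)
        assert gc.bicor(-1.5 * x, y) == pytest.approx(-r, abs=1e-12)

    def test_bounded(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            r = gc.bicor(rng.normal(size=10), rng.normal(size=10))
            assert -1.0 <= r <= 1.0

    def test_mad_zero_falls_back_to_sd(self):
        x = np.array([0.0] * 8 + [1.0, 2.0])  # median-dominated, MAD = 0
        y = np.arange(10.0)
        with pytest.warns(UserWarning, match="MAD"):
            r = gc.bicor(x, y)
        assert np.isfinite(r)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="3"):
            gc.bicor([1.0, 2.0], [1.0, 2.0])


class TestFisherZ:
    def test_zero_correlation(self):
        z, var = gc.fisher_z(0.0, 100)
        assert z == 0.0

    def test_variance_formula(self):
        _, var = gc.fisher_z(0.5, 103)
        assert var == pytest.approx(0.01)

    def test_round_trip(self):
        z, _ = gc.fisher_z(0.73, 50)
        assert np.tanh(z) == pytest.approx(0.73, abs=1e-12)

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            gc.fisher_z(1.0, 50)


class TestFixedEffectMeta:
    def _stratum(self, label, est, se, n=100, kind="linear"):
        return gc.StratumAssociation(label=label, estimate=est, se=se, n=n, kind=kind)

    def test_single_stratum_passthrough(self):
        res = gc.fixed_effect_meta([self._stratum("a", 0.7, 0.2)])
        assert res.estimate == pytest.approx(0.7)
        assert res.se == pytest.approx(0.2)

    def test_equal_weight_average(self):
        res = gc.fixed_effect_meta(
            [self._stratum("a", 1.0, 1.0), self._stratum("b", 3.0, 1.0)]
        )
        assert res.estimate == pytest.approx(2.0)
        assert res.se == pytest.approx(1.0 / np.sqrt(2))

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(13)
        ests = rng.normal(0.4, 0.1, 5)
        ses = rng.uniform(0.05, 0.3, 5)
        strata = [self._stratum(f"s{i}", ests[i], ses[i]) for i in range(5)]
        res = gc.fixed_effect_meta(strata)
        w = 1.0 / ses**2
        pooled = np.sum(w * ests) / np.sum(w)
        se = 1.0 / np.sqrt(np.sum(w))
        assert res.estimate == pytest.approx(pooled, abs=1e-12)
        assert res.se == pytest.approx(se, abs=1e-12)
        assert res.z == pytest.approx(pooled / se, abs=1e-12)
        assert res.p == pytest.approx(2 * stats.norm.sf(abs(pooled / se)), rel=1e-10)

    def test_k_identical_strata_shrink_se_by_sqrt_k(self):
        strata = [self._stratum(f"s{i}", 0.5, 0.1) for i in range(4)]
        res = gc.fixed_effect_meta(strata)
        assert res.estimate == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1 / 2)

    def test_bicor_pooled_on_fisher_scale(self):
        rng = np.random.default_rng(14)
        strata = []
        rs = []
        for i in range(3):
            x = rng.normal(size=80)
            y = 0.6 * x + 0.8 * rng.normal(size=80)
            strata.append(bicor_stratum(x, y, f"s{i}"))
            rs.append(gc.bicor(x, y))
        res = gc.fixed_effect_meta(strata)
        zs = np.arctanh(rs)
        w = np.full(3, 80 - 3)
        expected = np.tanh(np.sum(w * zs) / np.sum(w))
        assert res.estimate == pytest.approx(expected, abs=1e-12)
        assert -1 < res.estimate < 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            gc.fixed_effect_meta([])


class TestStoufferMeta:
    def test_single_stratum(self):
        Z, _ = gc.stouffer_meta([1.7], [50])
        assert Z == pytest.approx(1.7)

    def test_hand_algebra(self):
        Z, _ = gc.stouffer_meta([1.0, 1.0], [4, 4])
        assert Z == pytest.approx(np.sqrt(2))

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(15)
        z = rng.normal(size=6)
        n = rng.integers(50, 500, 6)
        Z, p = gc.stouffer_meta(z, n)
        expected = np.sum(np.sqrt(n) * z) / np.sqrt(np.sum(n))
        assert Z == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(abs(expected)), rel=1e-10)

    def test_equal_n_reduces_to_scaled_mean(self):
        z = np.array([0.5, 1.5, -0.2])
        Z, _ = gc.stouffer_meta(z, [100, 100, 100])
        assert Z == pytest.approx(z.mean() * np.sqrt(3), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc.stouffer_meta([], [])


def _survival_with_exposure(n=600, beta=0.4, seed=20):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    truth = gc.SimTruth({}, {}, 1.5, 60.0, 0.4, seed)
    time, event = gc.simulate_survival(beta * x, truth, rng=rng)
    return x, time, event


class TestCoxAssociation:
    def test_recovers_simulated_log_hazard(self):
        x, time, event = _survival_with_exposure()
        assoc = gc.cox_association(time, event, x, label="sim")
        assert assoc.kind == "cox"
        assert assoc.estimate == pytest.approx(0.4, abs=3 * assoc.se)
        assert assoc.ratio == pytest.approx(np.exp(assoc.estimate))

    def test_duplication_keeps_estimate_and_needs_cluster_se(self):
        x, time, event = _survival_with_exposure(n=300)
        base = gc.cox_association(time, event, x)
        x2 = np.concatenate([x, x])
        t2 = np.concatenate([time, time])
        e2 = np.concatenate([event, event])
        cluster = np.concatenate([np.arange(300), np.arange(300)])
        naive = gc.cox_association(t2, e2, x2)
        robust = gc.cox_association(t2, e2, x2, cluster=cluster)
        # duplication creates ties; Efron tie handling moves the point
        # estimate only marginally (exact invariance holds under Breslow)
        assert naive.estimate == pytest.approx(base.estimate, rel=0.01)
        assert robust.estimate == pytest.approx(base.estimate, rel=0.01)
        assert naive.se < base.se  # duplication fakes precision
        assert robust.se > naive.se  # the sandwich undoes it

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            gc.cox_association(np.arange(1.0, 11.0), np.zeros(10, int), np.ones(10))


class TestLogisticAssociation:
    def test_two_by_two_contingency_identity(self):
        # counts (a,b,c,d) = (20,10,10,20): OR = (20*20)/(10*10) = 4
        outcome = np.array([1] * 20 + [1] * 10 + [0] * 10 + [0] * 20)
        exposure = np.array([1] * 20 + [0] * 10 + [1] * 10 + [0] * 20)
        assoc = gc.logistic_association(outcome, exposure)
        assert assoc.estimate == pytest.approx(np.log(4), abs=1e-6)
        assert assoc.ratio == pytest.approx(4.0, abs=1e-5)

    def test_constant_exposure_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gc.logistic_association([0, 1, 0, 1], [1.0, 1.0, 1.0, 1.0])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            gc.logistic_association([1, 1, 1], [0.1, 0.2, 0.3])

    def test_recovers_simulated_odds_ratio(self):
        rng = np.random.default_rng(21)
        n = 5000
        x = rng.normal(size=n)
        logit = -0.5 + np.log(1.07) * x
        y = rng.binomial(1, 1 / (1 + np.exp(-logit)))
        assoc = gc.logistic_association(y, x)
        assert assoc.estimate == pytest.approx(np.log(1.07), rel=0.2, abs=0.02)


class TestEwasNumericTrait:
    def test_cpg_identical_to_trait(self):
        rng = np.random.default_rng(22)
        trait = rng.uniform(0.2, 0.8, 50)
        data = pd.DataFrame(
            {"cg00000001": trait, "cg00000002": rng.uniform(0, 1, 50)},
            index=[f"S{i}" for i in range(50)],
        )
        table = gc.ewas_numeric_trait(gc.MethylationMatrix(data), trait)
        row = table.set_index("cpg").loc["cg00000001"]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-100

    def test_outlier_masked_before_correlation(self):
        rng = np.random.default_rng(23)
        n = 100
        base = 0.5 + 0.01 * rng.normal(size=n)
        trait = rng.normal(size=n)
        x = base.copy()
        x[0] = min(1.0, base.mean() + 8 * base.std(ddof=1))  # 8-SD methylation outlier
        data = pd.DataFrame({"cg00000001": x}, index=[f"S{i}" for i in range(n)])
        table = gc.ewas_numeric_trait(gc.MethylationMatrix(data), trait)
        row = table.iloc[0]
        assert row["n"] == n - 1
        expected_r = stats.pearsonr(x[1:], trait[1:])[0]
        assert row["r"] == pytest.approx(expected_r, abs=1e-12)

    def test_sparse_cpg_emitted_with_missing_stats(self):
        n = 30
        col = np.full(n, np.nan)
        col[:5] = 0.5
        data = pd.DataFrame(
            {"cg00000001": col, "cg00000002": np.linspace(0.1, 0.9, n)},
            index=[f"S{i}" for i in range(n)],
        )
        table = gc.ewas_numeric_trait(
            gc.MethylationMatrix(data), np.linspace(0, 1, n)
        )
        sparse = table.set_index("cpg").loc["cg00000001"]
        assert np.isnan(sparse["r"]) and sparse["n"] == 5


class TestEwasCox:
    def _cohort(self, n=150, p=10, seed=24):
        rng = np.random.default_rng(seed)
        lp = rng.normal(size=n)
        truth = gc.SimTruth({}, {}, 1.5, 60.0, 0.4, seed)
        time, event = gc.simulate_survival(lp, truth, rng=rng)
        betas = rng.uniform(0.2, 0.8, size=(n, p))
        cpgs = [f"cg{i:08d}" for i in range(p)]
        # one CpG is a linear rescaling of the true log hazard
        betas[:, 0] = (lp - lp.min()) / (lp.max() - lp.min() + 1e-9)
        m = gc.MethylationMatrix(
            pd.DataFrame(betas, index=[f"S{i}" for i in range(n)], columns=cpgs)
        )
        cov = pd.DataFrame(
            {"age": rng.uniform(50, 80, n), "female": rng.binomial(1, 0.5, n)}
        )
        return m, time, event, cov, cpgs[0]

    def test_true_signal_cpg_most_significant(self):
        m, time, event, cov, signal_cpg = self._cohort()
        table = gc.ewas_cox(m, time, event, "I", cov)
        best = table.loc[table["p"].idxmin(), "cpg"]
        assert best == signal_cpg

    def test_model_ii_requires_packyrs(self):
        m, time, event, cov, _ = self._cohort()
        with pytest.raises(ValueError, match="packyrs"):
            gc.ewas_cox(m, time, event, "II", cov)

    def test_unknown_model_rejected(self):
        m, time, event, cov, _ = self._cohort()
        with pytest.raises(ValueError, match="model"):
            gc.ewas_cox(m, time, event, "IV", cov)


class TestPhenotypeUtilities:
    def test_comorbidity_all_zero(self):
        counts, contrib = gc.comorbidity_index(pd.DataFrame({"a": [0, 0], "b": [0, 0]}))
        assert counts.tolist() == [0, 0]
        assert contrib.tolist() == [2, 2]

    def test_comorbidity_sum(self):
        df = pd.DataFrame([[1, 0, 1, 1]], columns=list("abcd"))
        counts, contrib = gc.comorbidity_index(df)
        assert counts.iloc[0] == 3 and contrib.iloc[0] == 4

    def test_comorbidity_missing_excluded_and_flagged(self):
        df = pd.DataFrame([[1, np.nan, 1]], columns=list("abc"))
        counts, contrib = gc.comorbidity_index(df)
        assert counts.iloc[0] == 2 and contrib.iloc[0] == 2

    def test_comorbidity_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            gc.comorbidity_index(pd.DataFrame({"a": [2]}))

    @pytest.mark.parametrize(
        "fpi,fpg,expected",
        [(22.5, 1.0, 1.0), (0.0, 7.0, 0.0), (10.0, 5.0, 50.0 / 22.5)],
    )
    def test_homa_ir_formula(self, fpi, fpg, expected):
        assert gc.homa_ir(fpi, fpg) == pytest.approx(expected)

    def test_homa_ir_negative_rejected(self):
        with pytest.raises(ValueError):
            gc.homa_ir(-1.0, 5.0)

    def test_pvalue_adjustment_handles_missing(self):
        p = np.array([0.01, np.nan, 0.04])
        out = adjust_pvalues(p, "bonferroni")
        assert out[0] == pytest.approx(0.02)
        assert np.isnan(out[1])


def test_per_sd_scaling_multiplies_log_hazard():
    # reporting per-SD instead of per-unit scales the log HR by the SD
    x, time, event = _survival_with_exposure(n=500, beta=0.3, seed=30)
    x = 2.5 * x  # exposure with SD ~2.5
    per_unit = gc.cox_association(time, event, x)
    sd = x.std(ddof=1)
    per_sd = gc.cox_association(time, event, x / sd)
    assert per_sd.estimate == pytest.approx(per_unit.estimate * sd, rel=1e-6)
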