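"""ACE likelihood, model selection, profile CIs, classification, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinglyco.simulate import simulate_twin_trait
from twinglyco.twin import (
    DegenerateTraitError,
    TwinACEModel,
    TwinACEResults,
    classify_heritability,
    heritability_table,
    icc,
    power_simulation,
    residualize,
    select_best_model,
    twin_loglik,
)


def _pairs(a2, c2, n_mz, n_dz, seed):
    return simulate_twin_trait(n_mz, n_dz, a2, c2, np.random.default_rng(seed))


class TestResidualize:
    def _cov(self, n, rng):
        return pd.DataFrame(
            {
                "age": rng.normal(58, 9, n),
                "batch": rng.integers(1, 5, n),
            },
            index=[f"s{i}" for i in range(n)],
        )

    def test_noop_limit_without_covariate_effects(self):
        rng = np.random.default_rng(0)
        cov = self._cov(1060, rng)
        y = pd.Series(rng.standard_normal(1060), index=cov.index, name="t")
        r = residualize(y, cov)
        assert np.corrcoef(r, y)[0, 1] > 0.99

    def test_projection_removes_planted_age_slope(self):
        rng = np.random.default_rng(1)
        cov = self._cov(500, rng)
        y = pd.Series(
            0.02 * cov["age"].to_numpy() + rng.standard_normal(500),
            index=cov.index,
            name="t",
        )
        r = residualize(y, cov)
        slope = np.polyfit(cov["age"], r, 1)[0]
        assert abs(slope) < 1e-10

    def test_standardized_output(self):
        rng = np.random.default_rng(2)
        cov = self._cov(300, rng)
        y = pd.Series(rng.normal(5, 3, 300), index=cov.index, name="t")
        r = residualize(y, cov)
        assert r.mean() == pytest.approx(0.0, abs=1e-9)
        assert r.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_constant_trait_rejected(self):
        rng = np.random.default_rng(3)
        cov = self._cov(10, rng)
        with pytest.raises(DegenerateTraitError):
            residualize(pd.Series(np.ones(10), index=cov.index, name="t"), cov)


class TestICC:
    def test_perfect_agreement(self):
        r, _ = icc(np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]))
        assert r == pytest.approx(1.0)

    def test_perfect_disagreement(self):
        r, _ = icc(np.array([[1.0, -1.0], [2.0, -2.0], [-3.0, 3.0]]))
        assert r == pytest.approx(-1.0)

    def test_insufficient_pairs(self):
        with pytest.raises(DegenerateTraitError):
            icc(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_agreement_with_anova_icc(self):
        """Double-entry Pearson tracks the one-way random-effects ANOVA ICC."""
        pingouin = pytest.importorskip("pingouin")
        diffs = []
        for rep in range(50):
            mz, _ = _pairs(0.5, 0.2, 200, 1, 100 + rep)
            r, _ = icc(mz)
            long = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(200), 2),
                    "raters": np.tile([0, 1], 200),
                    "ratings": mz.ravel(),
                }
            )
            tab = pingouin.intraclass_corr(
                long, targets="targets", raters="raters", ratings="ratings"
            )
            anova_icc = float(tab.loc[tab["Type"] == "ICC(1,1)", "ICC"].iloc[0])
            diffs.append(abs(r - anova_icc))
        assert max(diffs) < 0.02


class TestLoglik:
    def test_independence_factorizes(self):
        mz, dz = _pairs(0.3, 0.2, 50, 60, 7)
        ll = twin_loglik(mz, dz, 0.0, 0.0, 1.0)
        vals = np.concatenate([mz.ravel(), dz.ravel()])
        assert ll == pytest.approx(stats.norm.logpdf(vals).sum(), abs=1e-10)

    @pytest.mark.parametrize("a2,c2,e2", [(0.5, 0.2, 0.3), (0.1, 0.1, 0.8), (0.6, 0.0, 0.7)])
    def test_matches_bivariate_normal_density_oracle(self, a2, c2, e2):
        mz, dz = _pairs(0.4, 0.2, 30, 40, 8)
        v = a2 + c2 + e2
        expected = 0.0
        for pairs, cov in ((mz, a2 + c2), (dz, 0.5 * a2 + c2)):
            mvn = stats.multivariate_normal(mean=[0, 0], cov=[[v, cov], [cov, v]])
            expected += mvn.logpdf(pairs).sum()
        assert twin_loglik(mz, dz, a2, c2, e2) == pytest.approx(expected, abs=1e-10)

    def test_pair_order_invariance(self):
        mz, dz = _pairs(0.4, 0.2, 30, 40, 9)
        ll1 = twin_loglik(mz, dz, 0.4, 0.2, 0.4)
        rng = np.random.default_rng(0)
        ll2 = twin_loglik(mz[rng.permutation(30)], dz[rng.permutation(40)], 0.4, 0.2, 0.4)
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_non_positive_definite_is_minus_inf(self):
        mz, dz = _pairs(0.4, 0.2, 10, 10, 10)
        assert twin_loglik(mz, dz, 0.0, 0.0, 0.0) == -np.inf


class TestFit:
    def test_falconer_closed_form_limit(self):
        # rMZ=0.75, rDZ=0.45 -> a2=0.60, c2=0.15, e2=0.25
        mz, dz = _pairs(0.6, 0.15, 200_000, 200_000, 11)
        fit = TwinACEModel(mz, dz).fit("ACE")
        assert fit.a2 == pytest.approx(0.60, abs=0.01)
        assert fit.c2 == pytest.approx(0.15, abs=0.01)
        assert fit.e2 == pytest.approx(0.25, abs=0.01)

    def test_ae_recovery_of_high_heritability(self):
        # the strongest AE trait of the study panel has a2 ~ 0.80
        mz, dz = _pairs(0.8, 0.0, 5000, 5000, 12)
        fit = TwinACEModel(mz, dz).fit("AE")
        assert fit.a2 == pytest.approx(0.80, abs=0.03)
        assert fit.c2 == 0.0

    @pytest.mark.parametrize("a2,c2", [(0.0, 0.0), (0.4, 0.3), (0.7, 0.2)])
    def test_parameter_recovery_grid(self, a2, c2):
        mz, dz = _pairs(a2, c2, 5000, 5000, hash((a2, c2)) % 1000)
        fit = TwinACEModel(mz, dz).fit("ACE")
        assert fit.a2 == pytest.approx(a2, abs=0.03)
        assert fit.c2 == pytest.approx(c2, abs=0.03)

    def test_e_model_is_independence_fit(self):
        mz, dz = _pairs(0.5, 0.2, 100, 100, 13)
        fit = TwinACEModel(mz, dz).fit("E")
        assert fit.a2 == 0.0 and fit.c2 == 0.0 and fit.e2 == 1.0
        assert fit.loglik == pytest.approx(
            twin_loglik(mz, dz, 0.0, 0.0, fit.raw["e"]), abs=1e-8
        )

    def test_nesting_inequalities(self):
        for seed in range(5):
            mz, dz = _pairs(0.4, 0.2, 150, 150, 20 + seed)
            m = TwinACEModel(mz, dz)
            ll = {k: m.fit(k).loglik for k in ("ACE", "AE", "CE", "E")}
            assert ll["ACE"] >= ll["AE"] - 1e-6
            assert ll["ACE"] >= ll["CE"] - 1e-6
            assert ll["AE"] >= ll["E"] - 1e-6
            assert ll["CE"] >= ll["E"] - 1e-6

    def test_components_sum_to_one(self):
        mz, dz = _pairs(0.5, 0.3, 200, 200, 14)
        for model in ("ACE", "AE", "CE", "E"):
            fit = TwinACEModel(mz, dz).fit(model)
            assert fit.a2 + fit.c2 + fit.e2 == pytest.approx(1.0, abs=1e-9)
            assert min(fit.a2, fit.c2, fit.e2) >= 0

    def test_from_dataframe_constructor(self):
        mz, dz = _pairs(0.6, 0.0, 50, 50, 15)
        df = pd.DataFrame(
            {
                "zygosity": ["MZ"] * 50 + ["DZ"] * 50,
                "value_1": np.concatenate([mz[:, 0], dz[:, 0]]),
                "value_2": np.concatenate([mz[:, 1], dz[:, 1]]),
            }
        )
        a = TwinACEModel.from_dataframe(df).fit("AE")
        b = TwinACEModel(mz, dz).fit("AE")
        assert a.a2 == pytest.approx(b.a2, abs=1e-9)


class TestSelection:
    def test_noise_selects_e(self):
        hits = 0
        for rep in range(100):
            mz, dz = _pairs(0.0, 0.0, 500, 500, 3000 + rep)
            if TwinACEModel(mz, dz).select().best_model == "E":
                hits += 1
        assert hits >= 80

    def test_additive_data_selects_ae(self):
        hits = 0
        for rep in range(100):
            mz, dz = _pairs(0.7, 0.0, 2000, 2000, 4000 + rep)
            if TwinACEModel(mz, dz).select().best_model == "AE":
                hits += 1
        assert hits >= 90

    def test_aic_tie_prefers_ae_over_ace(self):
        # data with rDZ < rMZ/2 pushes the C estimate to the zero boundary,
        # where ACE and AE have equal loglik and AE wins by AIC
        rng = np.random.default_rng(16)
        mz = stats.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]]).rvs(2000, random_state=rng)
        dz = stats.multivariate_normal([0, 0], [[1, 0.1], [0.1, 1]]).rvs(2000, random_state=rng)
        m = TwinACEModel(mz, dz)
        fits = m.fit_all()
        assert fits["ACE"].loglik == pytest.approx(fits["AE"].loglik, abs=1e-4)
        sel = select_best_model(fits)
        assert sel.best_model == "AE"
        assert fits["AE"].aic < fits["ACE"].aic

    def test_missing_submodel_rejected(self):
        mz, dz = _pairs(0.5, 0.0, 50, 50, 17)
        fits = TwinACEModel(mz, dz).fit_all()
        fits.pop("CE")
        with pytest.raises(ValueError):
            select_best_model(fits)


class TestProfileCI:
    def test_ae_interval_complement(self):
        mz, dz = _pairs(0.6, 0.0, 500, 500, 18)
        fit = TwinACEModel(mz, dz).fit("AE")
        lo_a, hi_a = fit.conf_int("a2")
        lo_e, hi_e = fit.conf_int("e2")
        assert lo_a == pytest.approx(1 - hi_e, abs=1e-3)
        assert hi_a == pytest.approx(1 - lo_e, abs=1e-3)

    def test_coverage_near_nominal(self):
        """95% profile intervals cover the true a2 in >=90% of simulations."""
        covered = 0
        reps = 200
        for rep in range(reps):
            mz, dz = _pairs(0.6, 0.0, 220, 310, 5000 + rep)
            fit = TwinACEModel(mz, dz).fit("AE")
            lo, hi = fit.conf_int("a2")
            if lo <= 0.6 <= hi:
                covered += 1
        assert covered >= 0.90 * reps

    def test_tiny_sample_interval_is_wide(self):
        rng = np.random.default_rng(19)
        mz = rng.standard_normal((3, 2))
        dz = rng.standard_normal((3, 2))
        fit = TwinACEModel(mz, dz).fit("AE")
        lo, hi = fit.conf_int("a2")
        assert lo == 0.0
        # far wider than the ~0.1 width seen at cohort-sized samples
        assert hi - lo > 0.25

    def test_fixed_component_rejected(self):
        mz, dz = _pairs(0.6, 0.0, 50, 50, 20)
        fit = TwinACEModel(mz, dz).fit("AE")
        with pytest.raises(ValueError):
            fit.conf_int("c2")


class TestClassification:
    def _result(self, model, a2):
        c2 = 0.0 if model in ("AE", "E") else 0.3
        e2 = 1 - a2 - c2
        return TwinACEResults(
            model=model, a2=a2, c2=c2, e2=e2, raw={}, loglik=0.0, aic=0.0,
            n_mz=10, n_dz=10, trait="t",
        )

    def test_ce_model_is_low(self):
        out = classify_heritability([self._result("CE", 0.0)])
        assert out[0].label == "low"
        assert "no additive" in out[0].basis

    def test_threshold_is_inclusive(self):
        assert classify_heritability([self._result("ACE", 0.35)])[0].label == "low"
        assert classify_heritability([self._result("ACE", 0.36)])[0].label == "high"

    def test_high_heritability(self):
        assert classify_heritability([self._result("AE", 0.61)])[0].label == "high"


class TestPower:
    def test_size_not_anticonservative_under_null(self):
        # at a2=c2=0 the LRT sits on the boundary of the parameter space, so
        # the plain chi-square reference is conservative: size <= alpha
        res = power_simulation(100, 100, 0.0, 0.0, alpha=0.05, n_reps=400, rng=30)
        assert res.power <= 0.05 + 3 * max(res.se, 0.011)

    def test_monotone_in_sample_size(self):
        small = power_simulation(25, 25, 0.4, 0.1, n_reps=250, rng=31)
        large = power_simulation(220, 310, 0.4, 0.1, n_reps=250, rng=32)
        assert large.power > small.power

    def test_reps_floor(self):
        with pytest.raises(ValueError):
            power_simulation(10, 10, 0.4, 0.1, n_reps=10)


class TestHeritabilityTable:
    def test_cohort_pipeline_table(self, small_cohort):
        table = heritability_table(
            small_cohort.trait_matrix, small_cohort.covariates
        )
        assert set(table["trait"]) == set(small_cohort.trait_matrix.columns)
        # ICC ordering: MZ above DZ whenever a substantial A component exists
        high = table[table["trait"] == "high_a"].iloc[0]
        assert high["icc_mz_value"] > high["icc_dz_value"]
        assert high["best_model"] in ("AE", "ACE")
        assert high["heritability_class"] == "high"
        noise = table[table["trait"] == "noise"].iloc[0]
        assert noise["heritability_class"] == "low"
        # formatted CI strings follow the published style
        assert "[" in high["A"] and "," in high["A"]
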