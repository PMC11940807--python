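"""MR estimators against independent oracles and exact identities."""

import numpy as np
import pytest
from scipy import stats

from mrmediate.estimators import (
    IVW,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    MREgger,
    MRPresso,
    WaldRatio,
    WeightedMedian,
    WeightedMode,
    _ivw_beta,
    estimate_all,
    ivw,
    wald_ratio,
)
from mrmediate.simulate import SimulationConfig, simulate_two_sample, strong_instruments

from conftest import make_harmonized, wls_normal_equations


class TestWaldRatio:
    def test_formula(self):
        h = make_harmonized([0.1], [0.05], [0.02])
        e = wald_ratio(h)
        assert e.beta == pytest.approx(0.5)
        assert e.se == pytest.approx(0.2)
        assert e.method == "wald"

    def test_null_outcome(self):
        e = wald_ratio(make_harmonized([0.1], [0.0], [0.02]))
        assert e.beta == 0.0 and e.pvalue == pytest.approx(1.0)

    def test_zero_exposure_errors(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(make_harmonized([0.0], [0.05], [0.02]))

    def test_negative_exposure_se_positive(self):
        e = wald_ratio(make_harmonized([-0.1], [0.05], [0.02]))
        assert e.beta == pytest.approx(-0.5) and e.se == pytest.approx(0.2)

    def test_or_ci_ordering(self):
        e = wald_ratio(make_harmonized([0.1], [0.05], [0.02]))
        assert e.ci_low <= e.or_ <= e.ci_high
        assert e.ci_low == pytest.approx(np.exp(e.beta - 1.96 * e.se), rel=1e-3)


class TestIVW:
    def test_equal_ratios_zero_heterogeneity(self):
        # both ratio estimates are 0.5 -> beta=0.5, Q=0, modes agree
        h = make_harmonized([0.1, 0.2], [0.05, 0.10], [0.02, 0.03])
        fe = ivw(h, mode="fixed")
        mre = ivw(h, mode="multiplicative_random")
        assert fe.beta == pytest.approx(0.5)
        assert fe.extra["Q"] == pytest.approx(0.0, abs=1e-25)
        assert fe.se == mre.se

    def test_k1_rejected_but_formula_reduces_to_wald(self):
        h1 = make_harmonized([0.1], [0.05], [0.02])
        with pytest.raises(InsufficientInstrumentsError):
            IVW().fit(h1)
        beta, denom = _ivw_beta(h1.beta_exp, h1.beta_out, 1 / h1.se_out**2)
        assert beta == pytest.approx(wald_ratio(h1).beta, rel=1e-14)
        assert denom**-0.5 == pytest.approx(wald_ratio(h1).se, rel=1e-14)

    def test_k3_matches_wls_oracle(self):
        h = make_harmonized([0.1, 0.2, 0.15], [0.05, 0.11, 0.07],
                            [0.02, 0.03, 0.025])
        e = ivw(h, mode="fixed")
        coef, _ = wls_normal_equations(h.beta_exp[:, None], h.beta_out,
                                       1 / h.se_out**2)
        assert e.beta == pytest.approx(coef[0], abs=1e-12)

    def test_mre_never_below_fixed(self, rng):
        bx = rng.uniform(0.05, 0.3, 10)
        by = rng.normal(0.2 * bx, 0.05)
        h = make_harmonized(bx, by, np.full(10, 0.005))
        fe, mre = ivw(h, "fixed"), ivw(h, "multiplicative_random")
        assert mre.se >= fe.se

    def test_all_zero_exposure_degenerate(self):
        with pytest.raises(DegenerateInstrumentError):
            ivw(make_harmonized([0.0, 0.0], [0.1, 0.1], [0.02, 0.02]))


class TestMREgger:
    def test_exact_linear_data(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        a, theta = 0.03, 0.7
        h = make_harmonized(bx, a + theta * bx, np.full(4, 0.02))
        fit = MREgger().fit(h)
        assert fit.beta_ == pytest.approx(theta, abs=1e-12)
        assert fit.intercept_ == pytest.approx(a, abs=1e-12)
        assert fit.Q_ == pytest.approx(0.0, abs=1e-20)

    def test_intercept_zero_constraint_equals_ivw(self, rng):
        """Through-origin WLS (Egger with intercept pinned at 0) is IVW."""
        bx = rng.uniform(0.05, 0.3, 8)
        by = rng.normal(0.2 * bx, 0.02)
        sy = np.full(8, 0.02)
        h = make_harmonized(bx, by, sy)
        coef, _ = wls_normal_equations(bx[:, None], by, 1 / sy**2)
        assert ivw(h).beta == pytest.approx(coef[0], abs=1e-12)

    def test_k10_matches_wls_oracle(self, rng):
        bx = rng.uniform(-0.3, 0.3, 10)
        by = rng.normal(0.05 + 0.4 * np.abs(bx) * np.sign(bx), 0.03) * np.sign(bx)
        sy = rng.uniform(0.01, 0.05, 10)
        h = make_harmonized(bx, by, sy)
        fit = MREgger().fit(h)
        sign = np.where(bx < 0, -1.0, 1.0)
        X = np.column_stack([np.ones(10), bx * sign])
        coef, se = wls_normal_equations(X, by * sign, 1 / sy**2)
        assert fit.intercept_ == pytest.approx(coef[0], abs=1e-10)
        assert fit.beta_ == pytest.approx(coef[1], abs=1e-10)
        # floored dispersion: reported se >= plain WLS se cannot be asserted
        # in general, but the two agree whenever sigma >= 1
        w = 1 / sy**2
        resid = by * sign - X @ coef
        scale = float(resid @ (w * resid)) / 8
        if scale >= 1:
            assert fit.se_ == pytest.approx(se[1], abs=1e-10)

    def test_k2_insufficient(self):
        with pytest.raises(InsufficientInstrumentsError):
            MREgger().fit(make_harmonized([0.1, 0.2], [0.05, 0.1], [0.02, 0.02]))

    def test_pvalues_use_t_distribution(self):
        h = make_harmonized([0.1, 0.2, 0.3, 0.4], [0.08, 0.13, 0.22, 0.29],
                            np.full(4, 0.02))
        fit = MREgger().fit(h)
        expected = 2 * stats.t.sf(abs(fit.beta_ / fit.se_), 2)
        assert fit.pvalue_ == pytest.approx(expected, rel=1e-12)


class TestWeightedMedian:
    def test_constant_ratios(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_harmonized(bx, 0.3 * bx, [0.02, 0.05, 0.01], se_exp=[1e-4] * 3)
        fit = WeightedMedian(n_boot=50, seed=1).fit(h)
        assert fit.beta_ == pytest.approx(0.3, abs=1e-12)

    def test_equal_weight_interpolation_grid(self):
        # ratios {0.1, 0.2, 0.9} with equal weights: cumulative grid
        # {1/6, 1/2, 5/6}; interpolating at 1/2 lands exactly on 0.2
        bx = np.ones(3)
        by = np.array([0.1, 0.2, 0.9])
        h = make_harmonized(bx, by, np.ones(3), se_exp=[1e-6] * 3)
        fit = WeightedMedian(n_boot=50, seed=1).fit(h)
        assert fit.beta_ == pytest.approx(0.2, abs=1e-12)

    def test_majority_valid_consistency(self, rng):
        """>= 50% of weight valid with tiny noise -> estimate ~ theta."""
        theta, k = 0.4, 15
        bx = rng.uniform(0.2, 0.5, k)
        by = theta * bx
        by[:5] += 1.0  # corrupt a minority
        sy = np.full(k, 1e-4)
        h = make_harmonized(bx, by, sy, se_exp=np.full(k, 1e-6))
        fit = WeightedMedian(n_boot=50, seed=1).fit(h)
        assert fit.beta_ == pytest.approx(theta, abs=1e-3)

    def test_bootstrap_seed_determinism(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        by = np.array([0.05, 0.09, 0.16, 0.06])
        h = make_harmonized(bx, by, np.full(4, 0.02), se_exp=np.full(4, 0.01))
        a = WeightedMedian(n_boot=100, seed=7).fit(h)
        b = WeightedMedian(n_boot=100, seed=7).fit(h)
        assert a.se_ == b.se_


class TestWeightedMode:
    def test_majority_cluster_ignores_outlier(self):
        bx = np.ones(4)
        by = np.array([0.2, 0.2, 0.2, 5.0])
        h = make_harmonized(bx, by, np.ones(4), se_exp=np.full(4, 1e-6))
        fit = WeightedMode(n_boot=50, seed=1).fit(h)
        assert fit.beta_ == pytest.approx(0.2, abs=0.05)

    def test_all_identical_returns_that_ratio(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_harmonized(bx, 0.25 * bx, [0.02] * 3, se_exp=[1e-4] * 3)
        fit = WeightedMode(n_boot=50, seed=1).fit(h)
        assert fit.beta_ == pytest.approx(0.25, abs=1e-12)

    def test_bimodal_matches_density_oracle(self, rng):
        """Grid-argmax of an independently coded weighted KDE."""
        ratios = np.concatenate([rng.normal(0.2, 0.02, 6), rng.normal(0.8, 0.02, 4)])
        bx = np.ones(10)
        sy = rng.uniform(0.5, 2.0, 10)
        h = make_harmonized(bx, ratios, sy, se_exp=np.full(10, 1e-6))
        fit = WeightedMode(n_boot=50, seed=1).fit(h)

        w = (sy / np.abs(bx)) ** -2
        wn = w / w.sum()
        mu = np.sum(wn * ratios)
        sd = np.sqrt(np.sum(wn * (ratios - mu) ** 2))
        iqr = np.percentile(ratios, 75) - np.percentile(ratios, 25)
        hbw = 0.9 * min(sd, iqr / 1.349) * 10 ** (-0.2)
        grid = np.linspace(ratios.min() - 3 * hbw, ratios.max() + 3 * hbw, 2048)
        dens = np.zeros_like(grid)
        for r, wi in zip(ratios, wn):
            dens += wi * np.exp(-0.5 * ((grid - r) / hbw) ** 2)
        assert fit.beta_ == pytest.approx(grid[np.argmax(dens)], abs=1e-12)


class TestMRPresso:
    def _clean(self, rng, k=12, theta=0.3):
        bx = rng.uniform(0.1, 0.4, k)
        sx = np.full(k, 0.01)
        sy = np.full(k, 0.02)
        by = rng.normal(theta * bx, sy)
        return make_harmonized(bx, by, sy, se_exp=sx)

    def test_seed_determinism(self, rng):
        h = self._clean(rng)
        a = MRPresso(n_sim=200, seed=11).fit(h)
        b = MRPresso(n_sim=200, seed=11).fit(h)
        assert a.global_pvalue_ == b.global_pvalue_
        assert a.beta_ == b.beta_

    def test_planted_outlier_flagged_and_corrected(self, rng):
        h = self._clean(rng, k=15)
        by = h.beta_out.copy()
        by[3] += 10 * h.se_out[3]
        h2 = make_harmonized(h.beta_exp, by, h.se_out, se_exp=h.se_exp,
                             ids=list(h.variant_id))
        fit = MRPresso(n_sim=500, seed=5).fit(h2)
        assert "rs3" in fit.outlier_ids_
        assert fit.global_pvalue_ < 0.05
        raw = fit.raw_beta_
        assert abs(fit.beta_ - 0.3) < abs(raw - 0.3)

    def test_no_outliers_returns_raw_ivw(self, rng):
        h = self._clean(rng)
        fit = MRPresso(n_sim=200, seed=3).fit(h)
        if not fit.outlier_ids_:
            assert fit.beta_ == pytest.approx(ivw(h).beta)

    def test_preconditions(self, rng):
        h = self._clean(rng, k=3)
        with pytest.raises(InsufficientInstrumentsError):
            MRPresso(n_sim=200, seed=1).fit(h)
        h4 = self._clean(rng, k=4)
        with pytest.raises(ValueError):
            MRPresso(n_sim=50, seed=1).fit(h4)


class TestEstimateAll:
    def test_k1_routes_to_wald(self):
        ests, errors = estimate_all(make_harmonized([0.1], [0.05], [0.02]))
        assert len(ests) == 1 and ests[0].method == "wald" and ests[0].primary

    def test_k2_only_ivw_among_multi_snp_methods(self):
        h = make_harmonized([0.1, 0.2], [0.05, 0.11], [0.02, 0.03],
                            se_exp=[0.01, 0.01])
        ests, errors = estimate_all(h, n_boot=50, n_sim=100)
        assert [e.method for e in ests] == ["ivw_fe"]
        assert set(errors) == {"egger", "weighted_median", "weighted_mode",
                               "presso_corrected"}

    def test_k10_runs_everything(self, rng):
        bx = rng.uniform(0.1, 0.4, 10)
        by = rng.normal(0.2 * bx, 0.02)
        h = make_harmonized(bx, by, np.full(10, 0.02), se_exp=np.full(10, 0.01))
        ests, errors = estimate_all(h, n_boot=50, n_sim=100, seed=2)
        assert errors == {}
        methods = {e.method for e in ests}
        assert methods == {"ivw_fe", "egger", "weighted_median", "weighted_mode",
                           "presso_corrected"} or "ivw_mre" in methods
        primaries = [e for e in ests if e.primary]
        assert len(primaries) == 1 and primaries[0].method.startswith("ivw")

    def test_heterogeneity_switches_to_random_effects(self, rng):
        bx = rng.uniform(0.1, 0.4, 10)
        by = 0.2 * bx + rng.normal(0, 0.2, 10)  # gross heterogeneity
        h = make_harmonized(bx, by, np.full(10, 0.01), se_exp=np.full(10, 0.01))
        ests, _ = estimate_all(h, n_boot=50, n_sim=100)
        assert ests[0].method == "ivw_mre"


class TestEquivariance:
    """Negating every outcome effect negates the estimate; se unchanged."""

    @pytest.mark.parametrize("cls,kwargs", [
        (IVW, {}),
        (MREgger, {}),
        (WeightedMedian, {"n_boot": 50, "seed": 3}),
        (WeightedMode, {"n_boot": 50, "seed": 3}),
    ])
    def test_outcome_negation(self, rng, cls, kwargs):
        bx = rng.uniform(0.1, 0.4, 8)
        by = rng.normal(0.3 * bx, 0.03)
        sy = rng.uniform(0.01, 0.04, 8)
        sx = np.full(8, 0.01)
        h_pos = make_harmonized(bx, by, sy, se_exp=sx)
        h_neg = make_harmonized(bx, -by, sy, se_exp=sx)
        a = cls(**kwargs).fit(h_pos)
        b = cls(**kwargs).fit(h_neg)
        assert b.beta_ == pytest.approx(-a.beta_, abs=1e-10)
        if cls in (IVW, MREgger):
            assert b.se_ == pytest.approx(a.se_, abs=1e-10)
        else:
            # bootstrap SE is invariant in distribution, not per draw
            assert b.se_ == pytest.approx(a.se_, rel=0.5)

    @pytest.mark.parametrize("cls,kwargs", [
        (IVW, {}),
        (MREgger, {}),
        (WeightedMedian, {"n_boot": 50, "seed": 3}),
    ])
    def test_exposure_rescaling(self, rng, cls, kwargs):
        c = 2.5
        bx = rng.uniform(0.1, 0.4, 8)
        by = rng.normal(0.3 * bx, 0.03)
        sy = rng.uniform(0.01, 0.04, 8)
        sx = np.full(8, 0.01)
        a = cls(**kwargs).fit(make_harmonized(bx, by, sy, se_exp=sx))
        b = cls(**kwargs).fit(make_harmonized(c * bx, by, sy, se_exp=c * sx))
        assert b.beta_ == pytest.approx(a.beta_ / c, rel=1e-9)

    def test_wald_rescaling(self):
        a = wald_ratio(make_harmonized([0.1], [0.05], [0.02]))
        b = wald_ratio(make_harmonized([0.25], [0.05], [0.02]))
        assert b.beta == pytest.approx(a.beta * 0.1 / 0.25)


class TestEggerPleiotropyRobustness:
    def test_inside_pleiotropy_biases_ivw_not_egger(self):
        """Directional pleiotropy (InSIDE): Egger slope stays near truth."""
        theta, reps = 0.3, 60
        ivw_est, egger_est = [], []
        for i in range(reps):
            cfg = strong_instruments(n_snps=30, theta=theta, seed=3000 + i,
                                     pleiotropy=(0.05, 0.05),
                                     palindromic_fraction=0.0)
            exp, out, truth = simulate_two_sample(cfg)
            h = make_harmonized(exp.df.beta.to_numpy(), out.df.beta.to_numpy(),
                                out.df.se.to_numpy(),
                                se_exp=exp.df.se.to_numpy())
            ivw_est.append(IVW().fit(h).beta_)
            egger_est.append(MREgger().fit(h).beta_)
        ivw_bias = abs(np.mean(ivw_est) - theta)
        egger_bias = abs(np.mean(egger_est) - theta)
        assert egger_bias < ivw_bias
        assert ivw_bias > 0.05  # the bias Egger removes is material
        assert egger_bias < 0.05
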