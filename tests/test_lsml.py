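"""Least-squares track: fixed-effect tests, Method III components, half-sib
heritability and sire-component correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from herdvar.lsml import (
    fit_fixed_model,
    henderson3_components,
    phs_correlations,
    phs_heritability,
    robertson_se_rg,
    significance_stars,
)
from herdvar.model_design import ModelSpec, build_design


def balanced_halfsib(rng, s=10, n=8, sigma_s=0.5, sigma_e=1.0):
    sire_idx = np.repeat(np.arange(s), n)
    y = np.repeat(rng.normal(0, sigma_s, s), n) + rng.normal(0, sigma_e, s * n)
    return y, sire_idx


class TestFitFixedModel:
    def test_balanced_oneway_equals_classical_anova(self, rng):
        levels = np.repeat([1, 2, 3], 30)
        y = rng.normal(size=90) + np.repeat([0.0, 0.4, 0.9], 30)
        df = pd.DataFrame({"g": levels, "y": y, "animal_code": range(90)})
        d = build_design(ModelSpec(responses=("y",), factors=("g",), covariate=None), df)
        fit = fit_fixed_model(d)
        classic = stats.f_oneway(*(y[levels == g] for g in (1, 2, 3)))
        assert fit.f_tests["g"][0] == pytest.approx(classic.statistic)
        for g in (1, 2, 3):
            assert fit.ls_means["g"][g][0] == pytest.approx(y[levels == g].mean())

    def test_ls_means_invariant_to_constrained_level(self, rng):
        # relabelling levels moves which level carries the zero constraint;
        # the LS means themselves must not move
        levels = rng.integers(1, 4, 120)
        x = rng.normal(size=120)
        y = 0.5 * x + rng.normal(size=120) + (levels == 2)
        df = pd.DataFrame({"g": levels, "x": x, "y": y, "animal_code": range(120)})
        d1 = build_design(ModelSpec(responses=("y",), factors=("g",), covariate="x"), df)
        relabel = {1: 3, 2: 2, 3: 1}
        df2 = df.assign(g=df.g.map(relabel))
        d2 = build_design(ModelSpec(responses=("y",), factors=("g",), covariate="x"), df2)
        m1 = fit_fixed_model(d1).ls_means["g"]
        m2 = fit_fixed_model(d2).ls_means["g"]
        for g in (1, 2, 3):
            assert m1[g][0] == pytest.approx(m2[relabel[g]][0])

    def test_covariate_slope_recovered(self, rng):
        x = rng.normal(size=150)
        y = 2.0 * x + rng.normal(size=150)
        df = pd.DataFrame(
            {"g": rng.integers(1, 3, 150), "x": x, "y": y, "animal_code": range(150)}
        )
        d = build_design(ModelSpec(responses=("y",), factors=("g",), covariate="x"), df)
        cov = fit_fixed_model(d).covariate
        assert cov["ci_low"] <= 2.0 <= cov["ci_high"]

    def test_significance_codes_convention(self):
        assert significance_stars(0.005) == "***"
        assert significance_stars(0.03) == "**"
        assert significance_stars(0.5) == "*"


class TestMethodIII:
    def test_balanced_design_anova_identity(self, rng):
        s, n = 12, 6
        y, sire_idx = balanced_halfsib(rng, s, n)
        comp = henderson3_components(y[:, None], np.ones((s * n, 1)), sire_idx)
        ys = y.reshape(s, n)
        ms_sire = n * np.sum((ys.mean(1) - y.mean()) ** 2) / (s - 1)
        ms_within = np.sum((ys - ys.mean(1, keepdims=True)) ** 2) / (s * (n - 1))
        assert comp["sigma2_s_raw"][0, 0] == pytest.approx((ms_sire - ms_within) / n)
        assert comp["sigma2_e"][0, 0] == pytest.approx(ms_within)

    def test_duplicated_trait_covariance_equals_variance(self, rng):
        y, sire_idx = balanced_halfsib(rng)
        comp = henderson3_components(
            np.column_stack([y, y]), np.ones((y.size, 1)), sire_idx
        )
        assert comp["sigma2_s"][0, 1] == pytest.approx(comp["sigma2_s"][0, 0])
        assert comp["sigma2_e"][0, 1] == pytest.approx(comp["sigma2_e"][0, 0])

    def test_unbalanced_recovery(self, rng):
        # true sire variance 1, residual 3; unbalanced family sizes
        reps, est_s, est_e = 100, [], []
        for _ in range(reps):
            sizes = rng.integers(3, 15, 40)
            sire_idx = np.repeat(np.arange(40), sizes)
            n = sire_idx.size
            y = np.repeat(rng.normal(0, 1.0, 40), sizes) + rng.normal(0, np.sqrt(3), n)
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            comp = henderson3_components(y[:, None], X, sire_idx)
            est_s.append(comp["sigma2_s_raw"][0, 0])
            est_e.append(comp["sigma2_e"][0, 0])
        assert np.mean(est_s) == pytest.approx(1.0, rel=0.10)
        assert np.mean(est_e) == pytest.approx(3.0, rel=0.10)

    def test_needs_two_sires(self):
        with pytest.raises(ValueError):
            henderson3_components(np.ones((4, 1)), np.ones((4, 1)), np.zeros(4, int))


class TestHalfSibHeritability:
    def test_quarter_intraclass_times_four(self):
        est = phs_heritability(1.0, 3.0, k_eff=10.0, n_sires=20, n_records=200)
        assert est.h2 == pytest.approx(1.0)  # t = 1/4 -> h2 = 1
        assert phs_heritability(0.0, 3.0, 10.0, 20, 200).h2 == 0.0

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError):
            phs_heritability(0.0, 0.0, 10.0, 20, 200)

    def test_swiger_se_positive_and_shrinks_with_size(self):
        small = phs_heritability(0.1, 0.9, 10.0, 10, 100)
        large = phs_heritability(0.1, 0.9, 20.0, 200, 4000)
        assert small.se > large.se > 0


class TestCorrelations:
    def test_constructed_components(self):
        comp = {
            "sigma2_s": np.array([[1.0, 0.5], [0.5, 1.0]]),
            "sigma2_e": np.array([[3.0, 0.0], [0.0, 3.0]]),
        }
        out = phs_correlations({"traits": ["x", "y"], "components": comp})
        assert out["r_g"][0, 1] == pytest.approx(0.5)
        assert out["r_p"][0, 1] == pytest.approx(0.5 / 4.0)

    def test_zero_sire_variance_gives_na_with_reason(self):
        comp = {
            "sigma2_s": np.array([[0.0, 0.0], [0.0, 1.0]]),
            "sigma2_e": np.array([[3.0, 0.1], [0.1, 3.0]]),
        }
        out = phs_correlations({"traits": ["x", "y"], "components": comp})
        assert np.isnan(out["r_g"][0, 1])
        assert ("x", "y") in out["notes"]

    def test_independent_traits_near_zero(self, rng):
        vals = []
        for _ in range(40):
            sire_idx = np.repeat(np.arange(30), 10)
            n = sire_idx.size
            Y = np.column_stack(
                [
                    np.repeat(rng.normal(0, 1, 30), 10) + rng.normal(0, 1, n),
                    np.repeat(rng.normal(0, 1, 30), 10) + rng.normal(0, 1, n),
                ]
            )
            comp = henderson3_components(Y, np.ones((n, 1)), sire_idx)
            out = phs_correlations({"traits": ["a", "b"], "components": comp})
            if not np.isnan(out["r_g"][0, 1]):
                vals.append(out["r_g"][0, 1])
        assert abs(np.mean(vals)) < 0.15

    def test_robertson_se_finite(self):
        a = phs_heritability(0.1, 0.9, 10.0, 50, 500)
        b = phs_heritability(0.15, 0.85, 10.0, 50, 500)
        assert robertson_se_rg(0.3, a, b) > 0
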