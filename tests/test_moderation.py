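"""moderation module: interaction fits, simple slopes, regions of significance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dyadsync.moderation import (
    ModerationFit,
    fit_interaction_model,
    probe_at_sd_levels,
    probe_binary_levels,
    region_of_significance,
    simple_slope,
)


def sim_linear(rng, n=400, b_focal=1.0, b_mod=0.5, b_int=-2.37, noise_sd=5.0,
               binary_focal=False, binary_mod=False):
    """Data with a known interaction structure, centered at generation."""
    focal = (rng.binomial(1, 0.5, n).astype(float) if binary_focal
             else rng.normal(0, 1.5, n))
    mod = (rng.binomial(1, 0.5, n).astype(float) if binary_mod
           else rng.normal(0, 1.0, n))
    cov = rng.binomial(1, 0.4, n).astype(float)
    fc = focal if binary_focal else focal - focal.mean()
    mc = mod if binary_mod else mod - mod.mean()
    y = 50 + b_focal * fc + b_mod * mc + b_int * fc * mc + 0.7 * cov
    y = y + rng.normal(0, noise_sd, n)
    return pd.DataFrame({"y": y, "focal": focal, "mod": mod, "cov1": cov})


def fit_from_printed(b_focal, b_int, **kw):
    return ModerationFit.from_coefficients(
        focal_coef=b_focal, interaction_coef=b_int, **kw)


class TestFit:
    def test_parameter_recovery_n400(self):
        rng = np.random.default_rng(42)
        data = sim_linear(rng, n=400)
        fit = fit_interaction_model(data, "y", "focal", "mod", ["cov1"])
        se_f = np.sqrt(fit.vcov.loc["focal", "focal"])
        se_i = np.sqrt(fit.vcov.loc[fit.interaction, fit.interaction])
        assert abs(fit.coef["focal"] - 1.0) < 2 * se_f
        assert abs(fit.coef[fit.interaction] - (-2.37)) < 2 * se_i
        assert fit.n_used == 400

    def test_centering_makes_continuous_mean_zero(self):
        rng = np.random.default_rng(1)
        data = sim_linear(rng, n=100)
        data["focal"] += 30  # uncentered input
        fit = fit_interaction_model(data, "y", "focal", "mod", ["cov1"])
        assert "focal" in fit.centering and abs(fit.centering["focal"] - 30) < 1
        assert "cov1" not in fit.centering  # binary left alone

    def test_zero_variance_moderator_rank_error(self):
        rng = np.random.default_rng(2)
        data = sim_linear(rng, n=50)
        data["mod"] = 1.0
        with pytest.raises(ValueError, match="rank deficient"):
            fit_interaction_model(data, "y", "focal", "mod", ["cov1"])

    def test_duplicate_predictor_rank_error_names_column(self):
        rng = np.random.default_rng(2)
        data = sim_linear(rng, n=50)
        data["cov1"] = data["focal"]
        with pytest.raises(ValueError, match="cov1|focal"):
            fit_interaction_model(data, "y", "focal", "mod", ["cov1"])

    def test_complete_case_counts(self):
        rng = np.random.default_rng(3)
        data = sim_linear(rng, n=60)
        data.loc[:9, "mod"] = np.nan
        fit = fit_interaction_model(data, "y", "focal", "mod", ["cov1"])
        assert fit.n_used == 50

    def test_too_few_complete_cases(self):
        rng = np.random.default_rng(3)
        data = sim_linear(rng, n=8)
        with pytest.raises(ValueError, match="complete cases"):
            fit_interaction_model(data, "y", "focal", "mod")

    def test_logistic_null_coefficient_coverage(self):
        rng = np.random.default_rng(8)
        inside = 0
        n_rep = 150
        for _ in range(n_rep):
            n = 200
            x = rng.normal(0, 1, n)          # "parent depression", null effect
            m = rng.binomial(1, 0.5, n).astype(float)
            logit_p = 0.2 + 0.8 * m          # planted log-odds 0 for x
            p = 1 / (1 + np.exp(-logit_p))
            y = rng.binomial(1, p)
            data = pd.DataFrame({"y": y, "focal": x, "mod": m})
            fit = fit_interaction_model(data, "y", "focal", "mod", family="logistic")
            se = np.sqrt(fit.vcov.loc["focal", "focal"])
            if abs(fit.coef["focal"]) < 2 * se:
                inside += 1
        assert inside / n_rep >= 0.90

    def test_unknown_family(self):
        with pytest.raises(ValueError, match="family"):
            fit_interaction_model(pd.DataFrame(), "y", "a", "b", family="poisson")


class TestSimpleSlope:
    def test_printed_affect_model_ersb_slope(self):
        # ERSB effect: -3.00 without synchrony, interaction 8.45
        fit = fit_from_printed(-3.00, 8.45, focal="ersb_any",
                               moderator="shared_positive_any")
        res = simple_slope(fit, 1.0)
        assert res.slope_est == pytest.approx(5.45, abs=1e-12)

    def test_printed_affect_model_synchrony_slope(self):
        # synchrony effect: -2.83 without unsupportive ERSB, interaction 8.45
        fit = fit_from_printed(-2.83, 8.45, focal="shared_positive_any",
                               moderator="ersb_any")
        res = simple_slope(fit, 1.0)
        assert res.slope_est == pytest.approx(5.62, abs=1e-12)

    def test_printed_rsa_model_low_synchrony_slope(self):
        # parent-depression slope 0.18 at the moderator mean, interaction
        # -2.37, probed 1 SD (0.21) below the mean
        fit = fit_from_printed(0.18, -2.37, focal="parent_dep_T",
                               moderator="rsa_z", moderator_sd=0.21)
        res = simple_slope(fit, -0.21)
        assert round(res.slope_est, 2) == 0.68

    def test_zero_interaction_constant_slope(self):
        fit = fit_from_printed(1.7, 0.0)
        slopes = {simple_slope(fit, at).slope_est for at in (-5, 0, 2, 11.3)}
        assert slopes == {1.7}

    def test_nonfinite_at_value(self):
        fit = fit_from_printed(1.0, 1.0)
        with pytest.raises(ValueError):
            simple_slope(fit, np.nan)

    def test_se_matches_delta_formula(self):
        rng = np.random.default_rng(5)
        data = sim_linear(rng, n=120)
        fit = fit_interaction_model(data, "y", "focal", "mod", ["cov1"])
        at = 0.7
        res = simple_slope(fit, at)
        v = fit.vcov
        se = np.sqrt(v.loc["focal", "focal"] + at**2 * v.loc[fit.interaction, fit.interaction]
                     + 2 * at * v.loc["focal", fit.interaction])
        assert res.slope_se == pytest.approx(se, abs=1e-12)
        assert res.p == pytest.approx(
            2 * stats.t.sf(abs(res.slope_est / se), fit.df_resid), abs=1e-12)

    def test_recode_identity_binary_moderator(self):
        # b_cond(1) = b_cond(0) + b_int, exactly, under 0<->1 recoding
        rng = np.random.default_rng(6)
        data = sim_linear(rng, n=200, binary_mod=True)
        fit = fit_interaction_model(data, "y", "focal", "mod", ["cov1"])
        s0 = simple_slope(fit, 0.0).slope_est
        s1 = simple_slope(fit, 1.0).slope_est
        assert s1 == pytest.approx(s0 + fit.coef[fit.interaction], abs=1e-10)
        data2 = data.assign(mod=1 - data["mod"])
        fit2 = fit_interaction_model(data2, "y", "focal", "mod", ["cov1"])
        assert simple_slope(fit2, 1.0).slope_est == pytest.approx(s0, abs=1e-10)
        assert simple_slope(fit2, 0.0).slope_est == pytest.approx(s1, abs=1e-10)

    def test_probe_helpers(self):
        rng = np.random.default_rng(7)
        data = sim_linear(rng, n=150, binary_mod=True)
        fit = fit_interaction_model(data, "y", "focal", "mod", ["cov1"])
        both = probe_binary_levels(fit)
        assert [p.at_value for p in both] == [0.0, 1.0]
        datac = sim_linear(rng, n=150)
        fitc = fit_interaction_model(datac, "y", "focal", "mod", ["cov1"])
        lo, mid, hi = probe_at_sd_levels(fitc)
        assert mid.at_value == pytest.approx(fitc.moderator_mean)
        assert hi.at_value - lo.at_value == pytest.approx(2 * fitc.moderator_sd)


def grid_scan_region(fit, alpha=0.05, range_sd=2.0, step=1e-4):
    """Brute-force oracle: scan |t(m)| over mean +/- range_sd*SD."""
    sd = fit.moderator_sd
    lo, hi = fit.moderator_mean - range_sd * sd, fit.moderator_mean + range_sd * sd
    m = np.arange(lo, hi + step * sd, step * sd)
    b_f = fit.coef[fit.focal]
    b_i = fit.coef[fit.interaction]
    v = fit.vcov
    slope = b_f + m * b_i
    se = np.sqrt(v.loc[fit.focal, fit.focal] + m**2 * v.loc[fit.interaction, fit.interaction]
                 + 2 * m * v.loc[fit.focal, fit.interaction])
    crit = stats.t.ppf(1 - alpha / 2, fit.df_resid) if fit.df_resid is not None \
        else stats.norm.ppf(1 - alpha / 2)
    sig = np.abs(slope / se) > crit
    # contiguous significant runs -> intervals
    bounds = []
    start = None
    for i, s in enumerate(sig):
        if s and start is None:
            start = m[i]
        elif not s and start is not None:
            bounds.append((start, m[i - 1]))
            start = None
    if start is not None:
        bounds.append((start, m[-1]))
    return bounds


def random_fit(rng):
    A = rng.normal(0, 1, (2, 2))
    V = A @ A.T * rng.uniform(0.05, 0.5) + np.eye(2) * 1e-4
    focal, interaction = "f", "f:m"
    vcov = pd.DataFrame(V, index=[focal, interaction], columns=[focal, interaction])
    return ModerationFit.from_coefficients(
        focal_coef=rng.normal(0, 2), interaction_coef=rng.normal(0, 2),
        focal="f", moderator="m", vcov=vcov,
        df_resid=float(rng.integers(20, 120)),
        moderator_sd=float(rng.uniform(0.2, 3.0)),
    )


class TestRegionOfSignificance:
    def test_matches_grid_scan_oracle(self):
        rng = np.random.default_rng(17)
        checked = 0
        for _ in range(30):
            fit = random_fit(rng)
            res = region_of_significance(fit)
            oracle = grid_scan_region(fit)
            assert len(res.region_bounds) == len(oracle)
            for (a1, b1), (a2, b2) in zip(res.region_bounds, oracle):
                assert abs(a1 - a2) < 1e-3 * fit.moderator_sd
                assert abs(b1 - b2) < 1e-3 * fit.moderator_sd
            checked += 1
        assert checked == 30

    def test_zero_interaction_significant_everywhere(self):
        vcov = pd.DataFrame([[0.01, 0.0], [0.0, 1e-6]],
                            index=["f", "f:m"], columns=["f", "f:m"])
        fit = ModerationFit.from_coefficients(
            focal_coef=5.0, interaction_coef=0.0, focal="f", moderator="m",
            vcov=vcov, df_resid=50.0, moderator_sd=1.0)
        res = region_of_significance(fit)
        (lo, hi), = res.region_bounds
        assert lo == pytest.approx(-2.0) and hi == pytest.approx(2.0)

    def test_zero_interaction_nonsignificant_empty(self):
        vcov = pd.DataFrame([[4.0, 0.0], [0.0, 1e-6]],
                            index=["f", "f:m"], columns=["f", "f:m"])
        fit = ModerationFit.from_coefficients(
            focal_coef=0.1, interaction_coef=0.0, focal="f", moderator="m",
            vcov=vcov, df_resid=50.0, moderator_sd=1.0)
        assert region_of_significance(fit).region_bounds == []

    def test_rsa_like_topology_significant_below_boundary(self):
        # negative interaction with a positive slope at low moderator values:
        # the significant region must lie below a finite upper boundary
        rng = np.random.default_rng(21)
        n = 5000
        m = rng.normal(0.02, 0.21, n)
        x = rng.normal(0, 7.6, n)
        y = 57.6 + 0.18 * x + 1.0 * (m - m.mean()) - 2.37 * x * (m - m.mean())
        y = y + rng.normal(0, 5, n)
        data = pd.DataFrame({"y": y, "x": x, "m": m})
        fit = fit_interaction_model(data, "y", "x", "m")
        res = region_of_significance(fit)
        lo_range, hi_range = res.region_range
        assert len(res.region_bounds) >= 1
        first = res.region_bounds[0]
        assert first[0] == pytest.approx(lo_range)   # extends to the low edge
        assert first[1] < hi_range                   # finite upper boundary

    def test_requires_vcov(self):
        fit = ModerationFit.from_coefficients(1.0, 1.0, moderator_sd=1.0)
        with pytest.raises(ValueError, match="covariance"):
            region_of_significance(fit)
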