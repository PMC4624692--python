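"""Cosinor fitting: exactness, oracles, equivariances, inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from ghrelin_rhythms import (
    RHYTHMIC_PANEL,
    SimulationConfig,
    acrophase_difference,
    fit_cosinor,
    predict,
    simulate_expression,
    zero_amplitude_test,
)
from ghrelin_rhythms.cosinor import CosinorError
from ghrelin_rhythms.simulate import OMEGA

from conftest import replicate_seeds

T_DESIGN = np.repeat(np.arange(0.0, 25.0, 4.0), 6)


def sse(params, t, y):
    m, a, phi_h = params
    return float(np.sum((y - (m + a * np.cos(OMEGA * t - OMEGA * phi_h))) ** 2))


def grid_refine_fit(t, y):
    """Independent oracle: coarse SSE grid over (M, A, phase) + local refinement."""
    best = None
    for m in np.linspace(y.min(), y.max(), 21):
        for a in np.linspace(0.0, (y.max() - y.min()), 21):
            for phi in np.linspace(0.0, 24.0, 49):
                v = sse((m, a, phi), t, y)
                if best is None or v < best[0]:
                    best = (v, (m, a, phi))
    res = optimize.minimize(sse, best[1], args=(t, y), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20_000})
    m, a, phi = res.x
    if a < 0:
        a, phi = -a, phi + 12.0
    return m, a, phi % 24.0, res.fun


@pytest.mark.parametrize("series", RHYTHMIC_PANEL, ids=lambda s: f"{s.tissue}-{s.gene}")
def test_noiseless_recovery_to_machine_precision(series):
    config = SimulationConfig(series=(series,), noise_sd=0.0, seed=0)
    df = simulate_expression(config)
    fit = fit_cosinor(df["zt_h"].to_numpy(), df["rq"].to_numpy())
    assert fit.mesor == pytest.approx(series.mesor, abs=1e-9)
    assert fit.amplitude == pytest.approx(series.amplitude, abs=1e-9)
    assert fit.acrophase_h == pytest.approx(series.acrophase_h, abs=1e-9)
    assert fit.rss < 1e-18
    assert fit.perfect_fit
    assert fit.f_zero_amplitude == np.inf
    assert fit.p_zero_amplitude == 0.0


def test_constant_data_fits_flat_model():
    y = np.full(T_DESIGN.shape, 5.0)
    fit = fit_cosinor(T_DESIGN, y)
    assert fit.mesor == pytest.approx(5.0)
    assert fit.amplitude == pytest.approx(0.0, abs=1e-12)
    assert fit.rss == pytest.approx(0.0, abs=1e-18)
    assert np.isnan(fit.acrophase_h)
    assert fit.f_zero_amplitude == 0.0
    assert fit.p_zero_amplitude == 1.0


def test_linearized_fit_matches_grid_search_oracle(noisy_series):
    df, _ = noisy_series
    t, y = df["zt_h"].to_numpy(), df["rq"].to_numpy()
    fit = fit_cosinor(t, y)
    m, a, phi, fun = grid_refine_fit(t, y)
    assert fit.mesor == pytest.approx(m, abs=1e-4)
    assert fit.amplitude == pytest.approx(a, abs=1e-4)
    assert abs(acrophase_difference(fit.acrophase_h, phi)) < 1e-3
    assert fit.rss == pytest.approx(fun, abs=1e-8)


def test_standard_errors_match_ols_oracle(noisy_series):
    # The linearized model is OLS on [1, cos, sin]; statsmodels provides an
    # independent covariance computation for the same design.
    import statsmodels.api as sm

    df, _ = noisy_series
    t, y = df["zt_h"].to_numpy(), df["rq"].to_numpy()
    fit = fit_cosinor(t, y)
    X = sm.add_constant(np.column_stack([np.cos(OMEGA * t), np.sin(OMEGA * t)]))
    ols = sm.OLS(y, X).fit()
    assert fit.mesor == pytest.approx(ols.params[0])
    assert fit.beta == pytest.approx(ols.params[1])
    assert fit.gamma == pytest.approx(ols.params[2])
    assert fit.se_mesor == pytest.approx(ols.bse[0])
    assert fit.rss == pytest.approx(ols.ssr)
    # Delta-method SEs from statsmodels' covariance
    cov = ols.cov_params()
    b, g, a = fit.beta, fit.gamma, fit.amplitude
    se_a = np.sqrt(b**2 * cov[1, 1] + g**2 * cov[2, 2] + 2 * b * g * cov[1, 2]) / a
    se_phi = np.sqrt(g**2 * cov[1, 1] + b**2 * cov[2, 2] - 2 * b * g * cov[1, 2]) / a**2
    assert fit.se_amplitude == pytest.approx(se_a)
    assert fit.se_acrophase_h == pytest.approx(se_phi * 12 / np.pi)


def test_predict_peak_and_trough_pituitary_parameters():
    fit = fit_cosinor(
        T_DESIGN, 2.2 + 1.0 * np.cos(OMEGA * T_DESIGN - OMEGA * 20.0)
    )
    assert predict(fit, 20.0) == pytest.approx(3.2, abs=1e-9)
    assert predict(fit, 8.0) == pytest.approx(1.2, abs=1e-9)


def test_predict_periodicity_and_flat_fit(noisy_series):
    df, _ = noisy_series
    fit = fit_cosinor(df["zt_h"].to_numpy(), df["rq"].to_numpy())
    tt = np.linspace(0, 24, 13)
    assert np.allclose(predict(fit, tt), predict(fit, tt + 24.0))
    flat = fit_cosinor(T_DESIGN, np.full(T_DESIGN.shape, 3.0))
    assert np.allclose(flat.predict(tt), 3.0)


@pytest.mark.parametrize(
    "a, b, expected",
    [(16.3, 20.0, -3.7), (7.0, 7.0, 0.0), (23.0, 1.0, -2.0), (1.0, 23.0, 2.0), (0.0, 12.0, 12.0)],
)
def test_acrophase_difference_wraps_to_half_cycle(a, b, expected):
    assert acrophase_difference(a, b) == pytest.approx(expected)


@given(
    scale=st.floats(0.1, 10.0),
    shift=st.floats(-5.0, 5.0),
    delta=st.floats(-24.0, 24.0),
)
@settings(max_examples=30, deadline=None, derandomize=True)
def test_equivariances(scale, shift, delta):
    rng = np.random.default_rng(7)
    y = 2.5 + 1.1 * np.cos(OMEGA * T_DESIGN - OMEGA * 15.0) + rng.normal(0, 0.6, T_DESIGN.size)
    base = fit_cosinor(T_DESIGN, y)
    scaled = fit_cosinor(T_DESIGN, scale * y)
    assert scaled.mesor == pytest.approx(scale * base.mesor, rel=1e-9)
    assert scaled.amplitude == pytest.approx(scale * base.amplitude, rel=1e-9)
    assert scaled.se_amplitude == pytest.approx(scale * base.se_amplitude, rel=1e-9)
    assert scaled.amplitude_ci[1] == pytest.approx(scale * base.amplitude_ci[1], rel=1e-9)
    assert scaled.acrophase_h == pytest.approx(base.acrophase_h, abs=1e-9)
    assert scaled.f_zero_amplitude == pytest.approx(base.f_zero_amplitude, rel=1e-9)
    shifted = fit_cosinor(T_DESIGN, y + shift)
    assert shifted.mesor == pytest.approx(base.mesor + shift, rel=1e-9)
    assert shifted.amplitude == pytest.approx(base.amplitude, rel=1e-9)
    translated = fit_cosinor(T_DESIGN + delta, y)
    assert abs(acrophase_difference(translated.acrophase_h, (base.acrophase_h + delta) % 24)) < 1e-8
    assert translated.amplitude == pytest.approx(base.amplitude, rel=1e-9)
    assert translated.rss == pytest.approx(base.rss, abs=1e-9)


def test_zero_amplitude_test_recomputes_fit_statistics(noisy_series):
    df, _ = noisy_series
    t, y = df["zt_h"].to_numpy(), df["rq"].to_numpy()
    fit = fit_cosinor(t, y)
    f_stat, p = zero_amplitude_test(fit, y)
    assert f_stat == pytest.approx(fit.f_zero_amplitude)
    assert p == pytest.approx(fit.p_zero_amplitude)


def test_zero_amplitude_type_i_error_at_nominal_level():
    # 10,000 flat (null) designs: rejection rate at alpha = 0.005 stays
    # within 3 binomial SEs of nominal.
    alpha = 0.005
    n_rep = 10_000
    rng = np.random.default_rng(2)
    hits = 0
    for _ in range(n_rep):
        y = rng.normal(2.0, 1.0, T_DESIGN.size)
        hits += fit_cosinor(T_DESIGN, y).p_zero_amplitude < alpha
    se = np.sqrt(alpha * (1 - alpha) / n_rep)
    assert hits / n_rep == pytest.approx(alpha, abs=3 * se)


def test_amplitude_bias_is_positive_and_small():
    # Rice regime A >= 3*sigma_A: bias bounded by sigma_A^2 / (2A).
    series = RHYTHMIC_PANEL[0]  # A = 1.2, sigma_A ~ 0.31 at sd 1.0
    amps = []
    for s in replicate_seeds(31, 2000):
        df = simulate_expression(
            SimulationConfig(series=(series,), noise_sd=1.0, seed=int(s))
        )
        amps.append(fit_cosinor(df["zt_h"].to_numpy(), df["rq"].to_numpy()).amplitude)
    amps = np.asarray(amps)
    sigma_a = 1.0 * np.sqrt(2.0 / T_DESIGN.size)
    bias = amps.mean() - series.amplitude
    mc_se = amps.std(ddof=1) / np.sqrt(len(amps))
    assert bias > 0
    assert bias <= sigma_a**2 / (2 * series.amplitude) + 3 * mc_se


def test_estimator_spread_matches_delta_method_se():
    # Empirical SD of amplitude estimates vs the reported SE, within 20%.
    series = RHYTHMIC_PANEL[2]  # gut preproghrelin, A = 3.3
    amps, ses = [], []
    for s in replicate_seeds(41, 400):
        df = simulate_expression(
            SimulationConfig(series=(series,), noise_sd=1.0, seed=int(s))
        )
        fit = fit_cosinor(df["zt_h"].to_numpy(), df["rq"].to_numpy())
        amps.append(fit.amplitude)
        ses.append(fit.se_amplitude)
    assert np.std(amps, ddof=1) == pytest.approx(np.mean(ses), rel=0.2)


def test_amplitude_ci_is_t_based_and_floored():
    from scipy import stats

    rng = np.random.default_rng(9)
    y = rng.normal(2.0, 1.0, T_DESIGN.size)
    fit = fit_cosinor(T_DESIGN, y, ci_level=0.99)
    tcrit = stats.t.ppf(0.995, fit.dof)
    lo, hi = fit.amplitude_ci
    assert hi == pytest.approx(fit.amplitude + tcrit * fit.se_amplitude)
    assert lo == pytest.approx(max(0.0, fit.amplitude - tcrit * fit.se_amplitude))
    assert lo >= 0.0


@pytest.mark.parametrize(
    "t, y",
    [
        (np.array([0.0, 4.0, 8.0]), np.array([1.0, 2.0, 3.0])),  # n <= 3
        (np.repeat([0.0, 12.0, 24.0], 3), np.arange(9.0)),  # collinear: sin term vanishes
    ],
)
def test_unfittable_data_raises(t, y):
    with pytest.raises(CosinorError):
        fit_cosinor(t, y)
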