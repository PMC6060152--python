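"""Mixed-model machinery: transforms, selection, LRT, verdicts, sleep phases."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from dialmet.lme import (
    CT,
    SkipAnalyte,
    analyze_analyte,
    candidate_fixed_terms,
    choose_transform,
    classify_sleep_pattern,
    combine_verdict,
    fit_mixed,
    select_fixed_effects,
    select_random_effects,
    sleep_phase_frame,
    sleep_phase_model,
    transform_response,
)


def _frame(z, mice, hours, condition=None, region="mPFC"):
    n = len(z)
    return pd.DataFrame(
        {
            "mouse": mice,
            "condition": condition if condition is not None else ["a"] * n,
            "region": region,
            "hour": hours,
            "z": z,
        }
    )


def _sim_frame(rng, n_mice=6, n_hours=9, mouse_sd=0.5, slope_sd=0.0,
               cond_effect=0.0, noise=0.5):
    rows = []
    for i in range(n_mice):
        cond = "wake" if i < n_mice // 2 else "sleep"
        b0 = rng.normal(0, mouse_sd)
        b1 = rng.normal(0, slope_sd)
        for h in range(1, n_hours + 1):
            mu = b0 + b1 * h + (cond_effect * h if cond == "wake" else 0.0)
            rows.append((f"m{i}", cond, "mPFC", float(h), mu + rng.normal(0, noise)))
    return pd.DataFrame(rows, columns=["mouse", "condition", "region", "hour", "z"])


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def test_transform_monotone_and_shifted():
    y = np.array([-2.0, 0.0, 3.0])
    for kind in ("log", "sqrt"):
        t = transform_response(y, kind)
        assert np.all(np.diff(t) > 0)
        assert np.isfinite(t).all()


def test_choose_transform_gaussian_vs_lognormal(rng):
    hours = np.tile(np.arange(1.0, 10.0), 6)
    mice = np.repeat([f"m{i}" for i in range(6)], 9)
    gauss = _frame(rng.normal(0, 1, 54), mice, hours)
    assert choose_transform(gauss, ("hour",)) == "identity"
    logn = _frame(np.exp(rng.normal(0, 0.8, 54)), mice, hours)
    assert choose_transform(logn, ("hour",)) == "log"
    const = _frame(np.ones(54), mice, hours)
    assert choose_transform(const, ("hour",)) == "identity"


# ---------------------------------------------------------------------------
# likelihood oracle
# ---------------------------------------------------------------------------

def _direct_random_intercept_ml(y, X, groups):
    """Independent ML fit of a random-intercept LMM: marginal Gaussian
    likelihood with per-group compound-symmetric covariance, optimized over
    (log sigma2, log tau2) with GLS-profiled fixed effects."""
    uniq = np.unique(groups)

    def negll(theta):
        s2, t2 = np.exp(theta)
        XtVX = np.zeros((X.shape[1], X.shape[1]))
        XtVy = np.zeros(X.shape[1])
        parts = []
        for g in uniq:
            m = groups == g
            n_g = int(m.sum())
            Vg = s2 * np.eye(n_g) + t2 * np.ones((n_g, n_g))
            Vinv = np.linalg.inv(Vg)
            parts.append((m, Vg, Vinv))
            XtVX += X[m].T @ Vinv @ X[m]
            XtVy += X[m].T @ Vinv @ y[m]
        beta = np.linalg.solve(XtVX, XtVy)
        ll = 0.0
        for m, Vg, Vinv in parts:
            r = y[m] - X[m] @ beta
            sign, logdet = np.linalg.slogdet(Vg)
            ll -= 0.5 * (logdet + r @ Vinv @ r + m.sum() * np.log(2 * np.pi))
        return -ll, beta

    best = None
    for start in ([-1.0, -1.0], [0.0, -2.0], [-2.0, 0.0]):
        res = optimize.minimize(
            lambda th: negll(th)[0], start, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    nll, beta = negll(best.x)
    return -nll, beta


def test_loglik_matches_direct_ml(rng):
    """MixedLM maximum-likelihood log-likelihood and fixed effects agree
    with a direct profiled-likelihood optimization to 1e-4 relative."""
    df = _sim_frame(rng, n_mice=8, mouse_sd=0.7, noise=0.6, cond_effect=0.1)
    fit = fit_mixed(df, ("C(condition)", "hour"), "1", "identity")
    X = np.column_stack(
        [
            np.ones(len(df)),
            (df["condition"] == "wake").to_numpy(float),
            df["hour"].to_numpy(float),
        ]
    )
    llf, beta = _direct_random_intercept_ml(
        df["z"].to_numpy(), X, df["mouse"].to_numpy()
    )
    assert fit.llf == pytest.approx(llf, rel=1e-4)
    got = np.asarray(fit.result.fe_params)
    # statsmodels orders params [Intercept, C(condition)[T.wake], hour]
    np.testing.assert_allclose(got, beta, rtol=1e-3, atol=1e-4)
    # AIC bookkeeping: 2k - 2 logLik with k = fixed + variance parameters
    assert fit.aic == pytest.approx(2 * fit.k_params - 2 * fit.llf, abs=1e-8)
    assert fit.k_params == len(got) + 2


# ---------------------------------------------------------------------------
# random- and fixed-effect selection
# ---------------------------------------------------------------------------

def test_random_slope_retained_when_present():
    hits = 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        df = _sim_frame(r, slope_sd=0.5, noise=0.4)
        if select_random_effects(df, ("C(condition)", "hour")) == "1 + hour":
            hits += 1
    assert hits >= 6


def test_random_slope_dropped_when_absent():
    drops = 0
    for seed in range(10):
        r = np.random.default_rng(100 + seed)
        df = _sim_frame(r, slope_sd=0.0, noise=0.4)
        if select_random_effects(df, ("C(condition)", "hour")) == "1":
            drops += 1
    assert drops >= 6


def test_random_effects_single_mouse_skipped():
    r = np.random.default_rng(0)
    df = _sim_frame(r, n_mice=1)
    with pytest.raises(SkipAnalyte):
        select_random_effects(df, ("hour",))


def test_candidate_hierarchy():
    for terms in candidate_fixed_terms(include_region=True):
        if CT in terms:
            assert "C(condition)" in terms and "hour" in terms
        if "C(condition):C(region)" in terms:
            assert "C(condition)" in terms and "C(region)" in terms
    # without region no region terms appear
    for terms in candidate_fixed_terms(include_region=False):
        assert all("region" not in t for t in terms)


def test_interaction_selected_when_planted():
    hits = 0
    for seed in range(10):
        r = np.random.default_rng(200 + seed)
        df = _sim_frame(r, cond_effect=0.3, noise=0.4)
        terms, _ = select_fixed_effects(df, "1", include_region=False)
        hits += CT in terms
    assert hits >= 8


def test_noise_selects_small_models():
    small = 0
    for seed in range(10):
        r = np.random.default_rng(300 + seed)
        df = _sim_frame(r, cond_effect=0.0, noise=0.5)
        terms, _ = select_fixed_effects(df, "1", include_region=False)
        small += len(terms) <= 1
    assert small >= 6


def test_lrt_nonnegative_and_bounded(zmatrix, design, cohort):
    _, _, _, truth = cohort
    for a in [truth.state_dependent[0], "A08"]:
        v = analyze_analyte(zmatrix, a, design)
        for p in (v.p_between, v.p_within_sew, v.p_within_ews):
            if p is not None and not np.isnan(p):
                assert 0.0 <= p <= 1.0


def test_planted_effect_direction_and_significance(zmatrix, design, cohort):
    _, _, _, truth = cohort
    a = truth.state_dependent[0]
    v = analyze_analyte(zmatrix, a, design)
    assert v.state_specific is True
    assert set(v.directions.values()) == {"wake_higher"}


# ---------------------------------------------------------------------------
# verdict rule
# ---------------------------------------------------------------------------

def test_verdict_rule_examples():
    """One significant model with agreeing directions suffices; opposite
    directions or all-null p-values do not."""
    w = ["wake_higher"] * 3
    assert combine_verdict([0.0032, 0.0007, 0.1291], w) is True
    assert combine_verdict([0.01, 0.2, 0.3],
                           ["wake_higher", "sleep_higher", "wake_higher"]) is False
    assert combine_verdict([0.06, 0.9, 0.56], w) is False
    assert combine_verdict([0.8409, 0.0012, 0.0040], w) is True


# ---------------------------------------------------------------------------
# sleep-phase model and pattern typing
# ---------------------------------------------------------------------------

def _phase_frame(rng, slopes, noise=0.3, n_mice=6):
    rows = []
    for phase, slope in slopes.items():
        for i in range(n_mice):
            mouse = f"{phase[:1]}{i}"
            b0 = rng.normal(0, 0.3)
            for t in (1.0, 2.0, 3.0):
                rows.append(
                    (mouse, "mPFC", phase, t, b0 + slope * t + rng.normal(0, noise))
                )
    return pd.DataFrame(rows, columns=["mouse", "region", "phase", "t", "z"])


def test_sleep_phase_detects_steeper_recovery(rng):
    frame = _phase_frame(rng, {"early": -0.3, "late": -0.3, "recovery": -1.0})
    res = sleep_phase_model(frame)
    assert res["p_interaction"] < 0.05
    s = res["slopes"]
    assert s["recovery"] < s["early"] < 0
    assert classify_sleep_pattern(res) == "Type2"


def test_sleep_phase_type3_and_type1(rng):
    res = sleep_phase_model(
        _phase_frame(rng, {"early": -1.0, "late": -0.2, "recovery": -0.3})
    )
    assert classify_sleep_pattern(res) == "Type3"
    res = sleep_phase_model(
        _phase_frame(rng, {"early": -0.6, "late": -0.1, "recovery": -0.6})
    )
    if res["p_interaction"] < 0.05:  # late differs; early vs recovery equal
        assert classify_sleep_pattern(res) == "Type1"


def test_sleep_phase_other_when_not_declining(rng):
    res = sleep_phase_model(
        _phase_frame(rng, {"early": 0.8, "late": -0.2, "recovery": -0.8})
    )
    assert res["p_interaction"] < 0.05
    assert classify_sleep_pattern(res) == "other"


def test_sleep_pattern_rules_pure():
    base = {"slopes": {"early": -0.5, "late": -0.2, "recovery": -0.5}}
    assert classify_sleep_pattern(
        {**base, "p_interaction": 0.2, "contrast_early_recovery_p": 0.01}
    ) is None
    assert classify_sleep_pattern(
        {**base, "p_interaction": 0.01, "contrast_early_recovery_p": 0.5}
    ) == "Type1"


def test_sleep_phase_constant_series(rng):
    frame = _phase_frame(rng, {"early": 0.0, "late": 0.0, "recovery": 0.0},
                         noise=0.2)
    res = sleep_phase_model(frame)
    assert abs(res["slopes"]["early"]) < 0.2
    assert res["p_interaction"] > 0.01


def test_sleep_phase_frame_windows(zmatrix, design):
    frame = sleep_phase_frame(zmatrix, "A01", design)
    assert set(frame["phase"]) == {"early", "late", "recovery"}
    assert frame["t"].between(1, 3).all()
    # early/late mice come from the sleep-first arm, recovery from the other
    ids = design.mouse_ids()
    early_mice = set(frame[frame["phase"] == "early"]["mouse"])
    assert early_mice <= set(ids["S6-EW3"])
    rec_mice = set(frame[frame["phase"] == "recovery"]["mouse"])
    assert rec_mice <= set(ids["EW6-S3"])
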