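"""Per-analyte linear mixed-effects state testing and sleep-decline typing.

Three models are fitted per analyte on the hourly z-scores:

* between-groups — hours 1-6, condition = experimental arm (sleep vs the two
  wake arms), both regions pooled with region fixed-effect candidates;
* two within-group models — hours 1-9 of one arm, condition = behavioral
  phase (the 6-h segment vs the 3-h segment after the transition).

Each model is ``y = b0 + b_i0 + sum_p beta_p x_itp + sum_q b_iq z_itq + e``
with per-mouse random effects (intercept, optionally a time slope) and
independent Gaussian residuals.  The fitting engine is statsmodels MixedLM
under maximum likelihood; everything around it — the random-effect
reduction, the hierarchy-respecting AIC search over fixed effects, the
forced-condition likelihood-ratio test, the direction call and the
state-specificity verdict — is implemented here.

The model-selection protocol:

1. response transform: identity / log / sqrt (on min-shifted values),
   whichever minimizes the absolute skewness of pilot-fit residuals;
2. random effects: start with intercept + time slope; drop the slope when
   its variance collapses (< v_tol) or its correlation with the intercept is
   near-perfect (> c_tol); the intercept is never dropped;
3. fixed effects: minimum AIC (2k - 2 logLik, ML) over the
   hierarchy-respecting subsets of {condition, time, condition x time,
   region, condition x region};
4. inference: likelihood-ratio chi-square of the full model (condition
   forced in) against the same model with the highest-order condition term
   removed — a condition x time interaction test when the interaction was
   selected, a main-effect test otherwise.

A separate sleep-phase model contrasts the decline slopes of early sleep,
late sleep and recovery sleep, and classifies significant interactions into
Type 1/2/3 decline patterns (equal rates / recovery faster / early faster).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats

from .config import SLEEP, WAKE, RunConfig, StudyDesign, log
from .preprocess import ZMatrix

COND = "C(condition)"
HOUR = "hour"
REGION = "C(region)"
CT = "C(condition):hour"
CR = "C(condition):C(region)"

WAKE_HIGHER = "wake_higher"
SLEEP_HIGHER = "sleep_higher"


class SkipAnalyte(RuntimeError):
    """Model could not be fit for this analyte (degenerate data)."""


# ---------------------------------------------------------------------------
# group roles and model frames
# ---------------------------------------------------------------------------

def group_roles(design: StudyDesign) -> dict[str, str]:
    """Map schedule shapes to roles: sleep_wake (S6-EW3-like), wake_sleep
    (EW6-S3-like), wake_wake (SW6-EW3-like)."""
    roles: dict[str, str] = {}
    for g in design.groups:
        first, last = g.schedule[0][1], g.schedule[-1][1]
        if first == SLEEP:
            roles["sleep_wake"] = g.name
        elif last == SLEEP:
            roles["wake_sleep"] = g.name
        else:
            roles["wake_wake"] = g.name
    if len(roles) != 3:
        raise ValueError("design does not have the three expected arm shapes")
    return roles


def _hour_state(design: StudyDesign, group: str, hour: int) -> str:
    """Majority scheduled state of the 4 bins composing an hour."""
    start = design.n_reference_bins + (hour - 1) * design.coarse_factor
    states = [
        design.scheduled_state(group, b)
        for b in range(start, start + design.coarse_factor)
    ]
    return WAKE if states.count(WAKE) >= states.count(SLEEP) else SLEEP


def model_frames(
    zm: ZMatrix, analyte: str, design: StudyDesign
) -> dict[str, pd.DataFrame]:
    """Build the three model data frames for one analyte.

    * ``between``: hours 1-6, condition = arm name, both regions;
    * ``within_sew`` / ``within_ews``: hours 1-9 of the sleep-first /
      wake-first arm, condition = scheduled phase of the hour.

    Mixed models tolerate missing cells, so only originally observed hourly
    values enter them; imputed cells (condition-mean or neighbour copies)
    carry no independent information and would overstate the evidence.
    """
    roles = group_roles(design)
    df = zm.data[
        (zm.data["analyte"] == analyte) & (zm.data["provenance"] == "observed")
    ]
    frames: dict[str, pd.DataFrame] = {}

    b = df[df["hour"] <= 6].copy()
    b["condition"] = b["group"]
    frames["between"] = b[["mouse", "condition", "region", "hour", "z"]]

    for key, role in (("within_sew", "sleep_wake"), ("within_ews", "wake_sleep")):
        w = df[df["group"] == roles[role]].copy()
        w["condition"] = [
            _hour_state(design, roles[role], int(h)) for h in w["hour"]
        ]
        frames[key] = w[["mouse", "condition", "region", "hour", "z"]]
    return frames


# ---------------------------------------------------------------------------
# response transform
# ---------------------------------------------------------------------------

def transform_response(y: np.ndarray, kind: str) -> np.ndarray:
    """Apply identity/log/sqrt after shifting the minimum to 1 (z-scores can
    be negative; the shift is monotone so directions are preserved)."""
    if kind == "identity":
        return np.asarray(y, dtype=float)
    shifted = y - np.nanmin(y) + 1.0
    if kind == "log":
        return np.log(shifted)
    if kind == "sqrt":
        return np.sqrt(shifted)
    raise ValueError(f"unknown transform {kind!r}")


def choose_transform(df: pd.DataFrame, fixed_terms: tuple[str, ...]) -> str:
    """Pick the transform minimizing |skewness| of pilot OLS residuals.

    The pilot fit uses the maximal fixed-effect design; random effects are
    irrelevant for a symmetry diagnostic.  Constant responses fall back to
    identity.
    """
    y = df["z"].to_numpy(dtype=float)
    if np.nanstd(y) == 0:
        log.warning("constant response; identity transform")
        return "identity"
    from patsy import dmatrix

    X = np.asarray(dmatrix(_formula_rhs(fixed_terms), df))
    best, best_skew = "identity", np.inf
    for kind in ("identity", "log", "sqrt"):
        yt = transform_response(y, kind)
        beta, *_ = np.linalg.lstsq(X, yt, rcond=None)
        resid = yt - X @ beta
        sk = abs(float(stats.skew(resid)))
        if np.isfinite(sk) and sk < best_skew - 1e-12:
            best, best_skew = kind, sk
    return best


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class LMEFit:
    fixed_terms: tuple[str, ...]
    re_formula: str
    transform: str
    llf: float
    aic: float
    k_params: int
    n_fixed: int
    converged: bool
    result: object = field(repr=False, default=None)


def _formula_rhs(terms: tuple[str, ...]) -> str:
    return " + ".join(terms) if terms else "1"


def _fit_ml(model, what: str = "model"):
    """ML fit with an optimizer cascade; best finite-likelihood solution wins.

    MixedLM can raise on a singular Hessian when a variance component sits
    on the boundary, and Powell occasionally wanders to a degenerate ray;
    non-finite likelihoods are rejected outright.
    """
    res = None
    last_err: Exception | None = None
    for method in ("lbfgs", "powell", "cg"):
        try:
            cand = model.fit(reml=False, method=method, maxiter=1000, disp=False)
        except Exception as e:  # singular Hessian at a variance boundary
            last_err = e
            continue
        if not np.isfinite(float(cand.llf)) or float(cand.scale) <= 0:
            last_err = RuntimeError("degenerate fit (non-finite likelihood)")
            continue
        if res is None or float(cand.llf) > float(res.llf):
            res = cand
        if res.converged:
            break
    if res is None:
        raise SkipAnalyte(f"MixedLM failed for {what}: {last_err}")
    return res


def _re_groups(data: pd.DataFrame) -> pd.Series:
    """Random-effect grouping unit.

    Baseline z-scoring standardizes each (mouse, region) series separately,
    so each series carries its own baseline-estimation offset and scale;
    the exchangeable unit for random effects is therefore the mouse-by-
    region series (it coincides with the mouse in single-region fits).
    """
    if "region" in data.columns and data["region"].nunique() > 1:
        return data["mouse"].astype(str) + "/" + data["region"].astype(str)
    return data["mouse"]


def fit_mixed(
    df: pd.DataFrame,
    fixed_terms: tuple[str, ...],
    re_formula: str = "1",
    transform: str = "identity",
) -> LMEFit:
    """One ML MixedLM fit; AIC = 2k - 2 logLik with k = fixed + variance params."""
    data = df.copy()
    data["y"] = transform_response(data["z"].to_numpy(dtype=float), transform)
    formula = "y ~ " + _formula_rhs(fixed_terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula, data, groups=_re_groups(data), re_formula=re_formula
        )
        res = _fit_ml(model, what=formula)
    q = res.cov_re.shape[0]
    k = len(res.fe_params) + q * (q + 1) // 2 + 1
    return LMEFit(
        fixed_terms=tuple(fixed_terms),
        re_formula=re_formula,
        transform=transform,
        llf=float(res.llf),
        aic=2 * k - 2 * float(res.llf),
        k_params=k,
        n_fixed=len(res.fe_params),
        converged=bool(res.converged),
        result=res,
    )


def select_random_effects(
    df: pd.DataFrame,
    fixed_terms: tuple[str, ...],
    time_var: str = "hour",
    v_tol: float = 1e-6,
    c_tol: float = 0.99,
    transform: str = "identity",
) -> str:
    """Maximal supported random structure among {intercept, intercept+slope}.

    The per-mouse time slope is dropped when its fitted variance collapses
    below ``v_tol``, its correlation with the intercept exceeds ``c_tol`` in
    magnitude, or the fit fails/does not converge.  The intercept is never
    dropped.
    """
    if df["mouse"].nunique() < 2:
        raise SkipAnalyte("random effects unidentifiable with < 2 mice")
    full_re = f"1 + {time_var}"
    try:
        fit = fit_mixed(df, fixed_terms, full_re, transform)
    except SkipAnalyte:
        return "1"
    if not fit.converged:
        return "1"
    cov = np.asarray(fit.result.cov_re)
    var_int, var_slope = cov[0, 0], cov[1, 1]
    if var_slope < v_tol or var_int < v_tol:
        return "1"
    corr = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
    if abs(corr) > c_tol:
        return "1"
    return full_re


def candidate_fixed_terms(include_region: bool) -> list[tuple[str, ...]]:
    """Hierarchy-respecting subsets of {condition, time, condition x time,
    region, condition x region}; interactions require their main effects."""
    mains = [COND, HOUR] + ([REGION] if include_region else [])
    out: list[tuple[str, ...]] = []
    for r in range(len(mains) + 1):
        for subset in itertools.combinations(mains, r):
            inter: list[list[str]] = [[]]
            if COND in subset and HOUR in subset:
                inter = [i + [CT] for i in inter] + inter
            if COND in subset and REGION in subset:
                inter = [i + [CR] for i in inter] + inter
            for extra in inter:
                out.append(tuple(list(subset) + sorted(extra)))
    return sorted(set(out), key=lambda t: (len(t), t))


def select_fixed_effects(
    df: pd.DataFrame,
    re_formula: str,
    include_region: bool,
    transform: str = "identity",
) -> tuple[tuple[str, ...], LMEFit]:
    """Minimum-AIC candidate among ML fits; non-converging candidates skipped."""
    best: LMEFit | None = None
    for terms in candidate_fixed_terms(include_region):
        try:
            fit = fit_mixed(df, terms, re_formula, transform)
        except SkipAnalyte:
            continue
        if not fit.converged:
            continue
        if best is None or fit.aic < best.aic - 1e-9:
            best = fit
    if best is None:
        raise SkipAnalyte("no fixed-effect candidate converged")
    return best.fixed_terms, best


def _force_condition(terms: tuple[str, ...]) -> tuple[str, ...]:
    if COND in terms:
        return terms
    return tuple([COND] + list(terms))


def _reduced_terms(terms: tuple[str, ...]) -> tuple[tuple[str, ...], str]:
    """Reduced model: the effect of condition removed entirely (main effect
    and every condition interaction).  The test's interpretation depends on
    the full model's form: a condition x time test when the interaction was
    selected, a main-effect test otherwise."""
    reduced = tuple(t for t in terms if t not in (COND, CT, CR))
    effect = "interaction" if CT in terms else "main"
    return reduced, effect


def test_condition(
    df: pd.DataFrame,
    full_terms: tuple[str, ...],
    re_formula: str,
    transform: str,
    direction_fn,
) -> tuple[float, str, str, LMEFit]:
    """LRT of the forced-condition full model against its condition-reduced
    counterpart; returns (p, effect type, direction, full fit)."""
    full_terms = _force_condition(full_terms)
    reduced_terms, effect = _reduced_terms(full_terms)
    full = fit_mixed(df, full_terms, re_formula, transform)
    if reduced_terms == full_terms:
        return 1.0, effect, direction_fn(full), full
    reduced = fit_mixed(df, reduced_terms, re_formula, transform)
    lr = 2 * (full.llf - reduced.llf)
    if lr < -1e-6:
        # ML surface multimodal: retry the full fit from a different optimizer
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res2 = full.result.model.fit(
                    reml=False, method="powell", maxiter=1000, disp=False
                )
                if float(res2.llf) > full.llf:
                    full.llf = float(res2.llf)
                    full.aic = 2 * full.k_params - 2 * full.llf
                    full.result = res2
                    lr = 2 * (full.llf - reduced.llf)
            except Exception:
                pass
        if lr < -1e-4:
            raise SkipAnalyte(
                f"reduced model out-fits full model (LR={lr:.3g})"
            )
    lr = max(lr, 0.0)
    dof = full.n_fixed - reduced.n_fixed
    p = float(stats.chi2.sf(lr, dof)) if dof > 0 else 1.0
    return p, effect, direction_fn(full), full


def _predict_fixed(fit: LMEFit, new: pd.DataFrame) -> np.ndarray:
    di = fit.result.model.data.design_info
    (X,) = build_design_matrices([di], new)
    return np.asarray(X) @ np.asarray(fit.result.fe_params)


def _direction_between(design: StudyDesign):
    roles = group_roles(design)
    wake_groups = [roles["wake_sleep"], roles["wake_wake"]]
    sleep_groups = [roles["sleep_wake"]]

    def fn(fit: LMEFit) -> str:
        regions = fit.result.model.data.frame["region"].unique()
        rows = [
            {"condition": c, "hour": 6.0, "region": r}
            for c in wake_groups + sleep_groups
            for r in regions
        ]
        new = pd.DataFrame(rows)
        pred = _predict_fixed(fit, new)
        new["pred"] = pred
        wake = new[new["condition"].isin(wake_groups)]["pred"].mean()
        slp = new[new["condition"].isin(sleep_groups)]["pred"].mean()
        return WAKE_HIGHER if wake >= slp else SLEEP_HIGHER

    return fn


def _direction_within(final_hour: float = 9.0):
    def fn(fit: LMEFit) -> str:
        frame = fit.result.model.data.frame
        regions = frame["region"].unique()
        conds = frame["condition"].unique()
        if len(conds) < 2:  # phase never varied (should not happen)
            return WAKE_HIGHER
        rows = [
            {"condition": c, "hour": final_hour, "region": r}
            for c in (WAKE, SLEEP)
            for r in regions
        ]
        new = pd.DataFrame(rows)
        new["pred"] = _predict_fixed(fit, new)
        wake = new[new["condition"] == WAKE]["pred"].mean()
        slp = new[new["condition"] == SLEEP]["pred"].mean()
        return WAKE_HIGHER if wake >= slp else SLEEP_HIGHER

    return fn


# ---------------------------------------------------------------------------
# per-analyte verdict
# ---------------------------------------------------------------------------

@dataclass
class StateVerdict:
    analyte: str
    p_between: float | None
    p_within_sew: float | None
    p_within_ews: float | None
    effects: dict[str, str]
    directions: dict[str, str]
    state_specific: bool | None  # None = undetermined (a model was skipped)

    @property
    def determined(self) -> bool:
        return self.state_specific is not None


def _run_model(
    df: pd.DataFrame, config: RunConfig, direction_fn
) -> tuple[float, str, str]:
    df = df.dropna(subset=["z"])
    if df.empty or df["mouse"].nunique() < 2:
        raise SkipAnalyte("insufficient data")
    include_region = df["region"].nunique() > 1
    maximal = candidate_fixed_terms(include_region)[-1]
    transform = choose_transform(df, maximal)
    re_formula = select_random_effects(
        df, maximal, "hour", config.v_tol, config.c_tol, transform
    )
    terms, _ = select_fixed_effects(df, re_formula, include_region, transform)
    p, effect, direction, _ = test_condition(
        df, terms, re_formula, transform, direction_fn
    )
    return p, effect, direction


def analyze_analyte(
    zm: ZMatrix,
    analyte: str,
    design: StudyDesign,
    config: RunConfig | None = None,
) -> StateVerdict:
    """Run the three models and issue the state-specificity verdict.

    State-specific iff at least one model rejects at alpha AND the implied
    wake-vs-sleep direction agrees across all three models.
    """
    config = config or RunConfig()
    frames = model_frames(zm, analyte, design)
    runners = {
        "between": _direction_between(design),
        "within_sew": _direction_within(),
        "within_ews": _direction_within(),
    }
    ps: dict[str, float | None] = {}
    effects: dict[str, str] = {}
    directions: dict[str, str] = {}
    skipped = False
    for key, direction_fn in runners.items():
        try:
            p, effect, direction = _run_model(frames[key], config, direction_fn)
            ps[key] = p
            effects[key] = effect
            directions[key] = direction
        except SkipAnalyte as e:
            log.info("analyte %s model %s skipped: %s", analyte, key, e)
            ps[key] = None
            skipped = True
    if skipped:
        verdict = None
    else:
        verdict = combine_verdict(
            list(ps.values()), list(directions.values()), config.alpha
        )
    return StateVerdict(
        analyte=analyte,
        p_between=ps.get("between"),
        p_within_sew=ps.get("within_sew"),
        p_within_ews=ps.get("within_ews"),
        effects=effects,
        directions=directions,
        state_specific=verdict,
    )


def combine_verdict(
    ps: list[float], directions: list[str], alpha: float = 0.05
) -> bool:
    """State-specificity rule: at least one model rejects at alpha AND the
    wake-vs-sleep direction is consistent across all models."""
    any_sig = any(p < alpha for p in ps)
    consistent = len(set(directions)) == 1
    return bool(any_sig and consistent)


def significance_stars(p: float | None) -> str:
    if p is None or np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def state_specificity_report(
    zm: ZMatrix,
    design: StudyDesign,
    analytes: list[str] | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-analyte table of the three model p-values and the verdict."""
    config = config or RunConfig()
    analytes = analytes or sorted(zm.data["analyte"].unique())
    rows = []
    for a in analytes:
        v = analyze_analyte(zm, a, design, config)
        rows.append(
            {
                "analyte": a,
                "p_between": v.p_between,
                "p_within_sew": v.p_within_sew,
                "p_within_ews": v.p_within_ews,
                "stars_between": significance_stars(v.p_between),
                "stars_within_sew": significance_stars(v.p_within_sew),
                "stars_within_ews": significance_stars(v.p_within_ews),
                "direction": (
                    v.directions.get("between")
                    if len(set(v.directions.values())) == 1
                    else "inconsistent"
                ),
                "state_specific": v.state_specific,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sleep-phase model and Type 1/2/3 classification
# ---------------------------------------------------------------------------

PHASE_EARLY, PHASE_LATE, PHASE_RECOVERY = "early", "late", "recovery"
_PHASE_TERM = "C(phase, Treatment('early'))"


def sleep_phase_frame(
    zm: ZMatrix, analyte: str, design: StudyDesign, region: str | None = None
) -> pd.DataFrame:
    """Early (S6 hours 1-3), late (S6 hours 4-6) and recovery (EW6-S3 hours
    7-9) sleep windows, time recoded 1-3 within each window.  As in the
    main models, only originally observed cells enter the fit."""
    roles = group_roles(design)
    df = zm.data[
        (zm.data["analyte"] == analyte) & (zm.data["provenance"] == "observed")
    ]
    if region is not None:
        df = df[df["region"] == region]
    s6 = df[df["group"] == roles["sleep_wake"]]
    rec = df[df["group"] == roles["wake_sleep"]]
    parts = [
        s6[s6["hour"].between(1, 3)].assign(phase=PHASE_EARLY, t=lambda d: d["hour"]),
        s6[s6["hour"].between(4, 6)].assign(
            phase=PHASE_LATE, t=lambda d: d["hour"] - 3
        ),
        rec[rec["hour"].between(7, 9)].assign(
            phase=PHASE_RECOVERY, t=lambda d: d["hour"] - 6
        ),
    ]
    out = pd.concat(parts, ignore_index=True)
    return out[["mouse", "region", "phase", "t", "z"]].dropna(subset=["z"])


def sleep_phase_model(
    frame: pd.DataFrame, config: RunConfig | None = None
) -> dict:
    """LRT for the sleep-condition x time interaction plus per-phase slopes.

    Fixed effects: sleep phase (categorical) x time (linear, 1-3); random
    intercept per mouse.  Returns interaction p, the three fitted slopes and
    the Wald p of the early-vs-recovery slope contrast.
    """
    config = config or RunConfig()
    if frame.empty or frame["mouse"].nunique() < 2:
        raise SkipAnalyte("insufficient data for sleep-phase model")
    data = frame.rename(columns={"z": "y"}).copy()
    full_f = f"y ~ {_PHASE_TERM} * t"
    red_f = f"y ~ {_PHASE_TERM} + t"
    groups = _re_groups(data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = _fit_ml(smf.mixedlm(full_f, data, groups=groups), "sleep-phase full")
        red = _fit_ml(smf.mixedlm(red_f, data, groups=groups), "sleep-phase reduced")
    lr = max(0.0, 2 * (float(full.llf) - float(red.llf)))
    dof = len(full.fe_params) - len(red.fe_params)
    p_int = float(stats.chi2.sf(lr, dof))

    params = full.fe_params
    bse = full.bse_fe
    b_t = float(params["t"])
    b_late = float(params.get(f"{_PHASE_TERM}[T.late]:t", 0.0))
    b_rec = float(params.get(f"{_PHASE_TERM}[T.recovery]:t", 0.0))
    slopes = {
        PHASE_EARLY: b_t,
        PHASE_LATE: b_t + b_late,
        PHASE_RECOVERY: b_t + b_rec,
    }
    se_rec = float(bse.get(f"{_PHASE_TERM}[T.recovery]:t", np.nan))
    if np.isfinite(se_rec) and se_rec > 0:
        contrast_p = 2 * float(stats.norm.sf(abs(b_rec) / se_rec))
    else:
        contrast_p = 1.0
    return {
        "p_interaction": p_int,
        "slopes": slopes,
        "contrast_early_recovery_p": contrast_p,
    }


def classify_sleep_pattern(result: dict, alpha: float = 0.05) -> str | None:
    """Type1/2/3/other classification of a sleep-phase interaction.

    Requires a significant interaction (else no label).  Types 1-3 require
    both compared slopes (early, recovery) to be negative; otherwise the
    pattern is "other".  Type 1: early and recovery decline at statistically
    indistinguishable rates; Type 2: recovery declines faster; Type 3: early
    declines faster.
    """
    if result["p_interaction"] >= alpha:
        return None
    early = result["slopes"][PHASE_EARLY]
    rec = result["slopes"][PHASE_RECOVERY]
    if early >= 0 or rec >= 0:
        return "other"
    if result["contrast_early_recovery_p"] >= alpha:
        return "Type1"
    return "Type2" if rec < early else "Type3"


def sleep_phase_report(
    zm: ZMatrix,
    design: StudyDesign,
    analytes: list[str] | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per (analyte, region) interaction p-value and decline pattern."""
    config = config or RunConfig()
    analytes = analytes or sorted(zm.data["analyte"].unique())
    rows = []
    for a in analytes:
        for region in sorted(zm.data["region"].unique()):
            try:
                frame = sleep_phase_frame(zm, a, design, region)
                res = sleep_phase_model(frame, config)
                pattern = classify_sleep_pattern(res, config.alpha)
            except SkipAnalyte:
                continue
            rows.append(
                {
                    "analyte": a,
                    "region": region,
                    "p_interaction": res["p_interaction"],
                    "stars": significance_stars(res["p_interaction"]),
                    "slope_early": res["slopes"][PHASE_EARLY],
                    "slope_late": res["slopes"][PHASE_LATE],
                    "slope_recovery": res["slopes"][PHASE_RECOVERY],
                    "pattern": pattern or "",
                }
            )
    return pd.DataFrame(rows)
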