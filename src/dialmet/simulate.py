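"""Synthetic study-shaped cohorts with known ground truth.

The generator emulates the three-arm microdialysis design: lognormal raw ion
intensities with per-mouse random intercepts, state-coupled drift (log-level
rises per hour spent awake and falls per hour asleep for state-dependent
analytes), "depletion" analytes that decline in every state, hypnogram-derived
wake fractions following the group schedules, homeostatically coupled EEG band
trajectories (2-6 Hz rising across enforced wakefulness, SWA high at sleep
onset and decaying across recovery sleep, gamma uncoupled), unknown spectral
features jittered around planted mass/retention-time centroids, and planted
artifacts (whole-series and point missingness, guaranteed-flaggable outliers).

Every planted property is recorded in :class:`GroundTruth` so downstream
stages have a recoverable target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    BAND_GAMMA,
    BAND_LOW,
    BAND_SWA,
    SLEEP,
    WAKE,
    StudyDesign,
    default_design,
    log,
)


class ParameterError(ValueError):
    """Degenerate or inconsistent generator parameters."""


@dataclass
class GeneratorParams:
    """Knobs of the cohort generator; defaults are the study conditions.

    Slopes are in log-intensity units per hour of the corresponding state;
    with ``noise_sd`` = 0.25 the default +/-0.12 per hour corresponds to a
    divergence of roughly 6 baseline standard deviations between a mouse
    awake for 6 h and one asleep for 6 h, comparable to the clearly visible
    hour-scale trends the design is meant to resolve.
    """

    seed: int = 0
    design: StudyDesign = field(default_factory=default_design)
    n_known_analytes: int = 36
    n_state_dependent: int = 11
    n_depletion: int = 3
    wake_slope: float = 0.12
    sleep_slope: float = -0.12
    depletion_slope: float = -0.08
    noise_sd: float = 0.25
    mouse_re_sd: float = 0.3
    baseline_log_low: float = 4.0
    baseline_log_high: float = 8.0
    p_point_missing: float = 0.005
    p_series_missing: float = 0.04
    n_bad_mice: int = 3
    p_series_missing_bad: float = 0.65
    n_planted_outliers: int = 13
    outlier_margin: float = 1.3
    outlier_factor: float = 5.0
    n_unknown_features: int = 12
    n_unknown_state_dependent: int = 4
    unknown_detect_prob: float = 0.9
    mass_jitter_sd: float = 0.00014
    rt_jitter_sd: float = 0.03
    eeg_noise_sd: float = 0.15
    eeg_wake_gain: float = 0.15
    eeg_mouse_sd: float = 0.2
    eeg_coupling: float = 3.0
    n_negative_coupled: int = 1

    def validate(self) -> None:
        d = self.design
        if d.n_mice <= 0:
            raise ParameterError("design has no mice")
        if self.n_known_analytes <= 0:
            raise ParameterError("need at least one analyte")
        if self.n_state_dependent > self.n_known_analytes:
            raise ParameterError("n_state_dependent exceeds n_known_analytes")
        if self.n_state_dependent + self.n_depletion + self.n_negative_coupled > \
                self.n_known_analytes:
            raise ParameterError("planted analyte classes exceed analyte count")
        for name in ("noise_sd", "mouse_re_sd", "eeg_noise_sd"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in (
            "p_point_missing", "p_series_missing", "p_series_missing_bad",
            "unknown_detect_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        sleep_first = [g for g in d.groups if g.schedule[0][1] == SLEEP]
        if sleep_first and self.n_bad_mice > sleep_first[0].n_mice:
            raise ParameterError("n_bad_mice exceeds the sleep-first group size")


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed the same way as the tables."""

    state_dependent: list[str]
    depletion: list[str]
    analyte_slopes: dict[str, tuple[float, float]]
    mouse_intercepts: dict[str, float]
    missing_series: list[tuple[str, str, str]]
    missing_points: list[tuple[str, str, str, int]]
    planted_outliers: list[tuple[str, str, str, int]]
    eeg_coupling: dict[str, tuple[str, int]]
    unknown_clusters: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=list))


# ---------------------------------------------------------------------------
# wake fractions and EEG trajectories
# ---------------------------------------------------------------------------

def _wake_fractions(params: GeneratorParams, rng: np.random.Generator) -> pd.DataFrame:
    """Per-mouse hypnogram summaries following the group schedules.

    Treadmill segments are fully awake; sleep-opportunity bins draw a small
    wake fraction (mice briefly rouse); novel-object / spontaneous wake bins
    draw a high fraction.  The beta tails occasionally cross 0.5, which is
    exactly what the wrong-state filter exists to remove.
    """
    d = params.design
    rows = []
    ids = d.mouse_ids()
    for g in d.groups:
        states = g.scheduled_states()
        # last schedule segment on the treadmill is fully awake
        segs = [seg for seg in g.schedule]
        for mouse in ids[g.name]:
            for b in range(d.bins_per_mouse):
                if d.is_reference_bin(b):
                    frac = 1.0
                else:
                    idx = b - d.n_reference_bins
                    state = states[idx]
                    # a final wake segment is the treadmill (enforced, fully awake)
                    on_treadmill = (
                        state == WAKE
                        and segs[-1][1] == WAKE
                        and idx >= len(states) - segs[-1][0]
                    )
                    if state == SLEEP:
                        frac = float(rng.beta(2.0, 9.0))
                    elif on_treadmill:
                        frac = 1.0
                    else:
                        frac = float(rng.beta(12.0, 2.0))
                rows.append((mouse, b, frac))
    return pd.DataFrame(rows, columns=["mouse", "bin", "wake_fraction"])


def _state_exposure(design: StudyDesign, wake: pd.DataFrame) -> pd.DataFrame:
    """Cumulative awake/asleep hours per mouse at the end of each bin."""
    wake = wake.sort_values(["mouse", "bin"]).copy()
    per_bin = design.bin_minutes / 60.0
    wake["awake_h"] = wake.groupby("mouse")["wake_fraction"].cumsum() * per_bin
    wake["asleep_h"] = (
        wake.groupby("mouse")["wake_fraction"].transform(lambda s: (1 - s).cumsum())
        * per_bin
    )
    return wake


def _band_power(
    params: GeneratorParams,
    wake: pd.DataFrame,
    rng: np.random.Generator,
    mouse_offsets: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Hourly EEG band powers with homeostatic shapes.

    2-6 Hz wake activity grows with cumulative time awake on top of a
    per-mouse trait offset (``mouse_offsets``, log units); SWA follows a
    sleep-pressure process (accumulates during wake, decays exponentially
    during sleep) so it starts high at sleep onset and declines across
    recovery sleep; gamma is uncoupled lognormal noise.
    """
    d = params.design
    mouse_offsets = mouse_offsets or {}
    exposure = _state_exposure(d, wake)
    rows = []
    for mouse, sub in exposure.groupby("mouse"):
        sub = sub.sort_values("bin")
        pressure = 1.0
        for hour in range(1, d.n_hours + 1):
            bins = sub[(sub["bin"] >= d.n_reference_bins)
                       & (sub["bin"] < d.n_reference_bins + hour * d.coarse_factor)]
            awake_h = float(bins["wake_fraction"].sum()) * d.bin_minutes / 60.0
            hour_bins = bins.tail(d.coarse_factor)
            frac_awake = float(hour_bins["wake_fraction"].mean())
            if frac_awake > 0.5:
                pressure += 0.25 * frac_awake
            else:
                pressure *= np.exp(-0.45)
            low = np.exp(
                1.0 + params.eeg_wake_gain * awake_h
                + mouse_offsets.get(mouse, 0.0)
                + rng.normal(0, params.eeg_noise_sd)
            )
            swa = np.exp(
                0.5 + 0.8 * pressure + rng.normal(0, params.eeg_noise_sd)
            )
            gamma = np.exp(0.0 + rng.normal(0, params.eeg_noise_sd))
            rows += [
                (mouse, hour, BAND_LOW, low),
                (mouse, hour, BAND_SWA, swa),
                (mouse, hour, BAND_GAMMA, gamma),
            ]
    return pd.DataFrame(rows, columns=["mouse", "hour", "band", "power"])


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------

def _analyte_names(params: GeneratorParams) -> list[str]:
    return [f"A{i + 1:02d}" for i in range(params.n_known_analytes)]


def simulate_clean_cohort(
    params: GeneratorParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate tables without planted artifacts.

    Returns (long sample table, wake fractions, band power, ground truth).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    d = params.design
    ids = d.mouse_ids()

    wake = _wake_fractions(params, rng)
    all_mice = [m for g in d.groups for m in ids[g.name]]
    band_offsets = {
        m: float(rng.normal(0, params.eeg_mouse_sd)) for m in all_mice
    }
    band = _band_power(params, wake, rng, band_offsets)
    exposure = _state_exposure(d, wake).set_index(["mouse", "bin"])

    analytes = _analyte_names(params)
    state_dep = analytes[: params.n_state_dependent]
    depletion = analytes[params.n_state_dependent:
                         params.n_state_dependent + params.n_depletion]
    neg_coupled = analytes[params.n_state_dependent + params.n_depletion:
                           params.n_state_dependent + params.n_depletion
                           + params.n_negative_coupled]

    slopes = {a: (0.0, 0.0) for a in analytes}
    for a in state_dep:
        slopes[a] = (params.wake_slope, params.sleep_slope)
    baselines = {
        a: float(rng.uniform(params.baseline_log_low, params.baseline_log_high))
        for a in analytes
    }
    mouse_int = {
        m: float(rng.normal(0, params.mouse_re_sd))
        for g in d.groups for m in ids[g.name]
    }

    coupling: dict[str, tuple[str, int]] = {}
    for a in state_dep:
        coupling[a] = (BAND_LOW, +1)

    bins = np.arange(d.bins_per_mouse)
    hours = np.array([d.hour_of_bin(b) for b in bins])
    elapsed_h = (bins + 1) * d.bin_minutes / 60.0
    frames = []
    for g in d.groups:
        for mouse in ids[g.name]:
            awake = exposure.loc[mouse].sort_index()["awake_h"].to_numpy()
            asleep = exposure.loc[mouse].sort_index()["asleep_h"].to_numpy()
            # trait-like coupling: mice with higher overall 2-6 Hz power
            # carry a constant (post-reference) shift in coupled analytes;
            # a mouse-level shift is absorbed by random intercepts, so it
            # plants a correlation without planting a condition effect
            coup = np.where(hours >= 1, band_offsets[mouse], 0.0)
            for region in d.regions:
                for a in analytes:
                    ws, ss = slopes[a]
                    drift = ws * awake + ss * asleep
                    if a in depletion:
                        drift = drift + params.depletion_slope * elapsed_h
                    if a in neg_coupled:
                        drift = drift - params.eeg_coupling * coup
                    level = (
                        baselines[a] + mouse_int[mouse] + drift
                        + rng.normal(0, params.noise_sd, d.bins_per_mouse)
                    )
                    frames.append(
                        pd.DataFrame(
                            {
                                "mouse": mouse,
                                "group": g.name,
                                "region": region,
                                "analyte": a,
                                "bin": bins,
                                "intensity": np.exp(level),
                            }
                        )
                    )
    table = pd.concat(frames, ignore_index=True)

    for a in neg_coupled:
        coupling[a] = (BAND_LOW, -1)

    truth = GroundTruth(
        state_dependent=state_dep,
        depletion=depletion,
        analyte_slopes=slopes,
        mouse_intercepts=mouse_int,
        missing_series=[],
        missing_points=[],
        planted_outliers=[],
        eeg_coupling=coupling,
    )
    return table, wake, band, truth


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

def plant_artifacts(
    table: pd.DataFrame,
    params: GeneratorParams,
    truth: GroundTruth | None = None,
    wake: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Blank whole series and random points; inject guaranteed outliers.

    Whole-series missingness is concentrated: ``n_bad_mice`` mice of the
    sleep-first arm lose each series with probability
    ``p_series_missing_bad``, all other mice with the background
    ``p_series_missing`` — the skewed pattern typical of probe or assay
    trouble in a few animals.  Outliers are written on the raw-intensity
    scale at a z-score of ``outlier_margin * outlier_factor * max|z|`` of
    the rest of the series, so the downstream 5x flag rule fires by
    construction.  When wake fractions are supplied, outliers are planted
    only at schedule-consistent bins (those the wrong-state filter retains).
    """
    params.validate()
    d = params.design
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 104729]))
    table = table.copy()
    if truth is None:
        truth = GroundTruth(
            state_dependent=[], depletion=[], analyte_slopes={},
            mouse_intercepts={}, missing_series=[], missing_points=[],
            planted_outliers=[], eeg_coupling={},
        )

    series_keys = (
        table[["mouse", "group", "region", "analyte"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    n_cells = len(table)
    if params.n_planted_outliers > len(series_keys):
        raise ParameterError("more planted outliers than available series")

    # -- whole-series missingness (concentrated in a few bad mice) ---------
    sleep_first = [g for g in d.groups if g.schedule[0][1] == SLEEP]
    bad_mice: set[str] = set()
    if sleep_first and params.n_bad_mice > 0:
        candidates_bad = sorted(
            set(table.loc[table["group"] == sleep_first[0].name, "mouse"])
        )
        pick_bad = rng.permutation(candidates_bad)[: params.n_bad_mice]
        bad_mice = set(pick_bad)
    p_per_series = np.where(
        series_keys["mouse"].isin(bad_mice),
        params.p_series_missing_bad,
        params.p_series_missing,
    )
    blank = series_keys[rng.random(len(series_keys)) < p_per_series]
    blank_set = set(map(tuple, blank[["mouse", "region", "analyte"]].to_numpy()))
    mask_series = table.set_index(["mouse", "region", "analyte"]).index.isin(blank_set)
    table.loc[mask_series, "intensity"] = np.nan
    truth.missing_series = sorted(blank_set)

    # -- point missingness --------------------------------------------------
    observed = table["intensity"].notna().to_numpy()
    point_mask = (rng.random(n_cells) < params.p_point_missing) & observed
    truth.missing_points = [
        (r.mouse, r.region, r.analyte, int(r.bin))
        for r in table.loc[point_mask].itertuples()
    ]
    table.loc[point_mask, "intensity"] = np.nan

    # -- planted outliers ----------------------------------------------------
    wake_idx = None
    if wake is not None:
        wake_idx = wake.set_index(["mouse", "bin"])["wake_fraction"]
    candidates = series_keys[
        ~series_keys.set_index(["mouse", "region", "analyte"]).index.isin(blank_set)
    ]
    if params.n_planted_outliers > len(candidates):
        raise ParameterError("not enough intact series for requested outliers")
    pick = candidates.sample(
        n=params.n_planted_outliers, random_state=int(rng.integers(2**31))
    )
    indexed = table.set_index(["mouse", "region", "analyte"]).sort_index()
    outliers: list[tuple[str, str, str, int]] = []
    for r in pick.itertuples():
        series = indexed.loc[(r.mouse, r.region, r.analyte)].reset_index(drop=True)
        ref = series[series["bin"] < d.n_reference_bins]["intensity"].dropna()
        if len(ref) < 2 or ref.std(ddof=1) == 0:
            continue
        mu, sd = float(ref.mean()), float(ref.std(ddof=1))
        exp_bins = series[(series["bin"] >= d.n_reference_bins)
                          & series["intensity"].notna()]
        if wake_idx is not None:
            keep = []
            for rr in exp_bins.itertuples():
                sched = d.scheduled_state(r.group, int(rr.bin))
                frac = float(wake_idx.loc[(r.mouse, int(rr.bin))])
                wrong = frac > 0.5 if sched == SLEEP else (1 - frac) > 0.5
                if not wrong:
                    keep.append(rr.Index)
            exp_bins = exp_bins.loc[keep]
        if exp_bins.empty:
            continue
        target_bin = int(
            exp_bins["bin"].iloc[int(rng.integers(len(exp_bins)))]
        )
        z = (series["intensity"] - mu) / sd
        others = z[series["bin"] != target_bin].abs()
        zmax = float(others.max(skipna=True))
        zmax = max(zmax, 1.0)  # floor so the planted spike is never tiny
        spike = mu + params.outlier_margin * params.outlier_factor * zmax * sd
        sel = (
            (table["mouse"] == r.mouse)
            & (table["region"] == r.region)
            & (table["analyte"] == r.analyte)
            & (table["bin"] == target_bin)
        )
        table.loc[sel, "intensity"] = spike
        outliers.append((r.mouse, r.region, r.analyte, target_bin))
    truth.planted_outliers = outliers
    log.info(
        "planted %d missing series, %d missing points, %d outliers",
        len(truth.missing_series), len(truth.missing_points), len(outliers),
    )
    return table, truth


def simulate_cohort(
    params: GeneratorParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Full cohort: clean simulation plus planted artifacts."""
    table, wake, band, truth = simulate_clean_cohort(params)
    table, truth = plant_artifacts(table, params, truth, wake)
    return table, wake, band, truth


# ---------------------------------------------------------------------------
# unknown spectral features
# ---------------------------------------------------------------------------

def simulate_unknown_features(
    params: GeneratorParams,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Jittered spectral features around planted (mass, rt) centroids.

    The first ``n_unknown_state_dependent`` clusters carry the same
    state-coupled drift as known state-dependent analytes; the rest are
    flat.  Per (mouse, region, bin) sample each cluster is detected with
    probability ``unknown_detect_prob``.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7919]))
    d = params.design
    ids = d.mouse_ids()
    wake = _wake_fractions(params, rng)
    exposure = _state_exposure(d, wake).set_index(["mouse", "bin"])

    n = params.n_unknown_features
    # centroids spaced far apart relative to the tolerances
    masses = np.sort(rng.uniform(80.0, 500.0, n))
    while np.any(np.diff(masses) < 0.05):
        masses = np.sort(rng.uniform(80.0, 500.0, n))
    rts = rng.uniform(0.5, 13.0, n)

    clusters: dict[str, dict] = {}
    frames = []
    nb = d.bins_per_mouse
    for ci in range(n):
        name = f"U{ci + 1:02d}"
        dep = ci < params.n_unknown_state_dependent
        base = float(rng.uniform(4, 7))
        clusters[name] = {
            "mass": float(masses[ci]),
            "rt": float(rts[ci]),
            "state_dependent": bool(dep),
        }
        for g in d.groups:
            for mouse in ids[g.name]:
                mi = float(rng.normal(0, params.mouse_re_sd))
                sub = exposure.loc[mouse].sort_index()
                drift = (
                    params.wake_slope * sub["awake_h"].to_numpy()
                    + params.sleep_slope * sub["asleep_h"].to_numpy()
                    if dep
                    else np.zeros(nb)
                )
                for region in d.regions:
                    detected = rng.random(nb) <= params.unknown_detect_prob
                    level = base + mi + drift + rng.normal(0, params.noise_sd, nb)
                    frames.append(
                        pd.DataFrame(
                            {
                                "mass": masses[ci]
                                + rng.normal(0, params.mass_jitter_sd, nb),
                                "rt": rts[ci]
                                + rng.normal(0, params.rt_jitter_sd, nb),
                                "mouse": mouse,
                                "region": region,
                                "bin": np.arange(nb),
                                "intensity": np.exp(level),
                            }
                        )[detected]
                    )
    features = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        state_dependent=[k for k, v in clusters.items() if v["state_dependent"]],
        depletion=[],
        analyte_slopes={},
        mouse_intercepts={},
        missing_series=[],
        missing_points=[],
        planted_outliers=[],
        eeg_coupling={},
        unknown_clusters=clusters,
    )
    return features, truth
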