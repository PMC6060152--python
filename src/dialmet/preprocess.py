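"""Preprocessing ladder for microdialysis intensity tables.

Order of operations (each step feeds the next):

1. detection filter       — keep analytes observed in >= ``min_mice`` mice in
                            every condition, separately per region;
2. baseline z-scoring     — per (mouse, region, analyte), using mean/sd of the
                            reference-window samples;
3. outlier flagging       — |z| more than ``factor`` (default 5) times every
                            other |z| of the same series -> set missing;
4. wrong-state exclusion  — 15-min bins where the observed state contradicts
                            the scheduled one by more than 50% are removed;
5. coarse-graining        — average blocks of 4 bins into hourly values;
6. two-tier imputation    — condition-mean for wholly missing series, then
                            k=2 nearest-hour averaging for point gaps.

The hourly result is a :class:`ZMatrix`: a long table of z-scores with a
provenance mask (observed / imputed_tier1 / imputed_tier2) and the per-series
baseline statistics, plus an audit of everything dropped or filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SLEEP, IntegrityError, SchemaError, StudyDesign, log

OBSERVED = "observed"
MISSING = "missing"
TIER1 = "imputed_tier1"
TIER2 = "imputed_tier2"

_SERIES = ["mouse", "region", "analyte"]


class ParameterError(ValueError):
    pass


@dataclass
class ZMatrix:
    """Hourly coarse-grained z-scores with provenance.

    ``data`` columns: mouse, group, region, analyte, hour (1-based), z,
    provenance.  ``baseline_stats`` columns: mouse, region, analyte,
    ref_mean, ref_sd, n_ref.
    """

    data: pd.DataFrame
    baseline_stats: pd.DataFrame
    audit: dict = field(default_factory=dict)

    def complete(self) -> bool:
        return not self.data["z"].isna().any()

    def pivot(self, region: str | None = None) -> pd.DataFrame:
        df = self.data
        if region is not None:
            df = df[df["region"] == region]
        return df.pivot_table(
            index=["mouse", "group", "region", "analyte"],
            columns="hour", values="z", observed=True,
        )


# ---------------------------------------------------------------------------
# 1. detection filter
# ---------------------------------------------------------------------------

def detection_filter(
    table: pd.DataFrame, min_mice: int = 3
) -> dict[str, list[str]]:
    """Analytes observed in at least ``min_mice`` mice per condition, per region.

    "Observed" means at least one non-missing intensity anywhere in the
    mouse's series for that region.
    """
    groups = table["group"].unique()
    if len(groups) == 0:
        raise SchemaError("table has no groups")
    smallest = table.groupby("group")["mouse"].nunique().min()
    if min_mice > smallest:
        raise ParameterError(
            f"min_mice={min_mice} exceeds smallest group size {smallest}"
        )
    obs = (
        table[table["intensity"].notna()]
        .groupby(["region", "analyte", "group"])["mouse"]
        .nunique()
        .unstack("group", fill_value=0)
        .reindex(columns=groups, fill_value=0)
    )
    keep = obs[(obs >= min_mice).all(axis=1)].reset_index()
    out: dict[str, list[str]] = {r: [] for r in table["region"].unique()}
    for r in keep.itertuples():
        out[r.region].append(r.analyte)
    for r in out:
        out[r] = sorted(out[r])
    return out


def apply_detection_filter(
    table: pd.DataFrame, retained: dict[str, list[str]]
) -> pd.DataFrame:
    keep = pd.concat(
        [
            pd.DataFrame({"region": region, "analyte": analytes})
            for region, analytes in retained.items()
        ],
        ignore_index=True,
    )
    return table.merge(keep, on=["region", "analyte"], how="inner")


# ---------------------------------------------------------------------------
# 2. baseline z-scores
# ---------------------------------------------------------------------------

def baseline_zscore_series(
    x: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """z_t = (x_t - mean(ref)) / sd(ref); requires >=2 finite reference values
    with positive sample sd."""
    ref = reference[np.isfinite(reference)]
    if len(ref) < 2:
        raise ValueError("fewer than 2 reference observations")
    mu = float(np.mean(ref))
    sd = float(np.std(ref, ddof=1))
    if sd == 0:
        raise ValueError("zero reference standard deviation")
    return (x - mu) / sd, mu, sd


def baseline_zscore(
    table: pd.DataFrame, design: StudyDesign
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple]]:
    """Standardize every (mouse, region, analyte) series by its reference bins.

    Series whose reference window is degenerate (all missing, <2 values, or
    zero sd) keep all-missing z so that tier-1 imputation can recover them
    downstream; they are returned in ``dropped`` with the reason.
    """
    table = table.sort_values(_SERIES + ["bin"]).reset_index(drop=True)
    zcol = np.full(len(table), np.nan)
    stats_rows = []
    dropped: list[tuple] = []
    ref_mask = table["bin"] < design.n_reference_bins
    for key, idx in table.groupby(_SERIES, sort=False).indices.items():
        x = table["intensity"].to_numpy()[idx]
        ref = x[ref_mask.to_numpy()[idx]]
        try:
            z, mu, sd = baseline_zscore_series(x, ref)
        except ValueError as e:
            dropped.append((*key, str(e)))
            continue
        zcol[idx] = z
        stats_rows.append((*key, mu, sd, int(np.isfinite(ref).sum())))
    ztable = table.copy()
    ztable["z"] = zcol
    stats = pd.DataFrame(
        stats_rows, columns=_SERIES + ["ref_mean", "ref_sd", "n_ref"]
    )
    if dropped:
        log.info("baseline z-score: %d series with degenerate reference", len(dropped))
    return ztable, stats, dropped


# ---------------------------------------------------------------------------
# 3. outlier rule
# ---------------------------------------------------------------------------

def flag_outliers(z: np.ndarray, factor: float = 5.0) -> list[int]:
    """Indices i with |z_i| > factor * max_{j != i} |z_j| (finite entries only).

    At most one index can satisfy the rule in a series of >= 2 values.
    """
    finite = np.flatnonzero(np.isfinite(z))
    if len(finite) < 2:
        if len(finite) == 1:
            log.warning("outlier rule on length-1 series: nothing to compare")
        return []
    a = np.abs(z[finite])
    order = np.argsort(a)
    top, second = finite[order[-1]], a[order[-2]]
    if np.abs(z[top]) > factor * second:
        return [int(top)]
    return []


def flag_outliers_table(
    ztable: pd.DataFrame, factor: float = 5.0
) -> tuple[pd.DataFrame, list[tuple]]:
    """Apply the outlier rule per series on 15-min z-scores; flagged -> missing."""
    ztable = ztable.reset_index(drop=True)
    flagged: list[tuple] = []
    zvals = ztable["z"].to_numpy().copy()
    for key, idx in ztable.groupby(_SERIES, sort=False).indices.items():
        for local in flag_outliers(zvals[idx], factor):
            row = ztable.iloc[idx[local]]
            flagged.append((*key, int(row["bin"])))
            zvals[idx[local]] = np.nan
    out = ztable.copy()
    out["z"] = zvals
    return out, flagged


# ---------------------------------------------------------------------------
# 4. wrong-state exclusion
# ---------------------------------------------------------------------------

def wrong_state_filter(
    ztable: pd.DataFrame,
    wake: pd.DataFrame,
    design: StudyDesign,
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, list[tuple[str, int]]]:
    """Remove bins whose observed state contradicts the schedule.

    A sleep-scheduled bin with wake fraction strictly above ``threshold``,
    or a wake-scheduled bin with sleep fraction strictly above it, is set
    missing.  Reference bins (treadmill) are exempt.  Missing wake fractions
    for any experimental bin present in the table raise IntegrityError.
    """
    wake_idx = wake.set_index(["mouse", "bin"])["wake_fraction"]
    mouse_group = ztable.drop_duplicates("mouse").set_index("mouse")["group"]
    discarded: list[tuple[str, int]] = []
    bad_bins: set[tuple[str, int]] = set()
    for mouse, grp in mouse_group.items():
        bins = ztable.loc[ztable["mouse"] == mouse, "bin"].unique()
        for b in bins:
            b = int(b)
            if design.is_reference_bin(b):
                continue
            try:
                frac = float(wake_idx.loc[(mouse, b)])
            except KeyError:
                raise IntegrityError(f"no wake fraction for mouse {mouse} bin {b}")
            sched = design.scheduled_state(grp, b)
            wrong = frac > threshold if sched == SLEEP else (1 - frac) > threshold
            if wrong:
                bad_bins.add((mouse, b))
                discarded.append((mouse, b))
    out = ztable.copy()
    mask = out.set_index(["mouse", "bin"]).index.isin(bad_bins)
    out.loc[mask, "z"] = np.nan
    return out, discarded


# ---------------------------------------------------------------------------
# 5. coarse-graining
# ---------------------------------------------------------------------------

def coarse_grain(
    ztable: pd.DataFrame,
    design: StudyDesign,
    factor: int | None = None,
) -> pd.DataFrame:
    """Average consecutive blocks of ``factor`` post-reference bins into hours.

    The hour value is the mean of the non-missing block members; it is
    missing iff all members are missing.  Reference bins are consumed by the
    z-scoring step and excluded here.
    """
    factor = factor or design.coarse_factor
    n_exp = design.bins_per_mouse - design.n_reference_bins
    if n_exp % factor:
        raise IntegrityError(
            f"{n_exp} experimental bins do not divide into blocks of {factor}"
        )
    exp = ztable[ztable["bin"] >= design.n_reference_bins].copy()
    exp["hour"] = (exp["bin"] - design.n_reference_bins) // factor + 1
    hourly = (
        exp.groupby(["mouse", "group", "region", "analyte", "hour"], sort=True)["z"]
        .mean()  # NaN iff all members NaN
        .reset_index()
    )
    hourly["provenance"] = np.where(hourly["z"].notna(), OBSERVED, MISSING)
    return hourly


# ---------------------------------------------------------------------------
# 6. imputation
# ---------------------------------------------------------------------------

def impute(zm: ZMatrix, knn_k: int = 2) -> ZMatrix:
    """Fill missing hourly cells; two tiers, provenance recorded.

    Tier 1 (wholly missing series): each hour takes the mean observed z of
    the other mice in the same (group, region, analyte, hour).  Tier 2
    (point gaps): mean of the ``knn_k`` nearest originally-observed hours of
    the same series (ties broken toward the earlier hour; one-sided at the
    edges; a single observed hour is copied).  Tier-2 neighbours never
    include imputed values, so no imputation chains.
    """
    df = zm.data.copy().sort_values(
        ["mouse", "group", "region", "analyte", "hour"]
    ).reset_index(drop=True)
    observed_mask = df["provenance"] == OBSERVED

    # condition means from originally observed values only
    donor = df[observed_mask]
    cond_mean = donor.groupby(["group", "region", "analyte", "hour"])["z"].mean()

    n_tier1 = n_tier2 = 0
    failures: list[tuple] = []
    z = df["z"].to_numpy().copy()
    prov = df["provenance"].to_numpy(dtype=object).copy()

    for key, idx in df.groupby(
        ["mouse", "group", "region", "analyte"], sort=False
    ).indices.items():
        mouse, grp, region, analyte = key
        sub_obs = observed_mask.to_numpy()[idx]
        hours = df["hour"].to_numpy()[idx]
        if not sub_obs.any():
            # tier 1: whole series from condition means
            for j, h in zip(idx, hours):
                try:
                    val = cond_mean.loc[(grp, region, analyte, int(h))]
                except KeyError:
                    failures.append((mouse, region, analyte, int(h)))
                    continue
                if np.isnan(val):
                    failures.append((mouse, region, analyte, int(h)))
                    continue
                z[j] = val
                prov[j] = TIER1
                n_tier1 += 1
            continue
        # tier 2: point gaps from nearest originally-observed hours
        obs_hours = hours[sub_obs]
        obs_vals = z[idx][sub_obs]
        for j, h in zip(idx, hours):
            if not np.isnan(z[j]):
                continue
            dist = np.abs(obs_hours - h)
            order = np.lexsort((obs_hours, dist))
            take = order[: min(knn_k, len(order))]
            z[j] = float(np.mean(obs_vals[take]))
            prov[j] = TIER2
            n_tier2 += 1

    if failures:
        raise IntegrityError(
            f"{len(failures)} cells imputable by neither tier, e.g. {failures[:5]}"
        )
    out = df.copy()
    out["z"] = z
    out["provenance"] = prov
    audit = dict(zm.audit)
    audit.update(
        {
            "imputed_tier1": n_tier1,
            "imputed_tier2": n_tier2,
            "imputed_total": n_tier1 + n_tier2,
            "total_cells": len(out),
            "imputed_fraction": (n_tier1 + n_tier2) / len(out) if len(out) else 0.0,
        }
    )
    return ZMatrix(data=out, baseline_stats=zm.baseline_stats, audit=audit)


# ---------------------------------------------------------------------------
# driver + heatmap
# ---------------------------------------------------------------------------

def preprocess(
    table: pd.DataFrame,
    wake: pd.DataFrame,
    design: StudyDesign,
    min_mice: int = 3,
    outlier_factor: float = 5.0,
    wrong_state_threshold: float = 0.5,
    coarse_factor: int | None = None,
    knn_k: int = 2,
) -> ZMatrix:
    """Run the full ladder and return a complete hourly ZMatrix with audit."""
    retained = detection_filter(table, min_mice)
    table = apply_detection_filter(table, retained)
    ztable, stats, dropped = baseline_zscore(table, design)
    ztable, flagged = flag_outliers_table(ztable, outlier_factor)
    ztable, discarded = wrong_state_filter(
        ztable, wake, design, wrong_state_threshold
    )
    hourly = coarse_grain(ztable, design, coarse_factor)
    zm = ZMatrix(
        data=hourly,
        baseline_stats=stats,
        audit={
            "retained_analytes": {r: len(a) for r, a in retained.items()},
            "dropped_series": len(dropped),
            "flagged_outliers": len(flagged),
            "flagged_outlier_coords": flagged,
            "discarded_bins": len(discarded),
            "raw_observations": int(table["intensity"].notna().sum()),
        },
    )
    zm = impute(zm, knn_k)
    log.info(
        "preprocess: %d hourly cells, %.1f%% imputed",
        zm.audit["total_cells"], 100 * zm.audit["imputed_fraction"],
    )
    return zm


def heatmap_matrix(
    zm: ZMatrix,
    group_a: str,
    group_b: str,
    hours: range | list[int] = range(1, 7),
    region: str | None = None,
) -> pd.DataFrame:
    """Analyte x hour matrix of mean-z differences (group_a minus group_b)."""
    df = zm.data
    if region is not None:
        df = df[df["region"] == region]
    df = df[df["hour"].isin(list(hours))]
    a = df[df["group"] == group_a]
    b = df[df["group"] == group_b]
    common = sorted(set(a["analyte"]) & set(b["analyte"]))
    if not common:
        raise SchemaError("groups share no analytes")
    ma = a.groupby(["analyte", "hour"])["z"].mean().unstack("hour")
    mb = b.groupby(["analyte", "hour"])["z"].mean().unstack("hour")
    return (ma.loc[common] - mb.loc[common]).sort_index()


# ---------------------------------------------------------------------------
# bookkeeping audits (design-arithmetic helpers)
# ---------------------------------------------------------------------------

def expected_sample_count(design: StudyDesign, n_missing_samples: int = 0) -> int:
    """Planned dialysate sample count: mice x regions x bins minus losses."""
    total = design.n_mice * len(design.regions) * design.bins_per_mouse
    return total - n_missing_samples


def imputed_cell_identity(
    n_missing_series: int, n_hours: int, n_missing_points: int, n_outliers: int
) -> int:
    """Cells filled by imputation: series x hours + point gaps + outliers."""
    return n_missing_series * n_hours + n_missing_points + n_outliers


def hourly_cell_count(
    n_mice: int, analytes_per_region: dict[str, int], n_hours: int
) -> int:
    """Denominator of the imputed fraction: mice x retained analytes x hours,
    summed over regions."""
    return n_mice * sum(analytes_per_region.values()) * n_hours
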