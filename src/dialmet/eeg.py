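"""Correlations between metabolite levels and EEG band power.

Per analyte and region, hourly metabolite levels (log-transformed after a
min-shift, since hourly values are z-scores and can be negative) are paired
with hourly band power over pooled mouse-hour observations inside a state
window: 2-6 Hz wake activity across the 6 enforced-wakefulness hours, slow
wave activity (SWA, 0.5-4 Hz) across the 3 recovery-sleep hours.  Pearson's
r with a two-sided p-value is reported per (analyte, region) and each band's
family of tests is controlled with the Benjamini-Hochberg step-up procedure.
A gamma-band (40-100 Hz) run of the same machinery serves as a negative
control: with no planted coupling the pass count should track the nominal
false discovery rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import BAND_GAMMA, BAND_LOW, BAND_SWA, StudyDesign, log
from .lme import group_roles
from .preprocess import ZMatrix


def default_windows(design: StudyDesign) -> dict[str, tuple[str, list[int]]]:
    """Band -> (group, hours) analysis windows for the standard design.

    2-6 Hz during the 6 h of enforced wakefulness, SWA during the 3 h of
    recovery sleep (both in the wake-then-sleep arm), gamma over the wake
    window as a null check.
    """
    roles = group_roles(design)
    ews = roles["wake_sleep"]
    return {
        BAND_LOW: (ews, list(range(1, 7))),
        BAND_SWA: (ews, list(range(7, 10))),
        BAND_GAMMA: (ews, list(range(1, 7))),
    }


def _log_shift(values: np.ndarray) -> np.ndarray:
    return np.log(values - np.nanmin(values) + 1.0)


def correlate_band(
    zm: ZMatrix,
    band_power: pd.DataFrame,
    band: str,
    window: tuple[str, list[int]],
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson r/p per (analyte, region) over pooled mouse-hour pairs.

    Records with zero variance in either vector (or too few pairs) carry
    r = NaN and ``excluded = True``; they are left out of the BH family.
    """
    group, hours = window
    bp = band_power[band_power["band"] == band].set_index(["mouse", "hour"])["power"]
    df = zm.data[
        (zm.data["group"] == group)
        & (zm.data["hour"].isin(hours))
        & (zm.data["provenance"] == "observed")  # imputed cells are copies
    ]
    rows = []
    for (analyte, region), sub in df.groupby(["analyte", "region"], sort=True):
        sub = sub.dropna(subset=["z"])
        pairs = [
            (float(z), float(bp.loc[(m, int(h))]))
            for m, h, z in zip(sub["mouse"], sub["hour"], sub["z"])
            if (m, int(h)) in bp.index
        ]
        rec = {
            "analyte": analyte,
            "region": region,
            "band": band,
            "n": len(pairs),
            "r": np.nan,
            "p": np.nan,
            "excluded": True,
        }
        if len(pairs) >= min_pairs:
            level = _log_shift(np.array([p[0] for p in pairs]))
            power = np.array([p[1] for p in pairs])
            if np.std(level) > 0 and np.std(power) > 0:
                r, p = stats.pearsonr(level, power)
                rec.update(r=float(r), p=float(p), excluded=False)
        rows.append(rec)
    out = pd.DataFrame(rows)
    log.info(
        "correlate %s on %s hours %s: %d records (%d excluded)",
        band, group, hours, len(out), int(out["excluded"].sum()),
    )
    return out


def bh_correct(records: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up at level q over one band's family.

    The family is all non-excluded records passed in (one band across
    analytes and regions).  Adds a boolean ``q_pass`` column.
    """
    out = records.copy()
    out["q_pass"] = False
    mask = ~out["excluded"] & out["p"].notna()
    if mask.sum() == 0:
        return out
    reject, *_ = multipletests(out.loc[mask, "p"], alpha=q, method="fdr_bh")
    out.loc[mask, "q_pass"] = reject
    return out


def gamma_null_check(
    zm: ZMatrix,
    band_power: pd.DataFrame,
    window: tuple[str, list[int]],
    q: float = 0.05,
) -> pd.DataFrame:
    """Run the same machinery on the gamma band (negative control)."""
    return bh_correct(correlate_band(zm, band_power, BAND_GAMMA, window), q)


def correlation_report(
    zm: ZMatrix,
    band_power: pd.DataFrame,
    design: StudyDesign,
    analytes: list[str] | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Two-band (2-6 Hz wake, SWA recovery) correlation table with BH flags."""
    windows = default_windows(design)
    sub = zm
    if analytes is not None:
        sub = ZMatrix(
            data=zm.data[zm.data["analyte"].isin(analytes)],
            baseline_stats=zm.baseline_stats,
            audit=zm.audit,
        )
    parts = []
    for band in (BAND_LOW, BAND_SWA):
        rec = correlate_band(sub, band_power, band, windows[band])
        parts.append(bh_correct(rec, q))
    return pd.concat(parts, ignore_index=True)
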