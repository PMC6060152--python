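"""Preprocessing ladder: filters, z-scoring, coarse-graining, imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dialmet as dm
from dialmet.preprocess import (
    MISSING,
    OBSERVED,
    ParameterError,
    ZMatrix,
    baseline_zscore_series,
    coarse_grain,
    detection_filter,
    expected_sample_count,
    flag_outliers,
    heatmap_matrix,
    hourly_cell_count,
    imputed_cell_identity,
    impute,
    wrong_state_filter,
)


# ---------------------------------------------------------------------------
# detection filter
# ---------------------------------------------------------------------------

def _presence_table(pattern):
    """pattern: {(region, analyte, group): n observed mice}."""
    rows = []
    for (region, analyte, group), n in pattern.items():
        for i in range(n):
            rows.append((f"{group}-m{i}", group, region, analyte, 0, 1.0))
    return pd.DataFrame(
        rows, columns=["mouse", "group", "region", "analyte", "bin", "intensity"]
    )


def test_detection_filter_threshold():
    """An analyte seen in only 2 mice of one condition is excluded there,
    even if every mouse of the other conditions has it."""
    pattern = {}
    for g in ("S6-EW3", "EW6-S3", "SW6-EW3"):
        pattern[("mPFC", "good", g)] = 3
        pattern[("mPFC", "weak", g)] = 6
    pattern[("mPFC", "weak", "EW6-S3")] = 2
    table = _presence_table(pattern)
    kept = detection_filter(table, min_mice=3)
    assert kept["mPFC"] == ["good"]


def test_detection_filter_matches_brute_force(cohort):
    table, *_ = cohort
    kept = detection_filter(table, min_mice=3)
    obs = table[table["intensity"].notna()]
    for region in table["region"].unique():
        expected = []
        for analyte in sorted(table["analyte"].unique()):
            sub = obs[(obs["region"] == region) & (obs["analyte"] == analyte)]
            counts = [
                sub[sub["group"] == g]["mouse"].nunique()
                for g in table["group"].unique()
            ]
            if min(counts) >= 3:
                expected.append(analyte)
        assert kept[region] == expected


def test_detection_filter_min_mice_bound(cohort):
    table, *_ = cohort
    with pytest.raises(ParameterError):
        detection_filter(table, min_mice=10)


# ---------------------------------------------------------------------------
# baseline z-scores
# ---------------------------------------------------------------------------

def test_zscore_at_reference_mean_is_zero():
    x = np.array([2.0, 2.0, 2.0, 2.0, 2.0, 5.0])
    ref = np.array([1.0, 2.0, 3.0])
    z, mu, sd = baseline_zscore_series(x, ref)
    assert mu == 2.0
    np.testing.assert_allclose(z[:5], 0.0)


def test_zscore_degenerate_reference():
    with pytest.raises(ValueError):
        baseline_zscore_series(np.ones(5), np.array([1.0, 1.0, 1.0, 1.0, 1.0]))
    with pytest.raises(ValueError):
        baseline_zscore_series(np.ones(5), np.array([1.0, np.nan, np.nan]))


def test_zscore_matches_two_pass_oracle(rng):
    """Independent two-pass mean/sd computation agrees to 1e-12."""
    x = rng.lognormal(5, 0.4, size=41)
    ref = x[:5]
    z, mu, sd = baseline_zscore_series(x, ref)
    mu2 = sum(ref) / len(ref)
    sd2 = (sum((v - mu2) ** 2 for v in ref) / (len(ref) - 1)) ** 0.5
    np.testing.assert_allclose(z, (x - mu2) / sd2, atol=1e-12)


@given(
    shift=st.floats(-50, 50),
    scale=st.floats(0.01, 100),
    seed=st.integers(0, 10_000),
)
@settings(max_examples=50, deadline=None)
def test_zscore_affine_invariance(shift, scale, seed):
    """Adding a constant to series and baseline, or scaling both by c > 0,
    leaves the z-scores unchanged."""
    r = np.random.default_rng(seed)
    x = r.normal(10, 2, size=20)
    ref = x[:5]
    z0, *_ = baseline_zscore_series(x, ref)
    z1, *_ = baseline_zscore_series(x + shift, ref + shift)
    z2, *_ = baseline_zscore_series(x * scale, ref * scale)
    np.testing.assert_allclose(z1, z0, atol=1e-7)
    np.testing.assert_allclose(z2, z0, atol=1e-7)


# ---------------------------------------------------------------------------
# outlier rule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "z, expected",
    [
        ([1.0, 1.0, 1.0, 10.0], [3]),   # 10 > 5 * 1
        ([1.0, 1.0, 1.0, 4.0], []),     # 4 <= 5 * 1
        ([2.0, 2.0, 2.0], []),          # constant series
        ([-8.0, 1.0, 1.0], [0]),        # rule is on |z|
        ([np.nan, 1.0, 10.0], [2]),
    ],
)
def test_flag_outliers_rule(z, expected):
    assert flag_outliers(np.array(z), factor=5.0) == expected


# ---------------------------------------------------------------------------
# wrong-state exclusion
# ---------------------------------------------------------------------------

def _one_mouse_ztable(design, group="S6-EW3", mouse="m01"):
    rows = [
        (mouse, group, "mPFC", "A01", b, 0.0)
        for b in range(design.bins_per_mouse)
    ]
    return pd.DataFrame(
        rows, columns=["mouse", "group", "region", "analyte", "bin", "z"]
    )


def test_wrong_state_boundaries(design):
    """Sleep-scheduled bin at fraction 0.6 discarded, at exactly 0.5
    retained (strict inequality); wake-scheduled bin at 0.2 discarded."""
    zt = _one_mouse_ztable(design, "S6-EW3")
    wake = pd.DataFrame(
        {
            "mouse": "m01",
            "bin": range(design.bins_per_mouse),
            "wake_fraction": [1.0] * 5 + [0.0] * 36,
        }
    )
    wake.loc[wake["bin"] == 6, "wake_fraction"] = 0.6
    wake.loc[wake["bin"] == 7, "wake_fraction"] = 0.5
    out, discarded = wrong_state_filter(zt, wake, design)
    assert ("m01", 6) in discarded
    assert ("m01", 7) not in discarded
    assert np.isnan(out.loc[out["bin"] == 6, "z"]).all()

    # wake-scheduled (SW6 arm): mostly-asleep bin discarded symmetrically
    zt2 = _one_mouse_ztable(design, "SW6-EW3", "m14")
    wake2 = pd.DataFrame(
        {
            "mouse": "m14",
            "bin": range(design.bins_per_mouse),
            "wake_fraction": [1.0] * 5 + [0.9] * 36,
        }
    )
    wake2.loc[wake2["bin"] == 10, "wake_fraction"] = 0.2
    _, discarded2 = wrong_state_filter(zt2, wake2, design)
    assert discarded2 == [("m14", 10)]


def test_wrong_state_missing_fraction(design):
    zt = _one_mouse_ztable(design)
    wake = pd.DataFrame({"mouse": ["m01"], "bin": [0], "wake_fraction": [1.0]})
    with pytest.raises(dm.IntegrityError):
        wrong_state_filter(zt, wake, design)


# ---------------------------------------------------------------------------
# coarse-graining
# ---------------------------------------------------------------------------

def test_coarse_grain_blocks(design):
    zt = _one_mouse_ztable(design)
    zvals = np.full(41, np.nan)
    zvals[5:9] = [1.0, 2.0, 3.0, 4.0]       # hour 1 -> 2.5
    zvals[9:13] = [1.0, np.nan, 3.0, np.nan]  # hour 2 -> 2.0 (partial block)
    zt["z"] = zvals
    hourly = coarse_grain(zt, design)
    assert len(hourly) == design.n_hours == 9
    h = hourly.set_index("hour")["z"]
    assert h.loc[1] == 2.5
    assert h.loc[2] == 2.0
    assert np.isnan(h.loc[3])
    assert (hourly.set_index("hour")["provenance"].loc[3]) == MISSING


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def _zm_from_rows(rows):
    df = pd.DataFrame(
        rows, columns=["mouse", "group", "region", "analyte", "hour", "z"]
    )
    df["provenance"] = np.where(df["z"].notna(), OBSERVED, MISSING)
    return ZMatrix(data=df, baseline_stats=pd.DataFrame())


def test_impute_two_neighbor_mean():
    rows = [("m1", "G", "R", "A", h, v) for h, v in
            [(4, 1.0), (5, np.nan), (6, 3.0)]]
    zm = impute(_zm_from_rows(rows))
    cell = zm.data[(zm.data["hour"] == 5)]
    assert cell["z"].iloc[0] == 2.0
    assert cell["provenance"].iloc[0] == "imputed_tier2"


def test_impute_edge_uses_one_side():
    rows = [("m1", "G", "R", "A", h, v) for h, v in
            [(1, np.nan), (2, 2.0), (3, 6.0), (4, 10.0)]]
    zm = impute(_zm_from_rows(rows))
    assert zm.data.set_index("hour")["z"].loc[1] == 4.0  # mean of hours 2, 3


def test_impute_tier1_condition_mean():
    rows = []
    vals = [0.1, 0.2, 0.3, 0.4, 0.5]
    for i, v in enumerate(vals):
        rows.append((f"d{i}", "G", "R", "A", 3, v))
    rows.append(("m1", "G", "R", "A", 3, np.nan))
    zm = impute(_zm_from_rows(rows))
    cell = zm.data[zm.data["mouse"] == "m1"]
    np.testing.assert_allclose(cell["z"].iloc[0], 0.3)
    assert cell["provenance"].iloc[0] == "imputed_tier1"


def test_impute_neither_tier_errors():
    rows = [("m1", "G", "R", "A", 3, np.nan)]
    with pytest.raises(dm.IntegrityError):
        impute(_zm_from_rows(rows))


def test_impute_idempotent(zmatrix):
    again = impute(zmatrix)
    pd.testing.assert_frame_equal(again.data, zmatrix.data)


def test_imputed_fraction_matches_recount(zmatrix):
    data = zmatrix.data
    n_imputed = int(data["provenance"].str.startswith("imputed").sum())
    assert zmatrix.audit["imputed_total"] == n_imputed
    assert zmatrix.audit["total_cells"] == len(data)
    assert zmatrix.audit["imputed_fraction"] == pytest.approx(
        n_imputed / len(data)
    )
    assert not data["z"].isna().any()


# ---------------------------------------------------------------------------
# heatmap matrix
# ---------------------------------------------------------------------------

def test_heatmap_antisymmetry_and_zero(zmatrix, cohort):
    _, _, _, truth = cohort
    ab = heatmap_matrix(zmatrix, "EW6-S3", "S6-EW3")
    ba = heatmap_matrix(zmatrix, "S6-EW3", "EW6-S3")
    pd.testing.assert_frame_equal(ab, -ba)
    same = heatmap_matrix(zmatrix, "EW6-S3", "EW6-S3")
    assert (same.abs() < 1e-12).all().all()


def test_heatmap_wake_rows_increase(zmatrix, cohort):
    """Wake-upregulated analytes show an increasing wake-minus-sleep
    difference across hours 1-6."""
    _, _, _, truth = cohort
    hm = heatmap_matrix(zmatrix, "EW6-S3", "S6-EW3")
    for a in truth.state_dependent:
        if a in hm.index:
            row = hm.loc[a]
            assert row.iloc[-1] > row.iloc[0]
            assert np.polyfit(np.arange(len(row)), row.to_numpy(), 1)[0] > 0


# ---------------------------------------------------------------------------
# bookkeeping helpers
# ---------------------------------------------------------------------------

def test_bookkeeping_arithmetic(design):
    assert expected_sample_count(design, 0) == 19 * 2 * 41
    assert expected_sample_count(design, 17) == 1541
    assert imputed_cell_identity(199, 9, 156, 13) == 1960
    assert hourly_cell_count(19, {"mPFC": 36, "M1": 33}, 9) == 11799
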