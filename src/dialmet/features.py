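"""Clustering of unknown LC-MS spectral features into putative analytes.

Two feature observations measure the same unknown analyte when their parent
masses differ by less than ``mass_tol`` (Daltons) and their retention times
by less than ``rt_tol`` (minutes).  That pairwise relation is not transitive,
so clusters are its transitive closure: single-linkage components of the
tolerance graph.  Each cluster is summarized by its median mass and
retention time and converted into a long sample table so the survivors run
through the same preprocessing and mixed-model machinery as known analytes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .config import StudyDesign, log


def cluster_features(
    features: pd.DataFrame, mass_tol: float = 0.0014, rt_tol: float = 0.3
) -> np.ndarray:
    """Single-linkage cluster labels under (|dm| < mass_tol and |drt| < rt_tol).

    Clusters are the connected components of the strict tolerance graph —
    the transitive closure of the pairwise "same feature" relation.  Edges
    are enumerated with a KD-tree on tolerance-scaled coordinates under the
    Chebyshev metric and re-checked against the strict rule, so the result
    is exact and order-independent.  Labels are 0-based, ordered by
    ascending cluster median mass.
    """
    if mass_tol <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")
    n = len(features)
    if n == 0:
        return np.array([], dtype=int)
    mass = features["mass"].to_numpy(dtype=float)
    rt = features["rt"].to_numpy(dtype=float)
    pts = np.column_stack([mass / mass_tol, rt / rt_tol])
    pairs = cKDTree(pts).query_pairs(r=1.0, p=np.inf, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        ok = (np.abs(mass[i] - mass[j]) < mass_tol) & (
            np.abs(rt[i] - rt[j]) < rt_tol
        )
        pairs = pairs[ok]
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, roots = connected_components(graph, directed=False)
    # relabel by median mass for stable, order-independent ids
    med = pd.Series(mass).groupby(roots).median().sort_values()
    remap = {root: k for k, root in enumerate(med.index)}
    return np.array([remap[r] for r in roots], dtype=int)


def cluster_summary(features: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster median mass/rt and observation count."""
    df = features.assign(cluster=labels)
    out = (
        df.groupby("cluster")
        .agg(mass=("mass", "median"), rt=("rt", "median"), n_obs=("mass", "size"))
        .reset_index()
    )
    return out


def features_to_long_table(
    features: pd.DataFrame,
    labels: np.ndarray,
    design: StudyDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a long sample table of per-sample cluster intensities.

    Intensities of multiple features from the same cluster in one sample are
    summed (they are fragments of the same ion count).  Returns the table and
    the cluster summary keyed by analyte id ``U<k>``.
    """
    summary = cluster_summary(features, labels)
    summary["analyte"] = [f"U{k + 1:03d}" for k in summary["cluster"]]
    df = features.assign(analyte=[f"U{k + 1:03d}" for k in labels])
    mouse_groups = _mouse_group_map(design)
    grouped = (
        df.groupby(["mouse", "region", "analyte", "bin"], as_index=False)["intensity"]
        .sum()
    )
    grouped["group"] = grouped["mouse"].map(mouse_groups)
    # complete grid: undetected (mouse, region, analyte, bin) cells are missing
    mice = grouped[["mouse", "group"]].drop_duplicates()
    full = (
        mice.merge(pd.DataFrame({"region": list(design.regions)}), how="cross")
        .merge(pd.DataFrame({"analyte": summary["analyte"]}), how="cross")
        .merge(pd.DataFrame({"bin": range(design.bins_per_mouse)}), how="cross")
    )
    table = full.merge(
        grouped, on=["mouse", "group", "region", "analyte", "bin"], how="left"
    )[["mouse", "group", "region", "analyte", "bin", "intensity"]]
    log.info(
        "clustered %d features into %d unknown analytes",
        len(features), len(summary),
    )
    return table, summary


def _mouse_group_map(design: StudyDesign) -> dict[str, str]:
    ids = design.mouse_ids()
    return {m: g for g, ms in ids.items() for m in ms}


def unknown_pipeline(
    features: pd.DataFrame,
    wake: pd.DataFrame,
    design: StudyDesign,
    config=None,
) -> pd.DataFrame:
    """Cluster unknowns, then apply the known-analyte pipeline and LME verdicts.

    Returns a report keyed by cluster median mass / retention time with the
    three model p-values and the state-specificity verdict, mirroring the
    per-analyte report for known metabolites.
    """
    from .config import RunConfig
    from .lme import state_specificity_report
    from .preprocess import preprocess

    config = config or RunConfig()
    if len(features) == 0:
        return pd.DataFrame(
            columns=["mass", "rt", "analyte", "p_between", "p_within_sew",
                     "p_within_ews", "state_specific"]
        )
    labels = cluster_features(features, config.mass_tol, config.rt_tol)
    table, summary = features_to_long_table(features, labels, design)
    zm = preprocess(
        table, wake, design,
        min_mice=config.min_mice,
        outlier_factor=config.outlier_factor,
        wrong_state_threshold=config.wrong_state_threshold,
        knn_k=config.knn_k,
    )
    report = state_specificity_report(zm, design, config=config)
    out = report.merge(
        summary[["analyte", "mass", "rt"]], on="analyte", how="left"
    )
    cols = ["mass", "rt", "analyte"] + [
        c for c in report.columns if c != "analyte"
    ]
    return out[cols]
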