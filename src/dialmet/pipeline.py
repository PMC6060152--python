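"""End-to-end pipeline: preprocess -> cluster -> LME -> classify -> correlate.

Every stage writes a tidy TSV under the output directory and contributes a
block to ``summary.json``.  With a fixed seed the whole run is
deterministic: the deterministic stages are bit-for-bit reproducible and
the stochastic stages (CV, permutations) consume seeded RNG streams.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import tables
from .classify import build_feature_matrix, classify_conditions, \
    fit_plsda, pairwise_comparisons, vip_table
from .config import RunConfig, StudyDesign, default_design, log
from .eeg import correlation_report
from .features import unknown_pipeline
from .lme import sleep_phase_report, state_specificity_report
from .preprocess import heatmap_matrix, preprocess


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    design: StudyDesign | None = None,
) -> dict:
    """Run all stages named in the config's inputs; returns the summary dict.

    ``config.inputs`` keys: ``samples`` (required), ``wake`` (required),
    ``band_power`` (optional; correlation skipped with a warning if absent),
    ``features`` (optional; unknown-feature stage skipped if absent).
    """
    design = design or default_design()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as e:  # noqa: BLE001 - tag and abort
            raise StageError(name, e) from e

    samples = _stage(
        "read", lambda: tables.read_long_table(config.inputs["samples"], design)
    )
    wake = _stage(
        "read", lambda: tables.read_wake_fractions(config.inputs["wake"])
    )

    # ---- preprocess -------------------------------------------------------
    def _pre():
        zm = preprocess(
            samples, wake, design,
            min_mice=config.min_mice,
            outlier_factor=config.outlier_factor,
            wrong_state_threshold=config.wrong_state_threshold,
            coarse_factor=config.coarse_factor,
            knn_k=config.knn_k,
        )
        zm.data.to_csv(outdir / "zmatrix.tsv", sep="\t", index=False)
        groups = design.group_names
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                hm = heatmap_matrix(zm, a, b)
                hm.to_csv(outdir / f"heatmap_{a}_vs_{b}.tsv", sep="\t")
        return zm

    zm = _stage("preprocess", _pre)
    audit = dict(zm.audit)
    audit.pop("flagged_outlier_coords", None)
    summary["preprocess"] = audit

    # ---- unknown-feature clustering --------------------------------------
    def _cluster():
        if "features" not in config.inputs:
            return None
        feats = tables.read_features(config.inputs["features"])
        report = unknown_pipeline(feats, wake, design, config)
        report.to_csv(outdir / "unknown_features.tsv", sep="\t", index=False)
        return {
            "n_features": len(feats),
            "n_clusters_reported": int(report["analyte"].nunique()),
            "n_state_specific": int(
                (report["state_specific"] == True).sum()  # noqa: E712
            ),
        }

    cluster_block = _stage("cluster", _cluster)
    summary["clustering"] = cluster_block or {"skipped": True}

    # ---- mixed-effects state testing --------------------------------------
    def _lme():
        report = state_specificity_report(zm, design, config=config)
        report.to_csv(outdir / "state_specificity.tsv", sep="\t", index=False)
        phases = sleep_phase_report(zm, design, config=config)
        phases.to_csv(outdir / "sleep_phases.tsv", sep="\t", index=False)
        return {
            "n_analytes": len(report),
            "n_state_specific": int((report["state_specific"] == True).sum()),  # noqa: E712
            "n_typed_patterns": int((phases["pattern"] != "").sum()),
        }

    summary["lme"] = _stage("lme", _lme)

    # ---- classification ----------------------------------------------------
    def _classify():
        fm = build_feature_matrix(zm)
        rng = np.random.default_rng(config.seed)
        model = fit_plsda(fm.X, fm.y, config.n_components)
        train_acc = float(np.mean(model.predict(fm.X.to_numpy()) == fm.y))
        vt = vip_table(model, list(fm.X.columns))
        vt.to_csv(outdir / "vip.tsv", sep="\t", index=False)
        cv = classify_conditions(fm, config, seed=rng)
        pd.DataFrame({"accuracy": cv.accuracies}).to_csv(
            outdir / "cv_accuracies.tsv", sep="\t", index=False
        )
        pw = pairwise_comparisons(fm, config=config, seed=rng)
        block = {
            "plsda_training_accuracy": train_acc,
            "three_way": {
                "mean_accuracy": cv.mean_accuracy,
                "ci": [cv.ci_low, cv.ci_high],
                "p_value": cv.p_value,
            },
            "pairwise": {
                " vs ".join(pair): {
                    "mean_accuracy": r.mean_accuracy,
                    "ci": [r.ci_low, r.ci_high],
                    "p_value": r.p_value,
                }
                for pair, r in pw.items()
            },
        }
        return block

    summary["classification"] = _stage("classify", _classify)

    # ---- EEG correlation ---------------------------------------------------
    def _correlate():
        if "band_power" not in config.inputs:
            log.warning("no band-power table supplied; correlation stage skipped")
            return {"skipped": True}
        bp = tables.read_band_power(config.inputs["band_power"])
        rep = correlation_report(zm, bp, design, q=config.fdr_q)
        rep.to_csv(outdir / "eeg_correlations.tsv", sep="\t", index=False)
        return {
            "n_tests": int((~rep["excluded"]).sum()),
            "n_pass": int(rep["q_pass"].sum()),
        }

    summary["correlation"] = _stage("correlate", _correlate)

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
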