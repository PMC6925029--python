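"""End-to-end pipeline chaining the stages into one deterministic run.

``run_pipeline`` executes, given a validated configuration:

1. optionally the image chain — simulate frames, segment, compute features,
   classify cells, enumerate to concentration and call positivity;
2. the cohort chain — simulate (or load) a feature-level cohort, apply the
   inclusion rule when enumeration metadata is available, preprocess per
   patient, cluster cells at third-level branching, metacluster at second
   level, and compute per-patient concordance, cohort ICCs and per-feature
   Welch tests.

Every stage logs one structured record with its parameters and in/out counts
so each number in the final report is traceable; re-running with the same
seed yields byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classification as cls
from . import concordance as conc
from . import morphometry as morpho
from . import segmentation as seg
from .io import PipelineConfig, frame_spec_from_config
from .synthetic import CohortSpec, CohortTable, generate_cohort_features, generate_frame

log = logging.getLogger("ctcmorph.pipeline")

__all__ = ["ConcordanceReport", "run_pipeline", "analyze_frame", "analyze_cohort"]


@dataclass
class ConcordanceReport:
    """Cohort-level results of one pipeline run."""

    per_patient_r: dict[str, pd.DataFrame]
    icc: dict[str, float]
    feature_tests: dict[str, pd.DataFrame]
    metacluster_composition: pd.DataFrame
    excluded_patients: dict[str, list[str]] = field(default_factory=dict)
    stage_log: list[dict] = field(default_factory=list)

    def mean_liquid_solid_r(self) -> float:
        values = []
        for r in self.per_patient_r.values():
            if "liquid" in r.index:
                for comp in r.columns:
                    if comp != "liquid" and np.isfinite(r.loc["liquid", comp]):
                        values.append(float(r.loc["liquid", comp]))
        return float(np.mean(values)) if values else float("nan")


def analyze_frame(scene, config: PipelineConfig):
    """Segment, measure and classify one frame; returns (cells, categories).

    The classification background uses the frame's WBC population (identified
    by CD45 against the cell-free image background) for DAPI/CK/CDX2 and the
    image background for CD45.
    """
    seg_result = seg.segment_frame(
        scene.channels,
        min_area_px=config.segmentation.min_area_px,
        fallback_dilation_px=config.segmentation.fallback_dilation_px,
        threshold_method=config.segmentation.threshold_method,
        split_h=config.segmentation.split_h,
    )
    img_bg = morpho.image_background(scene.channels, seg_result.cell_labels)
    features = morpho.features_for_frame(
        scene.channels, seg_result.nuclear_labels, seg_result.cell_labels
    )
    features = morpho.apply_sdom(features, img_bg)
    # provisional WBC set: CD45-positive against the image background
    wbc_rows = features[features["sdom_cd45"] >= config.classifier.t_cd45]
    background = morpho.combined_background(
        scene.channels,
        seg_result.cell_labels,
        [row for _, row in wbc_rows.iterrows()],
    )
    features = morpho.apply_sdom(features, background)
    clf = cls.ClassifierConfig(
        t_ck=config.classifier.t_ck,
        t_cd45=config.classifier.t_cd45,
        size_factor=config.classifier.size_factor,
        solidity_min=config.classifier.solidity_min,
        cdx2_sdom_threshold=config.classifier.cdx2_sdom_threshold,
    )
    wbc_mean_area = float(wbc_rows["nuclear_area"].mean()) if len(wbc_rows) else float("nan")
    categories = {
        int(lab): cls.classify_cell(features.loc[lab], wbc_mean_area, clf)
        for lab in features.index
    }
    groups = seg.find_touching_groups(seg_result.cell_labels)
    categories, group_ids = cls.group_ctcc(categories, groups)
    features = features.copy()
    features["category"] = [categories[int(lab)] for lab in features.index]
    features["ctcc_id"] = [group_ids.get(int(lab)) for lab in features.index]
    features["cdx2_bin"] = [
        cls.bin_cdx2(features.loc[lab, "sdom_cdx2"], clf.cdx2_sdom_threshold)[0]
        for lab in features.index
    ]
    return seg_result, features


def analyze_cohort(
    cohort: CohortTable,
    config: PipelineConfig,
    enumeration: dict[str, dict] | None = None,
) -> tuple[ConcordanceReport, conc.PreprocessedTable, conc.MetaclusterReport]:
    """Cohort-level statistics; ``enumeration`` optionally maps patient ->
    {liquid_count, monolayer_clusters} for the inclusion rule."""
    from .power import check_inclusion

    stage_log: list[dict] = []
    excluded: dict[str, list[str]] = {}
    if enumeration:
        keep = []
        for patient in cohort.patients:
            meta = enumeration.get(patient)
            if meta is None:
                keep.append(patient)
                continue
            decision = check_inclusion(
                meta.get("liquid_count", 0),
                meta.get("monolayer_clusters", 0),
                min_liquid=config.inclusion.min_liquid,
                min_clusters=config.inclusion.min_clusters,
                strict_clusters=config.inclusion.strict_clusters,
            )
            if decision.eligible:
                keep.append(patient)
            else:
                excluded[patient] = decision.reasons
        cohort = CohortTable(
            cohort.data[cohort.data["patient_id"].isin(keep)].reset_index(drop=True)
        )
    stage_log.append(
        {
            "stage": "inclusion",
            "patients_in": len(cohort.patients) + len(excluded),
            "patients_out": len(cohort.patients),
            "excluded": sorted(excluded),
        }
    )
    log.info("inclusion: %s", stage_log[-1])

    table = conc.preprocess_per_patient(cohort)
    stage_log.append(
        {
            "stage": "preprocess",
            "cells": len(table.data),
            "features_kept": len(table.feature_names),
            "features_dropped": sorted({f for v in table.dropped.values() for f in v}),
        }
    )
    log.info("preprocess: %s", stage_log[-1])

    assignment = conc.assign_patient_clusters(
        table,
        level=config.clustering.cell_level,
        metric=config.clustering.metric,
        method=config.clustering.linkage,
    )
    meta_report = conc.metacluster(
        assignment,
        table,
        main_level=config.clustering.meta_level,
        metric=config.clustering.metric,
        method=config.clustering.linkage,
    )
    stage_log.append(
        {
            "stage": "clustering",
            "patient_clusters": int(assignment.labels.nunique()),
            "metaclusters": int(meta_report.main_labels.nunique()),
        }
    )
    log.info("clustering: %s", stage_log[-1])

    per_patient_r = {}
    tests = {}
    for patient in cohort.patients:
        block = cohort.patient_block(patient)
        if block["compartment"].nunique() >= 2:
            per_patient_r[patient] = conc.concordance_r(cohort, patient)
            solids = [c for c in block["compartment"].unique() if c != "liquid"]
            if "liquid" in set(block["compartment"]) and solids:
                tests[patient] = conc.feature_tests(cohort, patient, "liquid", solids)

    # per-cell profile score for grouped (ICC) concordance: first PC of the
    # preprocessed data
    scores, _, _ = conc.pca_embed(table, n_components=1)
    score = pd.Series(scores[:, 0], index=table.data.index)
    patients = table.data["patient_id"]
    is_liquid = table.data["compartment"] == "liquid"
    icc = {
        "all": conc.icc_oneway(score, patients),
        "liquid": conc.icc_oneway(score[is_liquid], patients[is_liquid])
        if is_liquid.any() and patients[is_liquid].nunique() >= 2
        else float("nan"),
        "solid": conc.icc_oneway(score[~is_liquid], patients[~is_liquid])
        if (~is_liquid).any() and patients[~is_liquid].nunique() >= 2
        else float("nan"),
    }
    stage_log.append(
        {"stage": "concordance", "patients_with_r": sorted(per_patient_r), "icc": icc}
    )
    log.info("concordance: %s", stage_log[-1])

    report = ConcordanceReport(
        per_patient_r=per_patient_r,
        icc=icc,
        feature_tests=tests,
        metacluster_composition=meta_report.composition,
        excluded_patients=excluded,
        stage_log=stage_log,
    )
    return report, table, meta_report


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    enumeration: dict[str, dict] | None = None,
) -> ConcordanceReport:
    """Run the configured pipeline and write every report file to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.frames.enabled:
        frame_rows = []
        counts: dict[str, int] = {}
        for i in range(config.frames.n_frames):
            spec = frame_spec_from_config(config.frames, seed=config.seed + i)
            scene = generate_frame(spec)
            _, features = analyze_frame(scene, config)
            features = features.reset_index().assign(frame_id=i)
            frame_rows.append(features)
            for cat, n in features["category"].value_counts().items():
                counts[cat] = counts.get(cat, 0) + int(n)
        cells = pd.concat(frame_rows, ignore_index=True)
        cells.to_csv(out / "frame_cells.csv", index=False)
        hd_count = counts.get("HD-CTC", 0) + counts.get("CTCC-member", 0)
        concentration = cls.enumerate_to_concentration(
            hd_count, config.frames.leukocyte_concentration, config.frames.n_dapi_nuclei
        )
        enumeration_report = {
            "n_cells_by_category": counts,
            "hd_ctc_count": hd_count,
            "leukocyte_concentration": config.frames.leukocyte_concentration,
            "n_dapi_nuclei": config.frames.n_dapi_nuclei,
            "concentration_per_ml": concentration,
            "positive": cls.call_positivity(concentration),
        }
        (out / "enumeration.json").write_text(json.dumps(enumeration_report, indent=1))
        log.info("frames: %s", enumeration_report)

    if config.cohort_csv:
        cohort = CohortTable.from_csv(config.cohort_csv)
    else:
        cohort = generate_cohort_features(
            CohortSpec(
                n_patients=config.cohort.n_patients,
                compartments=tuple(config.cohort.compartments),
                cells_per_compartment=config.cohort.cells_per_compartment,
                n_features=config.cohort.n_features,
                within_sd=config.cohort.within_sd,
                shift_scale=config.cohort.shift_scale,
                target_profile_correlation=config.cohort.target_profile_correlation,
                seed=config.seed,
            )
        )
    cohort.to_csv(out / "cohort.csv")

    report, table, meta_report = analyze_cohort(cohort, config, enumeration)

    clusters = table.data[list(table.data.columns[:4])].copy()
    clusters["cluster"] = conc.assign_patient_clusters(
        table, level=config.clustering.cell_level,
        metric=config.clustering.metric, method=config.clustering.linkage,
    ).labels
    clusters.to_csv(out / "clusters.csv", index=False)
    meta_report.composition.to_csv(out / "metacluster_composition.csv")

    concordance_json = {
        "per_patient_r": {
            p: r.round(6).to_dict() for p, r in report.per_patient_r.items()
        },
        "mean_liquid_solid_r": report.mean_liquid_solid_r(),
        "icc": report.icc,
        "excluded_patients": report.excluded_patients,
        "stage_log": report.stage_log,
    }
    (out / "concordance.json").write_text(
        json.dumps(concordance_json, indent=1, default=float)
    )
    if report.feature_tests:
        pd.concat(
            {p: t for p, t in report.feature_tests.items()}, names=["patient_id"]
        ).to_csv(out / "feature_tests.csv")

    if config.figures:
        _write_figures(table, meta_report, out)
    return report


def _write_figures(table, meta_report, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores, evr, _ = conc.pca_embed(table, n_components=2)
    fig, ax = plt.subplots(figsize=(5, 4))
    for comp, marker in (("liquid", "o"), ("metastasis", "s"), ("primary", "^")):
        sel = (table.data["compartment"] == comp).to_numpy()
        if sel.any():
            ax.scatter(scores[sel, 0], scores[sel, 1], s=8, alpha=0.6, label=comp, marker=marker)
    ax.set_xlabel(f"PC1 ({evr[0]:.0%})")
    ax.set_ylabel(f"PC2 ({evr[1]:.0%})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "pca.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    means = meta_report.cluster_means
    im = ax.imshow(means.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
    ax.set_yticks(range(len(means.index)), means.index, fontsize=5)
    ax.set_xlabel("features")
    fig.colorbar(im, ax=ax, label="scaled mean")
    fig.tight_layout()
    fig.savefig(out / "metacluster_heatmap.png", dpi=120)
    plt.close(fig)
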