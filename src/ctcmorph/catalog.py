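"""Canonical single-cell morphometric feature catalogue.

The catalogue enumerates every feature the morphometry stage computes for a
segmented cell: shape descriptors of the nuclear and whole-cell masks,
per-channel intensity statistics on three regions (nucleus, cytoplasm, whole
cell), three intensity-distribution descriptors per channel on the whole-cell
mask, and the per-channel SDOM (standard deviations over the mean of the
surrounding-leukocyte background). Column names are stable and shared by the
synthetic cohort generator, the CSV emitters and the statistics stages.
"""

from __future__ import annotations

CHANNELS: tuple[str, ...] = ("dapi", "ck", "cd45", "cdx2")
REGIONS: tuple[str, ...] = ("nucleus", "cytoplasm", "cell")
INTENSITY_STATS: tuple[str, ...] = ("mean", "sd", "cv", "integrated", "max")

SHAPE_FEATURES: tuple[str, ...] = (
    "nuclear_area",
    "cell_area",
    "cytoplasm_area",
    "nuclear_perimeter",
    "cell_perimeter",
    "nuclear_roundness",
    "cell_roundness",
    "nc_ratio",
    "nuclear_eccentricity",
    "cell_eccentricity",
    "nuclear_solidity",
)

DISTRIBUTION_STATS: tuple[str, ...] = ("heterogeneity", "margination", "clumpiness")


def intensity_feature_names() -> list[str]:
    return [
        f"{stat}_{channel}_{region}"
        for channel in CHANNELS
        for region in REGIONS
        for stat in INTENSITY_STATS
    ]


def distribution_feature_names() -> list[str]:
    return [f"{stat}_{channel}" for channel in CHANNELS for stat in DISTRIBUTION_STATS]


def sdom_feature_names() -> list[str]:
    return [f"sdom_{channel}" for channel in CHANNELS]


FEATURE_CATALOG: tuple[str, ...] = tuple(
    list(SHAPE_FEATURES)
    + intensity_feature_names()
    + distribution_feature_names()
    + sdom_feature_names()
)

#: Mandatory leading annotation columns of every cohort table.
ANNOTATION_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "compartment",
    "cell_id",
    "category_truth",
)


def feature_names(n_features: int) -> list[str]:
    """Return ``n_features`` stable feature column names.

    The first ``len(FEATURE_CATALOG)`` names reuse the morphometry catalogue so
    synthetic cohorts mirror real feature tables; any excess is padded with
    generic ``f###`` names (used by wide simulation studies).
    """
    if n_features <= len(FEATURE_CATALOG):
        return list(FEATURE_CATALOG[:n_features])
    pad = [f"f{i:03d}" for i in range(len(FEATURE_CATALOG), n_features)]
    return list(FEATURE_CATALOG) + pad
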