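"""Rule-based rare-cell classification, CDX2 binning and enumeration.

Cells are assigned to the standard high-definition single-cell assay
categories by an explicit decision ladder on marker SDOMs and nuclear size
relative to the surrounding white blood cells:

1. CD45 SDOM >= ``t_cd45``                            -> WBC
2. CK SDOM >= ``t_ck`` and nucleus larger than ``size_factor`` x the WBC mean
   nuclear area: intact nucleus (solidity >= cutoff)  -> HD-CTC,
   fragmented / low-solidity nucleus                  -> Apoptotic-like
3. CK SDOM >= ``t_ck``, nucleus not larger            -> CTC-Small
4. CK and CD45 both negative, nucleus larger          -> CTC-LowCK
5. otherwise                                          -> FalsePositive

HD-CTCs whose cell masks form a touching group of two or more are relabelled
CTCC members (CTC clusters). Only the CDX2 positivity guide value (SDOM 5) is
assay-calibrated; the CK/CD45 thresholds and the size factor are package
defaults, config-exposed and flagged as uncalibrated. An analyst override may
flip a CDX2 bin; it is recorded with ``override_flag``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import math

__all__ = [
    "CATEGORIES",
    "ClassifierConfig",
    "MissingFeatureError",
    "classify_cell",
    "bin_cdx2",
    "group_ctcc",
    "enumerate_to_concentration",
    "call_positivity",
]

CATEGORIES: tuple[str, ...] = (
    "HD-CTC",
    "CTCC-member",
    "CTC-Small",
    "CTC-LowCK",
    "Apoptotic-like",
    "WBC",
    "FalsePositive",
)


class MissingFeatureError(ValueError):
    """A feature required by the decision ladder is missing for a cell."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision-ladder thresholds (uncalibrated package defaults except the
    CDX2 guide value of 5)."""

    t_ck: float = 5.0
    t_cd45: float = 3.0
    size_factor: float = 1.25
    solidity_min: float = 0.85
    cdx2_sdom_threshold: float = 5.0
    # absolute raw-intensity fallbacks used when SDOMs are unavailable
    # (e.g. touch preps without WBCs); None disables the fallback
    abs_ck_threshold: float | None = None
    abs_cd45_threshold: float | None = None


def _require(features: Mapping[str, float], name: str) -> float:
    if name not in features:
        raise MissingFeatureError(f"feature {name!r} missing")
    value = features[name]
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise MissingFeatureError(f"feature {name!r} is missing (NaN)")
    return float(value)


def classify_cell(
    features: Mapping[str, float],
    wbc_mean_nuclear_area: float,
    config: ClassifierConfig = ClassifierConfig(),
) -> str:
    """Assign one segmented cell to a category via the decision ladder.

    ``features`` must provide ``sdom_cd45``, ``sdom_ck``, ``nuclear_area`` and
    ``nuclear_solidity``. When an SDOM is missing (no usable background) the
    absolute fallback thresholds are applied to the raw cell means if
    configured, else a :class:`MissingFeatureError` names the feature.
    """
    nuclear_area = _require(features, "nuclear_area")
    solidity = _require(features, "nuclear_solidity")

    def positive(sdom_name: str, mean_name: str, t_sdom: float, t_abs: float | None) -> bool:
        value = features.get(sdom_name)
        if value is not None and not math.isnan(float(value)):
            return float(value) >= t_sdom
        if t_abs is not None:
            return _require(features, mean_name) >= t_abs
        raise MissingFeatureError(
            f"feature {sdom_name!r} is missing and no absolute fallback configured"
        )

    cd45_pos = positive("sdom_cd45", "mean_cd45_cell", config.t_cd45, config.abs_cd45_threshold)
    if cd45_pos:
        return "WBC"

    ck_pos = positive("sdom_ck", "mean_ck_cell", config.t_ck, config.abs_ck_threshold)
    large = nuclear_area > config.size_factor * wbc_mean_nuclear_area
    if ck_pos:
        if large:
            return "HD-CTC" if solidity >= config.solidity_min else "Apoptotic-like"
        return "CTC-Small"
    if large:
        return "CTC-LowCK"
    return "FalsePositive"


def bin_cdx2(
    sdom_cdx2: float | None,
    threshold: float = 5.0,
    override: str | None = None,
) -> tuple[str, bool]:
    """CDX2 bin (positive / negative / indeterminate) and the override flag.

    The guide threshold is SDOM 5; a supplied analyst override wins and sets
    the flag (mirroring cell-by-cell review of imperfect segmentations). A
    missing SDOM with no override is indeterminate.
    """
    if override is not None:
        if override not in ("positive", "negative"):
            raise ValueError("override must be 'positive' or 'negative'")
        return override, True
    if sdom_cdx2 is None or math.isnan(float(sdom_cdx2)):
        return "indeterminate", False
    return ("positive" if float(sdom_cdx2) >= threshold else "negative"), False


def group_ctcc(
    categories: Mapping[int, str],
    touching_groups: Sequence[Sequence[int]],
) -> tuple[dict[int, str], dict[int, int]]:
    """Relabel HD-CTCs in touching groups of >= 2 HD-CTCs as CTCC members.

    Only HD-CTCs count toward the >= 2 rule (a WBC touching a lone HD-CTC does
    not make a cluster). Returns updated categories and label -> group id.
    """
    updated = dict(categories)
    group_ids: dict[int, int] = {}
    next_id = 1
    for group in touching_groups:
        members = [lab for lab in group if categories.get(lab) == "HD-CTC"]
        if len(members) >= 2:
            for lab in members:
                updated[lab] = "CTCC-member"
                group_ids[lab] = next_id
            next_id += 1
    return updated, group_ids


def enumerate_to_concentration(
    count: int,
    leukocyte_concentration: float,
    n_dapi_nuclei: int,
) -> float:
    """Convert a slide count to cells/mL via the sample leukocyte
    concentration and the number of DAPI nuclei detected on the slide."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if leukocyte_concentration <= 0:
        raise ValueError("leukocyte_concentration must be > 0")
    if n_dapi_nuclei <= 0:
        raise ValueError("n_dapi_nuclei must be > 0")
    return count * leukocyte_concentration / n_dapi_nuclei


def call_positivity(concentration: float, threshold: float = 4.0) -> bool:
    """Sample positivity: strictly more than 4 HD-CTCs per mL."""
    return concentration > threshold
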