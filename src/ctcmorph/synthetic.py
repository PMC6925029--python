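"""Synthetic immunofluorescence frames and feature-level cohorts.

Two generators make every downstream stage testable without any external data:

``generate_frame``
    Renders a 4-channel (DAPI, pan-CK, CD45, CDX2) fluorescence frame emulating
    a liquid-biopsy monolayer: a lawn of leukocytes (WBCs) with rare, larger
    cytokeratin-positive tumor cells, optionally grouped into touching clusters
    (CTC-cluster geometry). Ground-truth label masks and per-object records are
    returned alongside the images, so segmentation and classification can be
    scored against the planted truth.

``generate_cohort_features``
    Draws a cells x features table with per-patient compartment structure
    (liquid / metastasis / primary) and a *controllable* liquid-solid
    concordance: the per-patient Pearson correlation between compartment
    mean-profiles equals ``target_profile_correlation`` both on the raw feature
    means and through the min-max-scaled profile-average estimator used by the
    concordance stage. Optional planted archetypes give ground-truth cluster
    labels for the metaclustering stage.

Both generators are bit-reproducible given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import disk as disk_footprint

from .catalog import ANNOTATION_COLUMNS, CHANNELS, feature_names

__all__ = [
    "FrameSceneSpec",
    "FrameScene",
    "ObjectRecord",
    "CohortSpec",
    "CohortTable",
    "PackingError",
    "generate_frame",
    "generate_cohort_features",
]


class PackingError(RuntimeError):
    """Raised when the requested objects cannot be placed in the frame."""


# --------------------------------------------------------------------------- #
# frame-level generator
# --------------------------------------------------------------------------- #

DEFAULT_CHANNEL_LEVELS: dict[str, dict[str, tuple[float, float]]] = {
    # per channel: population -> (mean, sd) of the object-level signal added
    # on top of the frame background
    "dapi": {"wbc": (600.0, 40.0), "tumor": (650.0, 40.0)},
    "ck": {"wbc": (0.0, 0.0), "tumor": (700.0, 50.0)},
    "cd45": {"wbc": (500.0, 40.0), "tumor": (0.0, 0.0)},
    "cdx2": {"wbc": (0.0, 0.0), "tumor_pos": (600.0, 50.0), "tumor_neg": (0.0, 0.0)},
}

DEFAULT_BACKGROUND: dict[str, tuple[float, float]] = {
    channel: (80.0, 8.0) for channel in CHANNELS
}


@dataclass(frozen=True)
class FrameSceneSpec:
    """Parameters of one synthetic multichannel frame.

    Counts are totals: ``n_tumor`` includes the cells consumed by the
    ``n_tumor_clusters`` touching groups (``cluster_size`` members each).
    """

    frame_shape: tuple[int, int] = (400, 400)
    n_wbc: int = 60
    n_tumor: int = 5
    n_tumor_clusters: int = 0
    cluster_size: int = 2
    wbc_nuclear_radius_px: tuple[float, float] = (6.0, 0.8)  # mean, sd
    tumor_nuclear_scale: float = 1.6
    axis_jitter_sd: float = 0.1  # log-sd of tumor ellipse axis jitter
    wbc_cyto_width_px: int = 2
    tumor_cyto_width_px: int = 4
    min_separation_px: int = 3
    channel_levels: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_CHANNEL_LEVELS
    )
    background_level: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: DEFAULT_BACKGROUND
    )
    cdx2_positive_fraction: float = 0.5
    max_attempts: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.frame_shape) < 16:
            raise ValueError("frame_shape too small")
        for name in ("n_wbc", "n_tumor", "n_tumor_clusters"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cluster_size < 2:
            raise ValueError("cluster_size must be >= 2")
        if self.n_tumor_clusters * self.cluster_size > self.n_tumor:
            raise ValueError("n_tumor smaller than cells consumed by clusters")
        if self.wbc_nuclear_radius_px[0] <= 0 or self.wbc_nuclear_radius_px[1] < 0:
            raise ValueError("wbc_nuclear_radius_px must be positive")
        if self.tumor_nuclear_scale <= 0:
            raise ValueError("tumor_nuclear_scale must be > 0")
        if not 0.0 <= self.cdx2_positive_fraction <= 1.0:
            raise ValueError("cdx2_positive_fraction must lie in [0, 1]")
        for channel, (mu, sd) in self.background_level.items():
            if mu < 0 or sd < 0:
                raise ValueError(f"background_level[{channel}] must be >= 0")
        for channel, pops in self.channel_levels.items():
            for pop, (mu, sd) in pops.items():
                if mu < 0 or sd < 0:
                    raise ValueError(f"channel_levels[{channel}][{pop}] must be >= 0")


@dataclass
class ObjectRecord:
    """Ground truth for one planted object."""

    label: int
    population: str  # "wbc" | "tumor"
    cluster_id: int | None
    center: tuple[float, float]  # (row, col)
    nuclear_area: int
    cell_area: int
    cdx2_positive: bool
    true_levels: dict[str, float]  # per-channel object signal above background

    @property
    def category_truth(self) -> str:
        if self.population == "wbc":
            return "WBC"
        return "CTCC-member" if self.cluster_id is not None else "HD-CTC"


@dataclass
class FrameScene:
    """One rendered frame with ground truth."""

    spec: FrameSceneSpec
    channels: dict[str, np.ndarray]  # uint16, keyed by catalog.CHANNELS
    nuclear_labels: np.ndarray  # uint16, 0 = background
    cell_labels: np.ndarray
    objects: list[ObjectRecord]

    def channel_stack(self) -> np.ndarray:
        return np.stack([self.channels[c] for c in CHANNELS])


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


class _Placer:
    """Incremental non-touching object placement with a blocked-area mask."""

    def __init__(self, shape: tuple[int, int], min_separation: int):
        self.shape = shape
        self.blocked = np.zeros(shape, dtype=bool)
        self.sep_fp = disk_footprint(max(min_separation, 1))

    def fits(self, rows: np.ndarray, cols: np.ndarray) -> bool:
        return not self.blocked[rows, cols].any()

    def commit(self, rows: np.ndarray, cols: np.ndarray) -> None:
        patch = np.zeros(self.shape, dtype=bool)
        patch[rows, cols] = True
        self.blocked |= ndimage.binary_dilation(patch, structure=self.sep_fp)


def _draw_object(
    center: tuple[float, float],
    axes: tuple[float, float],
    orientation: float,
    cyto_width: int,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None:
    """Rasterize nucleus ellipse + dilated cell mask; None if out of frame."""
    nr, nc = draw_ellipse(
        center[0], center[1], axes[0], axes[1], rotation=orientation
    )
    if len(nr) == 0:
        return None
    margin = cyto_width + 1
    if (
        nr.min() < margin
        or nc.min() < margin
        or nr.max() >= shape[0] - margin
        or nc.max() >= shape[1] - margin
    ):
        return None
    nuc = np.zeros(shape, dtype=bool)
    nuc[nr, nc] = True
    cell = ndimage.binary_dilation(nuc, structure=disk_footprint(cyto_width))
    cr, cc = np.nonzero(cell)
    return nr, nc, cr, cc


def _touches(
    rows_a: np.ndarray, cols_a: np.ndarray, mask_b: np.ndarray
) -> tuple[bool, bool]:
    """(overlaps, 8-adjacent) of pixel set A against boolean mask B."""
    overlap = bool(mask_b[rows_a, cols_a].any())
    dil = ndimage.binary_dilation(mask_b, structure=np.ones((3, 3), bool))
    adjacent = bool(dil[rows_a, cols_a].any())
    return overlap, adjacent


def generate_frame(spec: FrameSceneSpec) -> FrameScene:
    """Render one synthetic frame with ground-truth masks and records.

    Raises
    ------
    PackingError
        If an object cannot be placed after ``spec.max_attempts`` rejection
        samples (the frame is too crowded for the requested counts).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.frame_shape
    placer = _Placer(shape, spec.min_separation_px)

    nuclear_labels = np.zeros(shape, dtype=np.uint16)
    cell_labels = np.zeros(shape, dtype=np.uint16)
    objects: list[ObjectRecord] = []

    r_mean, r_sd = spec.wbc_nuclear_radius_px
    mu_r, sig_r = _lognormal_params(r_mean, r_sd)
    # base tumor axis chosen so E[tumor area] / E[wbc area] = scale^2 exactly
    tumor_axis = math.sqrt(r_mean**2 + r_sd**2) * spec.tumor_nuclear_scale
    jit_mu = -spec.axis_jitter_sd**2 / 2.0  # lognormal jitter with mean 1

    def sample_geometry(population: str) -> tuple[tuple[float, float], float, int]:
        if population == "wbc":
            r = float(rng.lognormal(mu_r, sig_r))
            return (r, r), 0.0, spec.wbc_cyto_width_px
        a = tumor_axis * float(rng.lognormal(jit_mu, spec.axis_jitter_sd))
        b = tumor_axis * float(rng.lognormal(jit_mu, spec.axis_jitter_sd))
        return (a, b), float(rng.uniform(0, math.pi)), spec.tumor_cyto_width_px

    def place_free(population: str):
        for _ in range(spec.max_attempts):
            axes, rot, cyto = sample_geometry(population)
            margin = max(axes) + cyto + 2
            center = (
                float(rng.uniform(margin, shape[0] - margin)),
                float(rng.uniform(margin, shape[1] - margin)),
            )
            drawn = _draw_object(center, axes, rot, cyto, shape)
            if drawn is None:
                continue
            nr, nc, cr, cc = drawn
            if placer.fits(cr, cc):
                return center, nr, nc, cr, cc
        raise PackingError(
            f"could not place {population} object in frame of shape {shape}; "
            "reduce counts or enlarge the frame"
        )

    label = 0

    def commit(population, cluster_id, center, nr, nc, cr, cc):
        nonlocal label
        label += 1
        nuclear_labels[nr, nc] = label
        cell_labels[cr, cc] = label
        placer.commit(cr, cc)
        cdx2_pos = population == "tumor" and bool(
            rng.random() < spec.cdx2_positive_fraction
        )
        levels: dict[str, float] = {}
        for channel in CHANNELS:
            pops = spec.channel_levels[channel]
            if population == "tumor" and channel == "cdx2":
                key = "tumor_pos" if cdx2_pos else "tumor_neg"
            else:
                key = population
            mean, sd = pops.get(key, (0.0, 0.0))
            levels[channel] = max(0.0, float(rng.normal(mean, sd))) if mean > 0 else 0.0
        objects.append(
            ObjectRecord(
                label=label,
                population=population,
                cluster_id=cluster_id,
                center=center,
                nuclear_area=int(len(nr)),
                cell_area=int(len(cr)),
                cdx2_positive=cdx2_pos,
                true_levels=levels,
            )
        )

    # --- tumor clusters: chains of touching cell masks, nuclei kept apart ---
    n_single_tumor = spec.n_tumor - spec.n_tumor_clusters * spec.cluster_size
    for cluster_id in range(1, spec.n_tumor_clusters + 1):
        center, nr, nc, cr, cc = place_free("tumor")
        commit("tumor", cluster_id, center, nr, nc, cr, cc)
        group_cells = np.zeros(shape, dtype=bool)
        group_cells[cr, cc] = True
        group_nuclei_halo = np.zeros(shape, dtype=bool)
        patch = np.zeros(shape, dtype=bool)
        patch[nr, nc] = True
        group_nuclei_halo |= ndimage.binary_dilation(
            patch, structure=disk_footprint(spec.min_separation_px)
        )
        prev_center, prev_axis = center, tumor_axis
        for _member in range(spec.cluster_size - 1):
            placed = False
            for _ in range(spec.max_attempts):
                axes, rot, cyto = sample_geometry("tumor")
                theta = rng.uniform(0, 2 * math.pi)
                d_far = prev_axis + max(axes) + 2 * cyto + 4
                for dist in np.arange(d_far, max(axes), -1.0):
                    cand_center = (
                        prev_center[0] + dist * math.sin(theta),
                        prev_center[1] + dist * math.cos(theta),
                    )
                    drawn = _draw_object(cand_center, axes, rot, cyto, shape)
                    if drawn is None:
                        continue
                    nr2, nc2, cr2, cc2 = drawn
                    overlap, adjacent = _touches(cr2, cc2, group_cells)
                    if overlap:
                        break  # stepped too close; this direction is done
                    if not adjacent:
                        continue
                    if group_nuclei_halo[nr2, nc2].any():
                        break
                    # must not collide with non-cluster objects
                    other_blocked = placer.blocked & ~ndimage.binary_dilation(
                        group_cells, structure=placer.sep_fp
                    )
                    if other_blocked[cr2, cc2].any():
                        break
                    commit("tumor", cluster_id, cand_center, nr2, nc2, cr2, cc2)
                    group_cells[cr2, cc2] = True
                    patch = np.zeros(shape, dtype=bool)
                    patch[nr2, nc2] = True
                    group_nuclei_halo |= ndimage.binary_dilation(
                        patch, structure=disk_footprint(spec.min_separation_px)
                    )
                    prev_center, prev_axis = cand_center, max(axes)
                    placed = True
                    break
                if placed:
                    break
            if not placed:
                raise PackingError("could not attach cluster member")

    for _ in range(n_single_tumor):
        center, nr, nc, cr, cc = place_free("tumor")
        commit("tumor", None, center, nr, nc, cr, cc)
    for _ in range(spec.n_wbc):
        center, nr, nc, cr, cc = place_free("wbc")
        commit("wbc", None, center, nr, nc, cr, cc)

    # --- render channels: constant background + object signal + gaussian noise
    channels: dict[str, np.ndarray] = {}
    for channel in CHANNELS:
        bg_mean, bg_sd = spec.background_level[channel]
        img = np.full(shape, bg_mean, dtype=np.float64)
        for obj in objects:
            level = obj.true_levels[channel]
            if level <= 0:
                continue
            region = (
                nuclear_labels == obj.label
                if channel == "dapi"
                else cell_labels == obj.label
            )
            img[region] += level
        img += rng.normal(0.0, bg_sd, size=shape)
        channels[channel] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    return FrameScene(
        spec=spec,
        channels=channels,
        nuclear_labels=nuclear_labels,
        cell_labels=cell_labels,
        objects=objects,
    )


# --------------------------------------------------------------------------- #
# feature-level cohort generator
# --------------------------------------------------------------------------- #

# Within-cell value model (concordance mode), per feature f and compartment c:
#   x = delta_cf + within_sd * (B - gamma * m_f)
#   B  = -1 w.p. EDGE_MASS;  +1 w.p. EDGE_MASS          (saturated cells that
#        pin the patient-level min-max range of the feature)
#        else Uniform(m_f - BULK_HALF_WIDTH, m_f + BULK_HALF_WIDTH)
# m_f in [-q_amp, q_amp] is a per-feature bulk offset shared by all
# compartments (feature-specific distribution shape); gamma*m_f is subtracted
# so compartment raw means equal delta_cf exactly in expectation.
EDGE_MASS = 0.06
BULK_HALF_WIDTH = 0.3
_GAMMA = 1.0 - 2.0 * EDGE_MASS


def _bulk_variance(q_amp: float) -> float:
    second = 2.0 * EDGE_MASS + _GAMMA * (q_amp**2 / 3.0 + BULK_HALF_WIDTH**2 / 3.0)
    return second - (_GAMMA * q_amp) ** 2 / 3.0


def _gap_expectations(sd_gap: float) -> tuple[float, float]:
    """Expectations over the compartment-mean gap D ~ N(0, sd_gap^2), on the
    within_sd=1 scale: G2 = E[4/(2+|D|)^2] (shared-term shrinkage) and
    Keff = E[D^2 / (4 (2+|D|)^2)] (antisymmetric-term variance)."""
    if sd_gap <= 0:
        return 1.0, 0.0
    x = np.linspace(-8.0, 8.0, 2001)
    pdf = np.exp(-x * x / 2.0) / math.sqrt(2.0 * math.pi)
    d = np.abs(sd_gap * x)
    g2 = float(np.trapezoid(4.0 / (2.0 + d) ** 2 * pdf, x))
    keff = float(np.trapezoid(d * d / (4.0 * (2.0 + d) ** 2) * pdf, x))
    return g2, keff


def _calibrate(rho: float, shift_scale: float, n_cells: int) -> tuple[float, float]:
    """Return (rho_delta, q_amp) realizing target rho both on raw mean
    profiles and through the pooled min-max / profile-average estimator."""
    if rho >= 0.99:
        return 1.0, 0.6
    q_amp = 0.3
    rho_delta = rho
    for _ in range(50):
        v_b = _bulk_variance(q_amp)
        # inflate the shift correlation to undo raw-mean sampling attenuation
        rho_delta = rho * (1.0 + v_b / (n_cells * shift_scale**2))
        rho_delta = float(np.clip(rho_delta, -1.0, 1.0))
        sd_gap = shift_scale * math.sqrt(2.0 * max(0.0, 1.0 - rho_delta))
        g2, keff = _gap_expectations(sd_gap)
        v_n = v_b / (4.0 * n_cells) * g2
        q_required = (keff * (1.0 + rho) + rho * v_n) / (1.0 - rho)
        q_amp = min(0.65, math.sqrt(max(q_required, 0.0) * 12.0 / (_GAMMA**2 * g2)))
    return rho_delta, q_amp


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic feature-level cohort.

    ``within_sd`` is the scale of the within-compartment cell variability (the
    half-range of the structured within-cell distribution in concordance mode,
    the gaussian sd in archetype mode). Compartment mean shifts have sd
    ``shift_scale * within_sd`` per feature; the first listed compartment is
    the liquid reference and every other compartment's shift vector correlates
    with it so the per-patient profile correlation equals
    ``target_profile_correlation``.
    """

    n_patients: int = 10
    compartments: tuple[str, ...] = ("liquid", "metastasis")
    cells_per_compartment: int = 43
    n_features: int = 82
    within_sd: float = 1.0
    shift_scale: float = 0.2
    target_profile_correlation: float = 0.65
    compartment_shift: Mapping[str, Sequence[float]] | None = None
    planted_cluster_archetypes: Sequence[Sequence[float]] | None = None
    archetype_weights: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.cells_per_compartment < 1:
            raise ValueError("counts must be >= 1")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not -1.0 <= self.target_profile_correlation <= 1.0:
            raise ValueError("target_profile_correlation must lie in [-1, 1]")
        if self.within_sd < 0 or self.shift_scale < 0:
            raise ValueError("scales must be >= 0")
        if not set(self.compartments) <= {"liquid", "metastasis", "primary"}:
            raise ValueError("compartments must be among liquid/metastasis/primary")
        if len(self.compartments) < 1:
            raise ValueError("need at least one compartment")


class CohortTable:
    """Cells x (annotations + features) table.

    ``data`` holds the mandated annotation columns (``patient_id``,
    ``compartment``, ``cell_id``, ``category_truth``) followed by feature
    columns. ``truth`` (optional, generator-populated) carries the planted
    ground truth: per-patient compartment mean-profiles and archetype labels.
    """

    def __init__(self, data: pd.DataFrame, truth: dict | None = None):
        missing = [c for c in ANNOTATION_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"cohort table missing annotation columns {missing}")
        self.data = data.reset_index(drop=True)
        self.truth = truth

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ANNOTATION_COLUMNS]

    @property
    def patients(self) -> list[str]:
        return list(pd.unique(self.data["patient_id"]))

    def patient_block(self, patient_id: str) -> pd.DataFrame:
        return self.data[self.data["patient_id"] == patient_id]

    def features(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.data)


def generate_cohort_features(spec: CohortSpec) -> CohortTable:
    """Generate a cohort table with planted compartment/cluster structure."""
    rng = np.random.default_rng(spec.seed)
    p = spec.n_features
    names = feature_names(p)
    n = spec.cells_per_compartment
    rho = spec.target_profile_correlation

    archetypes = None
    if spec.planted_cluster_archetypes is not None:
        archetypes = np.asarray(spec.planted_cluster_archetypes, dtype=float)
        if archetypes.ndim != 2 or archetypes.shape[1] != p:
            raise ValueError("archetypes must be (k, n_features)")
        weights = (
            np.full(len(archetypes), 1.0 / len(archetypes))
            if spec.archetype_weights is None
            else np.asarray(spec.archetype_weights, dtype=float)
        )
        weights = weights / weights.sum()

    explicit_shift = None
    if spec.compartment_shift is not None:
        explicit_shift = {
            comp: np.asarray(vec, dtype=float) for comp, vec in spec.compartment_shift.items()
        }
        for comp, vec in explicit_shift.items():
            if vec.shape != (p,):
                raise ValueError(f"compartment_shift[{comp}] must have n_features entries")

    if explicit_shift is None:
        rho_delta, q_amp = _calibrate(rho, spec.shift_scale, n)
    else:
        rho_delta, q_amp = rho, 0.4  # shape spread not calibrated to a target

    d_scale = spec.shift_scale * spec.within_sd
    rows: list[pd.DataFrame] = []
    truth_profiles: dict[tuple[str, str], np.ndarray] = {}
    truth_archetype: list[np.ndarray] = []

    for i_pat in range(spec.n_patients):
        patient = f"P{i_pat + 1:03d}"
        z_ref = rng.normal(size=p)
        m_f = q_amp * rng.uniform(-1.0, 1.0, size=p)
        for comp in spec.compartments:
            if explicit_shift is not None:
                delta = explicit_shift.get(comp, np.zeros(p))
            elif comp == spec.compartments[0]:
                delta = d_scale * z_ref
            else:
                z_c = rho_delta * z_ref + math.sqrt(
                    max(0.0, 1.0 - rho_delta**2)
                ) * rng.normal(size=p)
                delta = d_scale * z_c
            truth_profiles[(patient, comp)] = delta

            if archetypes is not None:
                assign = rng.choice(len(archetypes), size=n, p=weights)
                values = archetypes[assign] + rng.normal(
                    scale=spec.within_sd, size=(n, p)
                )
                values += delta
                labels = np.array([f"A{k}" for k in assign])
                truth_archetype.append(assign)
            else:
                u = rng.random((n, p))
                bulk = m_f + rng.uniform(-BULK_HALF_WIDTH, BULK_HALF_WIDTH, size=(n, p))
                b = np.where(u < EDGE_MASS, -1.0, np.where(u < 2 * EDGE_MASS, 1.0, bulk))
                values = delta + spec.within_sd * (b - _GAMMA * m_f)
                labels = np.full(n, "cell")
            block = pd.DataFrame(values, columns=names)
            block.insert(0, "category_truth", labels)
            block.insert(0, "cell_id", [f"{patient}_{comp}_{j:04d}" for j in range(n)])
            block.insert(0, "compartment", comp)
            block.insert(0, "patient_id", patient)
            rows.append(block)

    data = pd.concat(rows, ignore_index=True)
    truth = {
        "profiles": truth_profiles,
        "rho_delta": rho_delta,
        "q_amp": q_amp,
        "archetype": np.concatenate(truth_archetype) if truth_archetype else None,
    }
    return CohortTable(data, truth=truth)
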