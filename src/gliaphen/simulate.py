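"""Synthetic phantoms with planted ground truth.

Every downstream stage (segmentation, phenotyping, PET quantification, cohort
statistics) is exercised on data generated here, because the study design
this package re-implements deposits no raw images or PET volumes.  Three
input classes are emulated:

* multi-channel fluorescence fields (DAPI + glial marker + phenotype marker)
  with planted, non-overlapping nuclear discs and known glial/phenotype
  labels;
* PET phantoms with region-dependent uptake, a cerebellar reference VOI, and
  known planted concentrations;
* cohort outcome tables with log-normal animal-level variation and a known
  exposure geometric mean ratio, plus modified-Racine seizure-score series.

All generators are deterministic under a fixed seed.  Noise is additive
Gaussian clipped at zero: threshold behaviour, not photon statistics, is what
the downstream stages exercise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as _disk_px, line as _line_px
from skimage.morphology import dilation as _dilation, disk as _disk_se

from .cohort_stats import COHORT_COLUMNS, RacineSeries
from .petquant import CEREBELLUM, PetVolume, validate_vois
from .segmentation import FieldImage

#: The six analysed brain regions.
REGIONS = (
    "somatosensory cortex",
    "CA1",
    "CA3",
    "thalamus",
    "amygdala",
    "piriform cortex",
)

#: Histology / imaging timepoints, days post-exposure.
TIMEPOINTS = (1, 3, 7, 14, 28)

EXPOSURES = ("Veh", "DFP")


class PlacementError(RuntimeError):
    """Raised when non-overlapping nucleus placement fails (field too crowded)."""


@dataclass(frozen=True)
class FieldSimParams:
    """Parameters of one simulated fluorescence field.

    Defaults emulate a 20x widefield acquisition: 512 x 512 px at
    0.325 um/px (~166 um field of view) with ~6.5-um-diameter nuclei.
    ``marker_overlap_target`` is the planted fraction of each glial nucleus
    covered by the glial-marker channel; the glial marker additionally gets a
    perinuclear ring and 2-4 linear processes outside the nucleus, mimicking
    cytoplasmic IBA1/GFAP morphology.
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 0.325
    n_nuclei: int = 50
    glial_fraction: float = 0.4
    phenotype_fraction: float = 0.5
    nucleus_radius_px: float = 10.0
    radius_jitter: float = 0.1
    marker_overlap_target: float = 1.0
    ring_px: int = 3
    n_processes: int = 3
    process_len_px: int = 15
    background_level: float = 0.1
    foreground_level: float = 1.0
    noise_sd: float = 0.0
    glial_marker: str = "IBA1"
    phenotype_marker: str = "iNOS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("field dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be nonnegative")
        for name in ("glial_fraction", "phenotype_fraction", "marker_overlap_target"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.nucleus_radius_px <= 0:
            raise ValueError("nucleus_radius_px must be positive")
        if not (0.0 <= self.radius_jitter < 1.0):
            raise ValueError("radius_jitter must lie in [0, 1)")
        for name in ("background_level", "foreground_level", "noise_sd"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be a finite nonnegative real")

    @property
    def n_glial(self) -> int:
        return int(round(self.glial_fraction * self.n_nuclei))

    @property
    def n_phenotype(self) -> int:
        return int(round(self.phenotype_fraction * self.n_glial))

    def snr(self) -> float:
        """Contrast-to-noise: (foreground - background) / noise_sd."""
        if self.noise_sd == 0:
            return math.inf
        return (self.foreground_level - self.background_level) / self.noise_sd


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth of one field.

    ``nuclei`` has one row per planted nucleus (id, row, col, radius_px,
    is_glial, is_phenotype); the binary masks are the exact planted pixel
    sets of each channel's structure.
    """

    nuclei: pd.DataFrame
    region_area_mm2: float
    dapi_mask: np.ndarray
    glia_mask: np.ndarray
    phenotype_mask: np.ndarray

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)

    @property
    def n_glial(self) -> int:
        return int(self.nuclei["is_glial"].sum()) if len(self.nuclei) else 0

    @property
    def n_phenotype(self) -> int:
        return int(self.nuclei["is_phenotype"].sum()) if len(self.nuclei) else 0


def _place_nuclei(params: FieldSimParams, rng: np.random.Generator) -> list[tuple[int, int, float]]:
    """Rejection-sample non-overlapping disc centres; <= 10 * n attempts."""
    placed: list[tuple[int, int, float]] = []
    if params.n_nuclei == 0:
        return placed
    max_attempts = 10 * params.n_nuclei
    gap = 2 * params.ring_px + 2  # keep rings off neighbouring nuclei
    attempts = 0
    while len(placed) < params.n_nuclei:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed only {len(placed)}/{params.n_nuclei} nuclei after "
                f"{max_attempts} attempts; field too crowded"
            )
        attempts += 1
        r = params.nucleus_radius_px * (
            1.0 + rng.uniform(-params.radius_jitter, params.radius_jitter)
        )
        margin = int(math.ceil(r)) + params.ring_px + 1
        if 2 * margin >= min(params.height_px, params.width_px):
            raise PlacementError("nucleus too large for the field")
        row = int(rng.integers(margin, params.height_px - margin))
        col = int(rng.integers(margin, params.width_px - margin))
        ok = all(
            math.hypot(row - r0, col - c0) >= r + rr + gap for r0, c0, rr in placed
        )
        if ok:
            placed.append((row, col, r))
    return placed


def _render(mask: np.ndarray, params: FieldSimParams, rng: np.random.Generator) -> np.ndarray:
    img = params.background_level + (
        params.foreground_level - params.background_level
    ) * mask.astype(float)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def generate_field(
    params: FieldSimParams,
) -> tuple[FieldImage, FieldImage, FieldImage, SimTruth]:
    """Simulate one three-channel field with planted labels.

    Returns (dapi, glia, phenotype, truth).  The glial-marker channel covers
    exactly ``ceil(marker_overlap_target * area)`` pixels of each glial
    nucleus (so the planted in-nucleus overlap fraction is known and >= the
    target), plus a perinuclear ring and linear processes confined to
    extranuclear pixels so they perturb no nucleus's overlap fraction.  The
    phenotype channel does the same for phenotype-positive glial nuclei.
    """
    rng = np.random.default_rng(params.seed)
    shape = (params.height_px, params.width_px)
    placed = _place_nuclei(params, rng)
    n_glial, n_phen = params.n_glial, params.n_phenotype

    dapi_mask = np.zeros(shape, dtype=bool)
    all_nuclei = np.zeros(shape, dtype=bool)
    nucleus_px: list[tuple[np.ndarray, np.ndarray]] = []
    for row, col, r in placed:
        rr, cc = _disk_px((row, col), r, shape=shape)
        dapi_mask[rr, cc] = True
        all_nuclei[rr, cc] = True
        nucleus_px.append((rr, cc))

    def marker_channel(member_ids: list[int]) -> np.ndarray:
        covered = np.zeros(shape, dtype=bool)
        extra = np.zeros(shape, dtype=bool)
        se = _disk_se(params.ring_px)
        for i in member_ids:
            rr, cc = nucleus_px[i]
            n_px = len(rr)
            n_cover = math.ceil(params.marker_overlap_target * n_px)
            order = np.lexsort((rr, cc))  # left-to-right cap of the disc
            covered[rr[order[:n_cover]], cc[order[:n_cover]]] = True
            cell = np.zeros(shape, dtype=bool)
            cell[rr, cc] = True
            extra |= _dilation(cell, se)
            row0, col0, _ = placed[i]
            for _ in range(params.n_processes):
                ang = rng.uniform(0, 2 * math.pi)
                r_end = int(np.clip(row0 + params.process_len_px * math.sin(ang), 0, shape[0] - 1))
                c_end = int(np.clip(col0 + params.process_len_px * math.cos(ang), 0, shape[1] - 1))
                lr, lc = _line_px(row0, col0, r_end, c_end)
                extra[lr, lc] = True
        # Ring/processes stay outside every nucleus: planted overlap fractions
        # are then exactly the per-nucleus covered fraction.
        return covered | (extra & ~all_nuclei)

    glial_ids = list(range(n_glial))
    phen_ids = list(range(n_phen))
    glia_mask = marker_channel(glial_ids)
    phen_mask = marker_channel(phen_ids)

    dapi = FieldImage(_render(dapi_mask, params, rng), params.pixel_size_um, "DAPI")
    glia = FieldImage(_render(glia_mask, params, rng), params.pixel_size_um, params.glial_marker)
    phen = FieldImage(_render(phen_mask, params, rng), params.pixel_size_um, params.phenotype_marker)

    nuclei = pd.DataFrame(
        {
            "id": np.arange(1, len(placed) + 1),
            "row": [p[0] for p in placed],
            "col": [p[1] for p in placed],
            "radius_px": [p[2] for p in placed],
            "is_glial": [i < n_glial for i in range(len(placed))],
            "is_phenotype": [i < n_phen for i in range(len(placed))],
        }
    )
    truth = SimTruth(
        nuclei=nuclei,
        region_area_mm2=params.width_px * params.height_px * params.pixel_size_um**2 * 1e-6,
        dapi_mask=dapi_mask,
        glia_mask=glia_mask,
        phenotype_mask=phen_mask,
    )
    return dapi, glia, phen, truth


# ---------------------------------------------------------------------------
# PET phantom
# ---------------------------------------------------------------------------

#: Default phantom uptakes (kBq/ml); regions elevated relative to cerebellum.
DEFAULT_VOI_UPTAKE = {
    "thalamus": 296.0,
    "amygdala": 296.0,
    "piriform cortex": 222.0,
    "CA1": 222.0,
    "CA3": 222.0,
    "somatosensory cortex": 185.0,
}


def generate_pet_phantom(
    shape: tuple[int, int, int] = (64, 64, 48),
    voxel_size_mm: tuple[float, float, float] = (0.78, 0.78, 0.80),
    voi_uptake_map: dict[str, float] | None = None,
    reference_uptake: float = 148.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    injected_dose_kBq: float = 37000.0,
    body_weight_g: float = 250.0,
    background_fraction: float = 0.5,
    voi_radius_vox: int = 4,
) -> tuple[PetVolume, dict[str, np.ndarray], dict[str, float]]:
    """Simulate a PET frame with spherical VOIs of planted uptake.

    Each named VOI is a sphere filled at its stated activity concentration
    (kBq/ml) plus optional Gaussian noise; a ``cerebellum`` sphere at
    ``reference_uptake`` is always present.  Default dose (37 MBq) and weight
    (250 g) put the reference at SUV 1.  Returns the volume, the VOI mask
    set, and the planted-truth dict (uptake per VOI).
    """
    uptakes = dict(DEFAULT_VOI_UPTAKE if voi_uptake_map is None else voi_uptake_map)
    if any(v <= 0 for v in uptakes.values()) or reference_uptake <= 0:
        raise ValueError("uptake values must be positive")
    uptakes[CEREBELLUM] = reference_uptake

    # Lay spheres on a deterministic grid with spacing > 2r so VOIs are disjoint.
    names = sorted(uptakes)
    r = voi_radius_vox
    spacing = 2 * r + 3
    n_axis0 = max(0, (shape[0] - 2 * (r + 1)) // spacing + 1)
    n_axis1 = max(0, (shape[1] - 2 * (r + 1)) // spacing + 1)
    if n_axis0 * n_axis1 < len(names) or shape[2] < 2 * (r + 1):
        raise ValueError("volume too small for the requested VOI set")
    centres = []
    for idx in range(len(names)):
        i, j = divmod(idx, n_axis0)
        centres.append((r + 1 + j * spacing, r + 1 + i * spacing, shape[2] // 2))

    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    vois: dict[str, np.ndarray] = {}
    for name, (cz, cy, cx) in zip(names, centres):
        vois[name] = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2

    overlap = np.zeros(shape, dtype=int)
    for m in vois.values():
        overlap += m
    if overlap.max() > 1:
        raise ValueError("VOIs overlap")
    validate_vois(vois, shape)

    rng = np.random.default_rng(seed)
    vol = np.full(shape, background_fraction * reference_uptake, dtype=float)
    for name, m in vois.items():
        vol[m] = uptakes[name]
    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, size=shape)
    vol = np.clip(vol, 0.0, None)
    volume = PetVolume(vol, voxel_size_mm, injected_dose_kBq, body_weight_g)
    return volume, vois, uptakes


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters of one simulated outcome cohort.

    The generator realises the variance structure of an animal-level random
    intercept: each animal draws one N(0, sd_log_animal^2) effect shared
    across its region x timepoint cells, and each technical replicate adds
    independent N(0, sd_log_replicate^2) noise, all on the natural-log scale.
    The exposed group's log outcome is offset by ln(true_gmr).
    """

    n_animals_per_group: int = 8
    n_replicates: int = 3
    true_gmr: float = 2.0
    baseline_geomean: float = 1000.0
    sd_log_animal: float = 0.3
    sd_log_replicate: float = 0.15
    regions: tuple[str, ...] = REGIONS
    timepoints: tuple[int, ...] = TIMEPOINTS
    sex: str = "M"
    outcome_name: str = "glial_density"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals_per_group < 1:
            raise ValueError("n_animals_per_group must be positive")
        if not (2 <= self.n_replicates <= 4):
            raise ValueError("n_replicates must lie in [2, 4]")
        if self.true_gmr <= 0 or self.baseline_geomean <= 0:
            raise ValueError("true_gmr and baseline_geomean must be positive")
        if self.sd_log_animal < 0 or self.sd_log_replicate < 0:
            raise ValueError("sd terms must be nonnegative")


def generate_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Simulate an outcome table with a known exposure geometric mean ratio.

    Returns a long-format table with ``COHORT_COLUMNS``; for every cell,
    log value = ln(baseline) + 1[DFP] * ln(true_gmr) + animal + replicate
    noise.  Bit-identical under a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for group in EXPOSURES:
        offset = math.log(params.true_gmr) if group == "DFP" else 0.0
        for a in range(params.n_animals_per_group):
            animal_id = f"{params.sex}-{group}-{a + 1:02d}"
            animal_eff = rng.normal(0.0, params.sd_log_animal)
            for region in params.regions:
                for dpe in params.timepoints:
                    for rep in range(1, params.n_replicates + 1):
                        log_v = (
                            math.log(params.baseline_geomean)
                            + offset
                            + animal_eff
                            + rng.normal(0.0, params.sd_log_replicate)
                        )
                        rows.append(
                            (animal_id, params.sex, group, region, dpe,
                             params.outcome_name, math.exp(log_v), rep)
                        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


# ---------------------------------------------------------------------------
# Racine score series
# ---------------------------------------------------------------------------


def generate_racine_series(
    pattern,
    duration_min: float = 240.0,
    interval_min: float = 5.0,
    seed: int = 0,
    jitter_p: float = 0.0,
) -> RacineSeries:
    """Time-stamped seizure scores at a fixed observation interval.

    ``pattern`` is a sequence of integer scores in {0..5} cycled over the
    observation times (a scalar means a constant score).  ``jitter_p`` is the
    per-observation probability of a +/-1 excursion (clipped to the scale);
    the default 0 keeps the series deterministic.  ``duration_min`` must
    cover the 40-min inclusion window.
    """
    if duration_min < 40:
        raise ValueError("duration must cover at least the 40-min scoring window")
    base = np.atleast_1d(np.asarray(pattern, dtype=int))
    if base.min() < 0 or base.max() > 5:
        raise ValueError("pattern scores must lie in {0..5}")
    times = np.arange(interval_min, duration_min + 1e-9, interval_min)
    scores = base[np.arange(len(times)) % len(base)]
    if jitter_p > 0:
        rng = np.random.default_rng(seed)
        flip = rng.random(len(times)) < jitter_p
        step = rng.choice([-1, 1], size=len(times))
        scores = np.clip(scores + flip * step, 0, 5)
    return RacineSeries(times, scores)
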