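"""TSPO-PET quantification: SUV volumes and lowest-quartile-reference SUVR.

The standardized uptake value normalizes tissue activity concentration by the
injected dose per body weight, SUV(x) = C(x) / (dose / weight), with the usual
1 ml = 1 g tissue-density convention.  Region values are then expressed
relative to a cerebellar reference; to keep skull-penetrating signal from
radiotracer defluorination out of the reference, only the lowest quartile of
cerebellar voxels is averaged (SUVR_Q1).  "Lowest quartile" is operationalized
as the ceil(n/4) smallest voxels under a stable ascending sort, which is
unambiguous on small masks.

Decay correction is assumed applied upstream (a single reconstructed frame is
quantified); VOI generation by atlas registration is out of scope and VOIs
are inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

CEREBELLUM = "cerebellum"


@dataclass(frozen=True)
class PetVolume:
    """Reconstructed PET frame with injection metadata.

    ``voxels`` holds activity concentration in kBq/ml; ``injected_dose_kBq``
    and ``body_weight_g`` scale it to SUV.
    """

    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    injected_dose_kBq: float
    body_weight_g: float

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 3 or v.size == 0:
            raise ValueError("voxels must be a non-empty 3-D array")
        if not np.all(np.isfinite(v)) or v.min() < 0:
            raise ValueError("voxels must be finite and nonnegative")
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be three positive reals")
        if not (self.injected_dose_kBq > 0 and math.isfinite(self.injected_dose_kBq)):
            raise ValueError("injected_dose_kBq must be positive")
        if not (self.body_weight_g > 0 and math.isfinite(self.body_weight_g)):
            raise ValueError("body_weight_g must be positive")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "voxel_size_mm", tuple(float(s) for s in self.voxel_size_mm))


def validate_vois(vois: dict[str, np.ndarray], shape: tuple[int, ...]) -> None:
    """Check the VOI set: non-empty masks on the volume grid, cerebellum present."""
    if CEREBELLUM not in vois:
        raise ValueError(f"VOI set must contain a {CEREBELLUM!r} reference region")
    for name, mask in vois.items():
        m = np.asarray(mask)
        if m.shape != tuple(shape):
            raise ValueError(f"VOI {name!r} shape {m.shape} does not match volume {shape}")
        if not m.any():
            raise ValueError(f"VOI {name!r} is empty")


def compute_suv(volume: PetVolume) -> np.ndarray:
    """SUV volume: activity concentration / (injected dose / body weight)."""
    return volume.voxels / (volume.injected_dose_kBq / volume.body_weight_g)


def q1_reference(suv_volume: np.ndarray, cerebellum_mask: np.ndarray) -> float:
    """Mean SUV of the lowest quartile of cerebellar voxels.

    Sorts the cerebellar SUVs ascending and averages the first ceil(n/4).
    An empty mask or a zero reference (uniformly zero cerebellum) is an
    error: SUVR is undefined in either case.
    """
    values = np.asarray(suv_volume)[np.asarray(cerebellum_mask, dtype=bool)]
    n = values.size
    if n == 0:
        raise ValueError("cerebellum mask is empty")
    k = math.ceil(n / 4)
    ref = float(np.sort(values, kind="stable")[:k].mean())
    if ref <= 0:
        raise ValueError("lowest-quartile cerebellar reference is zero; SUVR undefined")
    return ref


def compute_suvr(
    suv_volume: np.ndarray, vois: dict[str, np.ndarray], cerebellum_key: str = CEREBELLUM
) -> tuple[pd.DataFrame, float]:
    """Per-VOI mean SUV and SUVR_Q1 against the cerebellar lowest-quartile reference.

    Returns a table with one row per VOI (``voi``, ``mean_suv``, ``suvr_q1``)
    and the reference value.  SUVR_Q1 = mean SUV / reference exactly.
    """
    suv = np.asarray(suv_volume)
    if cerebellum_key not in vois:
        raise ValueError(f"VOI set must contain the reference region {cerebellum_key!r}")
    canonical = dict(vois)
    canonical[CEREBELLUM] = canonical.pop(cerebellum_key)
    validate_vois(canonical, suv.shape)
    ref = q1_reference(suv, vois[cerebellum_key])
    rows = []
    for name in sorted(vois):
        mean_suv = float(suv[np.asarray(vois[name], dtype=bool)].mean())
        rows.append({"voi": name, "mean_suv": mean_suv, "suvr_q1": mean_suv / ref})
    return pd.DataFrame(rows), ref


def suvr_table(volume: PetVolume, vois: dict[str, np.ndarray]) -> tuple[pd.DataFrame, float]:
    """Convenience: SUV computation plus per-VOI SUVR in one call."""
    suv = compute_suv(volume)
    return compute_suvr(suv, vois)
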