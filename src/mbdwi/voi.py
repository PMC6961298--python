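"""ROI → VOI aggregation.

A tumor is outlined slice by slice; each slice contributes its ROI area A
and the mean parameter value V inside the ROI.  The per-patient volume-of-
interest value is the area-weighted mean ΣAV / ΣA over all tumor slices.
Unfittable (NaN) voxels are excluded from both the area and the mean, so
necrotic/cystic exclusions do not distort the weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RoiSlice", "VoiSummary", "voi_weighted_mean", "extract_roi_means", "voi_table"]


@dataclass(frozen=True)
class RoiSlice:
    """One slice's ROI: its area (mm² or voxel count — the scale cancels
    in the VOI mean) and the mean parameter value inside it."""

    slice_index: int
    area: float
    mean_value: float

    def __post_init__(self):
        if not self.area > 0:
            raise ValueError("ROI area must be > 0")


@dataclass(frozen=True)
class VoiSummary:
    """Area-weighted per-patient parameter value over all tumor slices."""

    patient_id: str
    parameter: str
    value: float
    n_slices: int


def voi_weighted_mean(
    slices: list[RoiSlice], patient_id: str = "", parameter: str = ""
) -> VoiSummary:
    """ΣAV / ΣA over the given ROI slices."""
    if not slices:
        raise ValueError("need at least one ROI slice")
    areas = np.array([s.area for s in slices], dtype=float)
    values = np.array([s.mean_value for s in slices], dtype=float)
    if np.any(areas <= 0):
        raise ValueError("ROI areas must be > 0")
    value = float(np.sum(areas * values) / np.sum(areas))
    return VoiSummary(patient_id, parameter, value, len(slices))


def extract_roi_means(
    parameter_map: np.ndarray,
    mask: np.ndarray,
    voxel_area: float = 1.0,
) -> list[RoiSlice]:
    """Per-slice ROI area and mean from a 3-D parameter map under a mask.

    The slice axis is the third array axis.  Area = (non-NaN in-mask voxel
    count) × in-plane voxel area; NaN voxels (unfittable) are excluded
    from both the count and the mean.  Slices whose in-mask voxels are all
    NaN (or not in the mask at all) are dropped, with a warning in the
    all-NaN case.
    """
    parameter_map = np.asarray(parameter_map, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if parameter_map.shape != mask.shape:
        raise ValueError("parameter map and mask must share their grid")
    out: list[RoiSlice] = []
    for k in range(mask.shape[2]):
        vals = parameter_map[:, :, k][mask[:, :, k]]
        if vals.size == 0:
            continue
        good = vals[~np.isnan(vals)]
        if good.size == 0:
            warnings.warn(f"slice {k}: all in-mask voxels unfittable; slice dropped",
                          stacklevel=2)
            continue
        out.append(RoiSlice(k, good.size * voxel_area, float(good.mean())))
    return out


def voi_table(summaries: list[VoiSummary]) -> pd.DataFrame:
    """Tidy table: patient_id, parameter, value, n_slices."""
    return pd.DataFrame(
        [(s.patient_id, s.parameter, s.value, s.n_slices) for s in summaries],
        columns=["patient_id", "parameter", "value", "n_slices"],
    )
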