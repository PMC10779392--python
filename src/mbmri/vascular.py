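"""Angiogram intensity-threshold segmentation, per-axis maximum-intensity
projections, and vessel-brain volume correlation.

Thresholding uses a strict ">" comparison (voxels exactly at the threshold
are excluded).  A per-axis MIP of the segmented angiogram is dimensionally
an area; the 3D lumen volume and the per-(axis, threshold) MIP areas are
computed and labelled distinctly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import VolumeImage

log = logging.getLogger("mbmri")

AXES = ("X", "Y", "Z")
_AXIS_INDEX = {"X": 0, "Y": 1, "Z": 2}


@dataclass
class VascularMeasures:
    """One subject's vascular measures across intensity thresholds.

    ``volumes_mm3`` maps threshold -> segmented 3D lumen volume;
    ``mip_areas_mm2`` maps (axis, threshold) -> suprathreshold MIP area.
    Both are non-increasing in the threshold.
    """

    subject: str
    thresholds: tuple[float, ...]
    volumes_mm3: dict[float, float] = field(default_factory=dict)
    mip_areas_mm2: dict[tuple[str, float], float] = field(default_factory=dict)


def segment_vessels(
    angio: VolumeImage, threshold: float
) -> tuple[np.ndarray, float]:
    """Binary lumen mask (intensity strictly above threshold) and its volume
    in mm^3."""
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    mask = angio.data > threshold
    return mask, float(mask.sum()) * angio.voxel_volume


def mip(angio: VolumeImage, axis: str) -> np.ndarray:
    """Maximum-intensity projection along one axis (X, Y or Z)."""
    if axis not in _AXIS_INDEX:
        raise ValidationError(f"axis must be one of {AXES}, got {axis!r}")
    return angio.data.max(axis=_AXIS_INDEX[axis])


def mip_pixel_area(angio: VolumeImage, axis: str) -> float:
    """Area of one projected pixel (product of the two in-plane voxel dims)."""
    dims = [d for i, d in enumerate(angio.voxel_dims) if i != _AXIS_INDEX[axis]]
    return float(dims[0] * dims[1])


def mip_vessel_area(angio: VolumeImage, axis: str, threshold: float) -> float:
    """Suprathreshold area of the MIP along one axis, in mm^2."""
    proj = mip(angio, axis)
    return float((proj > threshold).sum()) * mip_pixel_area(angio, axis)


def vascular_measures(
    angio: VolumeImage,
    thresholds: tuple[float, ...] = (7000.0, 7500.0, 8000.0),
    subject: str = "",
) -> VascularMeasures:
    """All vascular measures of one subject across the given thresholds."""
    out = VascularMeasures(subject=subject, thresholds=tuple(thresholds))
    for th in thresholds:
        _, vol = segment_vessels(angio, th)
        out.volumes_mm3[th] = vol
        for axis in AXES:
            out.mip_areas_mm2[(axis, th)] = mip_vessel_area(angio, axis, th)
    return out


def measures_table(measures: list[VascularMeasures]) -> pd.DataFrame:
    """Long-format table of per-subject vascular measures."""
    rows = []
    for m in measures:
        for th in m.thresholds:
            rows.append(
                {
                    "subject": m.subject, "axis": "3D", "threshold": th,
                    "measure": m.volumes_mm3[th], "units": "mm3",
                }
            )
            for axis in AXES:
                rows.append(
                    {
                        "subject": m.subject, "axis": axis, "threshold": th,
                        "measure": m.mip_areas_mm2[(axis, th)], "units": "mm2",
                    }
                )
    return pd.DataFrame(rows)


def vessel_brain_correlation(
    measures: list[VascularMeasures],
    brain_volumes: dict[str, float],
) -> tuple[pd.DataFrame, float, float]:
    """OLS fit of each (axis, threshold) MIP vessel measure on brain volume.

    Returns a per-combination table (axis, threshold, slope, r, r2, p) plus
    the mean and SD of R^2 across the defined combinations.  Constant vessel
    measures give an undefined combination (warning, excluded from the
    summary).
    """
    if len(measures) < 3:
        raise ValidationError("need >= 3 subjects for correlation")
    subjects = [m.subject for m in measures]
    missing = [s for s in subjects if s not in brain_volumes]
    if missing:
        raise ValidationError(f"no brain volume for subjects: {missing}")
    bv = np.array([brain_volumes[s] for s in subjects])
    rows = []
    for axis in AXES:
        for th in measures[0].thresholds:
            y = np.array([m.mip_areas_mm2[(axis, th)] for m in measures])
            if y.std() == 0 or bv.std() == 0:
                log.warning(
                    "constant measure for axis %s, threshold %g; combination "
                    "undefined", axis, th,
                )
                rows.append(
                    {
                        "axis": axis, "threshold": th, "slope": np.nan,
                        "r": np.nan, "r2": np.nan, "p": np.nan,
                    }
                )
                continue
            fit = stats.linregress(bv, y)
            rows.append(
                {
                    "axis": axis, "threshold": th, "slope": fit.slope,
                    "r": fit.rvalue, "r2": fit.rvalue ** 2, "p": fit.pvalue,
                }
            )
    table = pd.DataFrame(rows)
    defined = table["r2"].dropna()
    if len(defined) == 0:
        raise ValidationError("all vessel measures constant; no summary")
    return table, float(defined.mean()), float(defined.std(ddof=1))
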