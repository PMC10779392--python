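"""Domain types and readers/writers for every external format the pipeline touches.

Volumes and 4D BOLD series travel as NIfTI; region lookup tables, subject
metadata, matrices and edge lists as CSV; run configuration as YAML; reports
as JSON.  Axis convention for all grids: x = left-right, y =
anterior-posterior, z = dorsal-ventral, pre-aligned to the atlas grid
(registration is out of scope).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import DimensionError, FormatError, ValidationError

log = logging.getLogger("mbmri")

GROUPS = ("control", "cko")
HEMISPHERES = ("left", "right")
ATLAS_SCALES = ("coarse", "medium")

#: required columns of a region lookup table
REGION_TABLE_COLUMNS = ("label", "name", "hemisphere", "macro_region", "scale")
#: required columns of a subject metadata table
SUBJECT_META_COLUMNS = ("subject", "group", "sex", "body_weight")


@dataclass
class VolumeImage:
    """A 3D scalar grid with physical voxel dimensions in mm."""

    data: np.ndarray
    voxel_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionError(
                f"VolumeImage requires a 3D grid, got {self.data.ndim}D"
            )
        self.voxel_dims = tuple(float(v) for v in self.voxel_dims)
        if len(self.voxel_dims) != 3 or any(v <= 0 for v in self.voxel_dims):
            raise FormatError(f"voxel_dims must be 3 positives, got {self.voxel_dims}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_dims))


@dataclass
class BoldImage:
    """A 4D BOLD acquisition (x, y, z, t) with repetition time in seconds."""

    data: np.ndarray
    voxel_dims: tuple[float, float, float]
    tr: float = 1.8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DimensionError(
                f"BoldImage requires a 4D grid, got {self.data.ndim}D"
            )
        self.voxel_dims = tuple(float(v) for v in self.voxel_dims)
        if any(v <= 0 for v in self.voxel_dims):
            raise FormatError(f"voxel_dims must be positive, got {self.voxel_dims}")
        if not self.tr > 0:
            raise FormatError(f"tr must be positive, got {self.tr}")

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[3])

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])


@dataclass
class AtlasLabelImage:
    """Integer-labelled parcellation (0 = background) plus its region table.

    Every nonzero label present in the grid must appear exactly once in
    ``region_table`` (columns: label, name, hemisphere, macro_region, scale,
    optional boolean is_ventricle).
    """

    labels: np.ndarray
    voxel_dims: tuple[float, float, float]
    region_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionError(
                f"AtlasLabelImage requires a 3D grid, got {self.labels.ndim}D"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.array_equal(self.labels, np.round(self.labels)):
                raise FormatError("label grid must be integer-valued")
            self.labels = self.labels.astype(np.int32)
        if self.labels.min() < 0:
            raise FormatError("label grid must be non-negative")
        self.voxel_dims = tuple(float(v) for v in self.voxel_dims)
        if any(v <= 0 for v in self.voxel_dims):
            raise FormatError(f"voxel_dims must be positive, got {self.voxel_dims}")
        self.region_table = validate_region_table(self.region_table)
        present = set(np.unique(self.labels)) - {0}
        known = set(self.region_table["label"])
        missing = present - known
        if missing:
            raise ValidationError(
                f"labels present in grid but absent from region table: {sorted(missing)}"
            )

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_dims))


@dataclass
class SubjectMeta:
    """One subject's metadata row."""

    subject: str
    group: str
    sex: str
    body_weight: float
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"subject {self.subject!r}: unknown group {self.group!r} "
                f"(expected one of {GROUPS})"
            )
        if self.sex not in ("M", "F"):
            raise ValidationError(
                f"subject {self.subject!r}: unknown sex {self.sex!r} (expected M or F)"
            )
        if not self.body_weight > 0:
            raise ValidationError(
                f"subject {self.subject!r}: body_weight must be > 0, "
                f"got {self.body_weight}"
            )


@dataclass
class RunConfig:
    """Run-wide parameters, with the study's fixed constants as defaults.

    Defaults: 0.008-0.2 Hz passband, order-2 Butterworth applied
    forward-backward, 0.3 mm FWHM smoothing, edge-discrimination threshold
    R^2 > 0.2, angiogram intensity thresholds 7000/7500/8000, TR 1.8 s,
    pooled-variance two-sample t-tests.
    """

    passband: tuple[float, float] = (0.008, 0.2)
    filter_order: int = 2
    smoothing_fwhm: float = 0.3
    edge_r2_threshold: float = 0.2
    vascular_thresholds: tuple[float, ...] = (7000.0, 7500.0, 8000.0)
    ttest_variance_mode: str = "pooled"
    tr: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.passband
        nyquist = 1.0 / (2.0 * self.tr)
        if not (0 < low < high < nyquist):
            raise ValidationError(
                f"passband {self.passband} infeasible: need 0 < low < high < "
                f"Nyquist ({nyquist:.4g} Hz at TR {self.tr} s)"
            )
        if self.filter_order < 1:
            raise ValidationError("filter_order must be >= 1")
        if self.smoothing_fwhm < 0:
            raise ValidationError("smoothing_fwhm must be >= 0")
        if not 0 < self.edge_r2_threshold < 1:
            raise ValidationError("edge_r2_threshold must lie in (0, 1)")
        if self.ttest_variance_mode not in ("pooled", "welch"):
            raise ValidationError(
                f"unknown ttest_variance_mode {self.ttest_variance_mode!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config; omitted fields keep the study defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "passband" in raw:
            raw["passband"] = tuple(raw["passband"])
        if "vascular_thresholds" in raw:
            raw["vascular_thresholds"] = tuple(raw["vascular_thresholds"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["passband"] = list(self.passband)
        d["vascular_thresholds"] = list(self.vascular_thresholds)
        return d


# ---------------------------------------------------------------------------
# NIfTI volumes


def _nifti_affine(voxel_dims: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_dims
    return aff


def read_volume(path: str | Path) -> VolumeImage:
    """Read a 3D NIfTI volume."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionError(
            f"{path}: expected a 3D volume, found {data.ndim}D"
        )
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel dimensions {zooms}")
    return VolumeImage(data=np.asarray(data, dtype=np.float64), voxel_dims=zooms)


def read_bold(path: str | Path, tr: float | None = None) -> BoldImage:
    """Read a 4D BOLD NIfTI.

    TR is taken from the header's time-axis spacing; an explicit ``tr``
    overrides it (a mismatch is logged and the override wins).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise DimensionError(
            f"{path}: expected a 4D BOLD image, found {data.ndim}D"
        )
    zooms = img.header.get_zooms()
    if any(z <= 0 for z in zooms[:3]):
        raise FormatError(f"{path}: non-positive voxel dimensions {zooms[:3]}")
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr is None:
        if header_tr <= 0:
            raise FormatError(
                f"{path}: header TR is {header_tr}; pass tr= explicitly"
            )
        tr = header_tr
    elif header_tr > 0 and not np.isclose(header_tr, tr):
        log.warning(
            "%s: header TR %.4g s differs from configured TR %.4g s; using config",
            path, header_tr, tr,
        )
    return BoldImage(
        data=np.asarray(data, dtype=np.float64), voxel_dims=zooms[:3], tr=tr
    )


def write_volume(vol: VolumeImage, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32),
                          _nifti_affine(vol.voxel_dims))
    img.header.set_zooms(vol.voxel_dims)
    nib.save(img, str(path))


def write_labels(atlas: AtlasLabelImage, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(atlas.labels, dtype=np.int32),
                          _nifti_affine(atlas.voxel_dims))
    img.header.set_zooms(atlas.voxel_dims)
    nib.save(img, str(path))


def write_bold(bold: BoldImage, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(bold.data, dtype=np.float32),
                          _nifti_affine(bold.voxel_dims))
    img.header.set_zooms(bold.voxel_dims + (bold.tr,))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Tables


def validate_region_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a region lookup table and normalise dtypes."""
    table = table.copy()
    missing = [c for c in REGION_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"region table missing columns: {missing}")
    if len(table) == 0:
        raise ValidationError("region table is empty")
    table["label"] = table["label"].astype(int)
    dup = table["label"][table["label"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate label ids in region table: {sorted(set(dup))}")
    bad_hemi = ~table["hemisphere"].isin(HEMISPHERES)
    if bad_hemi.any():
        row = table.index[bad_hemi][0]
        raise ValidationError(
            f"region table row {row}: unknown hemisphere "
            f"{table.loc[row, 'hemisphere']!r} (expected one of {HEMISPHERES})"
        )
    bad_scale = ~table["scale"].isin(ATLAS_SCALES)
    if bad_scale.any():
        row = table.index[bad_scale][0]
        raise ValidationError(
            f"region table row {row}: unknown scale {table.loc[row, 'scale']!r}"
        )
    if "is_ventricle" not in table.columns:
        table["is_ventricle"] = False
    table["is_ventricle"] = table["is_ventricle"].astype(bool)
    return table.reset_index(drop=True)


def read_region_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a region lookup CSV."""
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty region table file") from None
    return validate_region_table(table)


def write_region_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_region_table(table).to_csv(path, index=False)


def read_subject_meta(path: str | Path) -> list[SubjectMeta]:
    """Read and validate a subject metadata CSV."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty subject metadata file") from None
    missing = [c for c in SUBJECT_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"subject metadata missing columns: {missing}")
    if df["subject"].duplicated().any():
        dups = df["subject"][df["subject"].duplicated()].tolist()
        raise ValidationError(f"duplicate subject ids: {dups}")
    metas = []
    for _, row in df.iterrows():
        metas.append(
            SubjectMeta(
                subject=str(row["subject"]),
                group=str(row["group"]),
                sex=str(row["sex"]),
                body_weight=float(row["body_weight"]),
                excluded=bool(row["excluded"]) if "excluded" in df.columns else False,
            )
        )
    return metas


def write_subject_meta(metas: Sequence[SubjectMeta], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(m) for m in metas]).to_csv(path, index=False)


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular output as CSV with a header row."""
    rows.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_matrix(matrix: np.ndarray, region_ids: Sequence[int],
                 path: str | Path) -> None:
    """Persist a square region-by-region matrix with region-id headers."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise DimensionError(f"expected a square matrix, got shape {matrix.shape}")
    if matrix.shape[0] != len(region_ids):
        raise DimensionError(
            f"matrix of size {matrix.shape[0]} vs {len(region_ids)} region ids"
        )
    df = pd.DataFrame(matrix, index=list(region_ids), columns=list(region_ids))
    df.to_csv(path, index_label="region", float_format="%.15g")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[int]]:
    df = pd.read_csv(path, index_col=0)
    ids = [int(c) for c in df.columns]
    return df.to_numpy(dtype=np.float64), ids


def write_json_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
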