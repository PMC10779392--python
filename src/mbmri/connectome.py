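"""Region time-series extraction and per-subject functional connectomes.

A connectome is the matrix of Pearson correlations of the BOLD signal between
all pairs of atlas regions in one subject.  Edges are canonically vectorised
as the strict upper triangle in row-major order over the fixed region
ordering, each tagged intra-left / intra-right / inter-hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, DimensionError, ValidationError
from .io_formats import AtlasLabelImage, BoldImage

EDGE_CLASSES = ("intra-left", "intra-right", "inter-hemisphere")


@dataclass
class RegionTimeSeriesSet:
    """One subject's region-averaged BOLD series (frames x regions)."""

    data: np.ndarray
    region_ids: np.ndarray
    subject: str
    group: str
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        if self.data.ndim != 2:
            raise DimensionError("region series must be a frames x regions matrix")
        if self.data.shape[1] != len(self.region_ids):
            raise DimensionError(
                f"{self.data.shape[1]} series vs {len(self.region_ids)} region ids"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class Connectome:
    """Symmetric region-by-region Pearson correlation matrix of one subject."""

    matrix: np.ndarray
    region_ids: np.ndarray
    subject: str
    group: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise DimensionError(f"connectome must be square, got {m.shape}")
        if m.shape[0] != len(self.region_ids):
            raise DimensionError("region id count does not match matrix size")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValidationError("connectome matrix is not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValidationError("connectome diagonal must be exactly 1")
        if np.any(np.abs(m) > 1 + 1e-10):
            raise ValidationError("correlations must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


@dataclass
class EdgeVector:
    """Canonical edge vectorisation of a connectome.

    ``values[k]`` is the correlation of edge k where edges enumerate the
    strict upper triangle row-major; ``pairs[k] = (i, j)`` with i < j indexes
    into the region ordering, and ``classes[k]`` is the hemisphere class.
    """

    values: np.ndarray
    pairs: np.ndarray          # (E, 2) int
    classes: np.ndarray        # (E,) str
    region_ids: np.ndarray

    @property
    def n_edges(self) -> int:
        return len(self.values)


def edge_pairs(n_regions: int) -> np.ndarray:
    """Strict upper-triangle (i, j) index pairs in row-major order."""
    iu = np.triu_indices(n_regions, k=1)
    return np.column_stack(iu)


def n_edges(n_regions: int) -> int:
    return n_regions * (n_regions - 1) // 2


def extract_region_timeseries(
    bold: BoldImage,
    atlas: AtlasLabelImage,
    subject: str = "",
    group: str = "control",
) -> RegionTimeSeriesSet:
    """Average the BOLD series over each atlas region (unweighted voxel mean)."""
    if bold.spatial_shape != atlas.labels.shape:
        raise DimensionError(
            f"BOLD spatial grid {bold.spatial_shape} does not match atlas grid "
            f"{atlas.labels.shape}"
        )
    labels_flat = atlas.labels.reshape(-1)
    series_flat = bold.data.reshape(-1, bold.n_frames)
    region_ids = atlas.region_table["label"].to_numpy()
    out = np.empty((bold.n_frames, len(region_ids)))
    for k, rid in enumerate(region_ids):
        sel = labels_flat == rid
        if not sel.any():
            raise ValidationError(
                f"region {rid} has zero voxels in the label grid"
            )
        out[:, k] = series_flat[sel].mean(axis=0)
    return RegionTimeSeriesSet(
        data=out, region_ids=region_ids, subject=subject, group=group, tr=bold.tr
    )


def compute_connectome(rts: RegionTimeSeriesSet) -> Connectome:
    """Pairwise Pearson correlation of the region series."""
    if rts.n_frames < 3:
        raise DegenerateDataError(
            f"need >= 3 frames to correlate, got {rts.n_frames}"
        )
    sd = rts.data.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if len(constant):
        raise DegenerateDataError(
            f"constant-in-time series for region(s) "
            f"{rts.region_ids[constant].tolist()}"
        )
    m = np.corrcoef(rts.data, rowvar=False)
    m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return Connectome(
        matrix=m, region_ids=rts.region_ids, subject=rts.subject, group=rts.group
    )


def _hemisphere_lookup(region_table: pd.DataFrame) -> dict[int, str]:
    return dict(zip(region_table["label"].astype(int), region_table["hemisphere"]))


def edge_classes(region_ids: Sequence[int], region_table: pd.DataFrame) -> np.ndarray:
    """Hemisphere class of each canonical edge."""
    hemi = _hemisphere_lookup(region_table)
    pairs = edge_pairs(len(region_ids))
    ids = np.asarray(region_ids)
    out = np.empty(len(pairs), dtype=object)
    for k, (i, j) in enumerate(pairs):
        hi, hj = hemi[int(ids[i])], hemi[int(ids[j])]
        if hi != hj:
            out[k] = "inter-hemisphere"
        else:
            out[k] = f"intra-{hi}"
    return out.astype(str)


def vectorize_edges(conn: Connectome, region_table: pd.DataFrame) -> EdgeVector:
    """Canonical strict-upper-triangle edge vector with hemisphere classes."""
    pairs = edge_pairs(conn.n_regions)
    values = conn.matrix[pairs[:, 0], pairs[:, 1]]
    classes = edge_classes(conn.region_ids, region_table)
    return EdgeVector(
        values=values, pairs=pairs, classes=classes, region_ids=conn.region_ids
    )


def devectorize_edges(edges: EdgeVector) -> np.ndarray:
    """Rebuild the symmetric unit-diagonal matrix from an edge vector."""
    n = len(edges.region_ids)
    m = np.eye(n)
    m[edges.pairs[:, 0], edges.pairs[:, 1]] = edges.values
    m[edges.pairs[:, 1], edges.pairs[:, 0]] = edges.values
    return m


def upper_triangle_values(matrix: np.ndarray) -> np.ndarray:
    """Strict upper triangle of a square matrix in canonical edge order."""
    iu = np.triu_indices(matrix.shape[0], k=1)
    return np.asarray(matrix)[iu]


def connectome_similarity(c1: Connectome, c2: Connectome) -> tuple[float, float, float]:
    """Pearson similarity of two connectomes across their edge vectors.

    Returns (r, R^2, two-sided p) with p from the t-transform at
    df = E - 2 edges.
    """
    if not np.array_equal(c1.region_ids, c2.region_ids):
        raise ValidationError("connectomes have different region orderings")
    v1 = upper_triangle_values(c1.matrix)
    v2 = upper_triangle_values(c2.matrix)
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise DegenerateDataError("zero-variance edge vector")
    res = stats.pearsonr(v1, v2)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)
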