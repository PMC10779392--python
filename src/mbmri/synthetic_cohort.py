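"""Synthetic cohorts with planted, recoverable structure.

Every generator pairs its output with ground truth so each downstream stage
can be verified without real data:

* BOLD-like region time series whose population correlation is a shared base
  connectome plus a subject-identity edge pattern plus a group-effect edge
  pattern, with additive observation noise;
* mirrored labelled brain phantoms with per-group volume scalings (global
  shrinkage, medulla-like enlargement);
* angiogram phantoms with cylindrical vessels of known lumen over a noisy
  background;
* two-group univariate morphometry samples.

All generators are deterministic given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import RegionTimeSeriesSet, edge_pairs, n_edges
from .errors import GenerationError, ValidationError
from .io_formats import AtlasLabelImage, BoldImage, SubjectMeta, VolumeImage

# 14 coarse-scale regions per hemisphere; ventricles are a flagged label so
# tissue totals can exclude the fluid compartment.
COARSE_REGIONS = (
    ("olfactory_bulb", "forebrain"),
    ("olfactory_cortex", "forebrain"),
    ("isocortex", "forebrain"),
    ("hippocampus", "forebrain"),
    ("striatum", "forebrain"),
    ("pallidum", "forebrain"),
    ("thalamus", "forebrain"),
    ("hypothalamus", "forebrain"),
    ("midbrain", "brainstem"),
    ("pons", "brainstem"),
    ("medulla", "brainstem"),
    ("cerebellar_cortex", "cerebellum"),
    ("cerebellar_nuclei", "cerebellum"),
    ("ventricles", "ventricular"),
)


def default_region_table(n_per_hemisphere: int = 14, scale: str = "coarse") -> pd.DataFrame:
    """Mirrored left/right region lookup table.

    For the default 14 regions per hemisphere the canonical coarse-scale
    names are used; other sizes get systematic names cycled over the same
    macro-regions.
    """
    rows = []
    for h_idx, hemi in enumerate(("left", "right")):
        for i in range(n_per_hemisphere):
            if n_per_hemisphere == len(COARSE_REGIONS):
                name, macro = COARSE_REGIONS[i]
            else:
                name = f"region_{i + 1:03d}"
                macro = COARSE_REGIONS[i % len(COARSE_REGIONS)][1]
            rows.append(
                {
                    "label": h_idx * n_per_hemisphere + i + 1,
                    "name": f"{hemi}_{name}",
                    "hemisphere": hemi,
                    "macro_region": macro,
                    "scale": scale,
                    "is_ventricle": name == "ventricles",
                }
            )
    return pd.DataFrame(rows)


def project_to_correlation(matrix: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Repair a symmetric matrix into a valid correlation matrix.

    Eigenvalues are clipped at ``floor`` and the diagonal renormalised to 1.
    """
    m = np.asarray(matrix, dtype=np.float64)
    m = (m + m.T) / 2.0
    vals, vecs = np.linalg.eigh(m)
    if not np.all(np.isfinite(vals)):
        raise GenerationError("eigendecomposition failed on target matrix")
    vals = np.clip(vals, floor, None)
    m = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(m))
    if np.any(d <= 0):
        raise GenerationError("target matrix not repairable to positive-definite")
    m = m / np.outer(d, d)
    m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return m


def default_base_connectome(region_table: pd.DataFrame,
                            shrink: float = 0.6) -> np.ndarray:
    """Structured base connectome C0: macro-region blocks plus elevated
    homotopic (left/right mirror) correlations over a weak global baseline.

    Off-diagonals are shrunk by ``shrink`` so C0 keeps a comfortable
    smallest eigenvalue; planted edge perturbations then leave the matrix
    positive definite and the positive-definiteness repair is a no-op, i.e.
    the realised targets carry exactly the planted effects.
    """
    n = len(region_table)
    names = [nm.split("_", 1)[1] for nm in region_table["name"]]
    macro = region_table["macro_region"].to_numpy()
    hemi = region_table["hemisphere"].to_numpy()
    c = np.full((n, n), 0.10)
    for i in range(n):
        for j in range(n):
            if macro[i] == macro[j]:
                c[i, j] = 0.30 if hemi[i] != hemi[j] else 0.45
            if names[i] == names[j] and hemi[i] != hemi[j]:
                c[i, j] = 0.60
    c *= shrink
    np.fill_diagonal(c, 1.0)
    return project_to_correlation(c)


@dataclass
class SyntheticCohortSpec:
    """Full parameterisation of a synthetic BOLD cohort.

    Cohort geometry mirrors the study: 5 control + 7 conditional-knockout
    subjects, 28 regions (14 per hemisphere), 1002 frames (3 runs of 334
    repetitions) at TR 1.8 s.  ``group_effect`` is a signed correlation
    offset planted on ``group_edge_set`` in the cKO group only;
    ``subject_effect_sd`` scales zero-mean per-subject draws on
    ``subject_edge_set`` (the same edge set in both groups, which is what
    makes within-group difference patterns correlate across groups).
    """

    n_control: int = 5
    n_cko: int = 7
    n_regions: int = 28
    n_frames: int = 1002
    tr: float = 1.8
    base_connectome: np.ndarray | None = None
    subject_edge_set: np.ndarray | None = None
    subject_effect_sd: float = 0.15
    n_subject_edges: int = 20
    group_edge_set: np.ndarray | None = None
    group_effect: float = 0.3
    n_group_edges: int = 10
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_cko < 1:
            raise ValidationError("need at least one subject per group")
        if self.n_regions < 2 or self.n_regions % 2:
            raise ValidationError("n_regions must be an even count >= 2")
        if self.n_frames <= self.n_regions:
            raise ValidationError("n_frames must exceed n_regions")
        if self.noise_sd < 0 or self.subject_effect_sd < 0:
            raise ValidationError("noise/effect standard deviations must be >= 0")

    @property
    def n_subjects(self) -> int:
        return self.n_control + self.n_cko

    @property
    def region_table(self) -> pd.DataFrame:
        return default_region_table(self.n_regions // 2)

    def resolved(self) -> "SyntheticCohortSpec":
        """Fill in the derived fields (C0 and edge sets) deterministically."""
        e = n_edges(self.n_regions)
        rng = np.random.default_rng(self.seed)
        c0 = self.base_connectome
        if c0 is None:
            c0 = default_base_connectome(self.region_table)
        c0 = np.asarray(c0, dtype=np.float64)
        if c0.shape != (self.n_regions, self.n_regions):
            raise ValidationError(
                f"base connectome shape {c0.shape} vs n_regions {self.n_regions}"
            )
        # Default edge sets are sampled with a node-degree cap (the group set
        # is a matching) so the planted perturbations keep a small spectral
        # norm: C0 plus the group offset then stays positive definite and the
        # repair never distorts off-target edges systematically.
        pairs = edge_pairs(self.n_regions)

        def _sample_capped(pool: np.ndarray, size: int, cap: int) -> np.ndarray:
            degree = np.zeros(self.n_regions, dtype=int)
            chosen: list[int] = []
            for k in rng.permutation(pool):
                i, j = pairs[k]
                if degree[i] < cap and degree[j] < cap:
                    chosen.append(int(k))
                    degree[i] += 1
                    degree[j] += 1
                    if len(chosen) == size:
                        break
            if len(chosen) < size:     # fall back for dense requests
                rest = np.setdiff1d(pool, chosen)
                chosen.extend(
                    int(v) for v in
                    rng.choice(rest, size=size - len(chosen), replace=False)
                )
            return np.asarray(chosen, dtype=int)

        subj = self.subject_edge_set
        if subj is None:
            subj = _sample_capped(np.arange(e), min(self.n_subject_edges, e),
                                  cap=2)
        subj = np.sort(np.asarray(subj, dtype=int))
        grp = self.group_edge_set
        if grp is None:
            pool = np.setdiff1d(np.arange(e), subj)
            grp = _sample_capped(pool, min(self.n_group_edges, len(pool)),
                                 cap=1)
        grp = np.sort(np.asarray(grp, dtype=int))
        if subj.size and (subj.min() < 0 or subj.max() >= e):
            raise ValidationError("subject_edge_set indices out of range")
        if grp.size and (grp.min() < 0 or grp.max() >= e):
            raise ValidationError("group_edge_set indices out of range")
        return replace(self, base_connectome=c0, subject_edge_set=subj,
                       group_edge_set=grp)


@dataclass
class CohortGroundTruth:
    """Everything planted into a synthetic cohort, for verification."""

    spec: SyntheticCohortSpec
    subjects: list[SubjectMeta]
    target_connectomes: dict[str, np.ndarray] = field(default_factory=dict)
    subject_edge_set: np.ndarray | None = None
    group_edge_set: np.ndarray | None = None
    group_edge_signs: np.ndarray | None = None
    region_volumes: pd.DataFrame | None = None
    lumen_voxel_count: int | None = None


def _edge_matrix(n_regions: int, edge_idx: np.ndarray,
                 values: np.ndarray) -> np.ndarray:
    """Symmetric zero-diagonal matrix with ``values`` on the given canonical
    edges."""
    pairs = edge_pairs(n_regions)[edge_idx]
    m = np.zeros((n_regions, n_regions))
    m[pairs[:, 0], pairs[:, 1]] = values
    m[pairs[:, 1], pairs[:, 0]] = values
    return m


def cohort_subject_meta(spec: SyntheticCohortSpec,
                        rng: np.random.Generator) -> list[SubjectMeta]:
    """Subject ids, groups, alternating sexes and plausible body weights
    (34 +/- 3 g)."""
    metas = []
    for g, count in (("control", spec.n_control), ("cko", spec.n_cko)):
        for i in range(count):
            metas.append(
                SubjectMeta(
                    subject=f"{g}-{i + 1:02d}",
                    group=g,
                    sex="M" if (len(metas) % 2 == 0) else "F",
                    body_weight=float(np.clip(rng.normal(34.0, 3.0), 20.0, None)),
                )
            )
    return metas


def simulate_bold_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[RegionTimeSeriesSet], CohortGroundTruth]:
    """Draw region time series for every subject of a synthetic cohort.

    Subject i's target correlation is

        T_i = project_to_correlation(C0 + b_i on M_subj + [cko] * delta on M_grp)

    with b_i ~ N(0, subject_effect_sd) drawn per subject on the subject edge
    set.  Series are drawn as Gaussian frames with population correlation
    T_i (Cholesky factor), plus independent N(0, noise_sd) observation noise
    per sample.  With unit-variance signals the noise attenuates observed
    correlations by the factor 1 / (1 + noise_sd^2).
    """
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    metas = cohort_subject_meta(spec, rng)
    region_ids = spec.region_table["label"].to_numpy()

    delta = _edge_matrix(
        spec.n_regions, spec.group_edge_set,
        np.full(len(spec.group_edge_set), spec.group_effect),
    )
    truth = CohortGroundTruth(
        spec=spec,
        subjects=metas,
        subject_edge_set=spec.subject_edge_set,
        group_edge_set=spec.group_edge_set,
        group_edge_signs=np.full(len(spec.group_edge_set),
                                 int(np.sign(spec.group_effect)) or 1),
    )

    cohort = []
    for meta in metas:
        b_i = rng.normal(0.0, spec.subject_effect_sd,
                         size=len(spec.subject_edge_set))
        target = spec.base_connectome + _edge_matrix(
            spec.n_regions, spec.subject_edge_set, b_i
        )
        if meta.group == "cko":
            target = target + delta
        try:
            target = project_to_correlation(target)
        except GenerationError as exc:
            raise GenerationError(
                f"subject {meta.subject}: {exc}"
            ) from exc
        chol = np.linalg.cholesky(target)
        z = rng.standard_normal((spec.n_frames, spec.n_regions))
        signal = z @ chol.T
        if spec.noise_sd > 0:
            signal = signal + rng.normal(
                0.0, spec.noise_sd, size=signal.shape
            )
        truth.target_connectomes[meta.subject] = target
        cohort.append(
            RegionTimeSeriesSet(
                data=signal, region_ids=region_ids, subject=meta.subject,
                group=meta.group, tr=spec.tr,
            )
        )
    return cohort, truth


def paint_bold_phantom(
    rts: RegionTimeSeriesSet,
    atlas: AtlasLabelImage,
    voxel_noise_sd: float = 0.0,
    seed: int = 0,
) -> BoldImage:
    """Voxel-level mode: paint each region's series onto its phantom voxels,
    plus independent voxel noise, so voxelwise preprocessing is exercisable
    end to end."""
    rng = np.random.default_rng(seed)
    shape = atlas.labels.shape + (rts.n_frames,)
    data = np.zeros(shape)
    for k, rid in enumerate(rts.region_ids):
        sel = atlas.labels == rid
        data[sel] = rts.data[:, k]
    if voxel_noise_sd > 0:
        data[atlas.labels > 0] += rng.normal(
            0.0, voxel_noise_sd, size=(int((atlas.labels > 0).sum()), rts.n_frames)
        )
    return BoldImage(data=data, voxel_dims=atlas.voxel_dims, tr=rts.tr)


# ---------------------------------------------------------------------------
# Labelled brain phantoms


def default_group_scalings() -> dict[str, float]:
    """Per-region cKO volume scalings: global shrinkage with a medulla-like
    enlargement; the fluid compartment is left untouched."""
    scalings = {name: 0.85 for name, _ in COARSE_REGIONS}
    scalings["medulla"] = 1.2
    scalings["ventricles"] = 1.0
    return scalings


def make_atlas_phantom(
    n_regions_per_hemisphere: int = 14,
    voxel_dims: tuple[float, float, float] = (0.2, 0.2, 0.2),
    group_scalings: dict[str, float] | None = None,
    seed: int = 0,
    n_control: int = 5,
    n_cko: int = 7,
    jitter_sd: float = 0.02,
    base_voxels: Sequence[int] | None = None,
) -> tuple[dict[str, AtlasLabelImage], pd.DataFrame, list[SubjectMeta]]:
    """Mirrored labelled phantoms with planted per-group volume effects.

    Per subject, region voxel counts are base counts x group scaling (cKO
    only) x a per-subject multiplicative jitter shared between hemispheres,
    so left/right blocks stay exact mirrors.  Returns the label images, a
    truth table (subject, label, voxels, volume_mm3 = count x voxel volume)
    and the subject metadata.
    """
    if group_scalings is None:
        group_scalings = default_group_scalings()
    if any(s <= 0 for s in group_scalings.values()):
        raise ValidationError("group scalings must be positive")
    table = default_region_table(n_regions_per_hemisphere)
    names = [nm.split("_", 1)[1] for nm in table["name"][:n_regions_per_hemisphere]]
    if base_voxels is None:
        base_voxels = [260 + 28 * i for i in range(n_regions_per_hemisphere)]
    base_voxels = np.asarray(base_voxels, dtype=float)
    if len(base_voxels) != n_regions_per_hemisphere:
        raise ValidationError("base_voxels length must match regions per hemisphere")

    rng = np.random.default_rng(seed)
    spec = SyntheticCohortSpec(n_control=n_control, n_cko=n_cko,
                               n_regions=2 * n_regions_per_hemisphere)
    metas = cohort_subject_meta(spec, rng)

    # target voxel counts per (subject, region-name), shared across hemispheres
    counts: dict[str, np.ndarray] = {}
    for meta in metas:
        jit = 1.0 + rng.normal(0.0, jitter_sd, size=n_regions_per_hemisphere)
        jit = np.clip(jit, 0.5, None)
        scale = np.array(
            [group_scalings.get(nm, 1.0) if meta.group == "cko" else 1.0
             for nm in names]
        )
        counts[meta.subject] = np.maximum(
            1, np.round(base_voxels * scale * jit)
        ).astype(int)

    max_half = max(int(c.sum()) for c in counts.values())
    side = int(np.ceil((max_half * 1.4) ** (1.0 / 3.0)))
    half_shape = (side, side, side)
    if side ** 3 < max_half:
        raise GenerationError("phantom grid too small for requested volumes")

    images: dict[str, AtlasLabelImage] = {}
    truth_rows = []
    voxvol = float(np.prod(voxel_dims))
    for meta in metas:
        left = np.zeros(side ** 3, dtype=np.int32)
        pos = 0
        for i, c in enumerate(counts[meta.subject]):
            left[pos:pos + c] = i + 1
            pos += c
        left = left.reshape(half_shape)
        right = left[::-1, :, :].copy()
        right[right > 0] += n_regions_per_hemisphere
        full = np.concatenate([left, right], axis=0)
        images[meta.subject] = AtlasLabelImage(
            labels=full, voxel_dims=voxel_dims, region_table=table
        )
        for h_idx in range(2):
            for i, c in enumerate(counts[meta.subject]):
                truth_rows.append(
                    {
                        "subject": meta.subject,
                        "label": h_idx * n_regions_per_hemisphere + i + 1,
                        "voxels": int(c),
                        "volume_mm3": c * voxvol,
                    }
                )
    truth = pd.DataFrame(truth_rows)
    return images, truth, metas


# ---------------------------------------------------------------------------
# Angiogram phantoms


@dataclass
class TubeSpec:
    """A cylindrical vessel in voxel coordinates: ``start`` point, ``direction``
    (need not be normalised), ``length`` and ``radius`` in voxel units."""

    start: tuple[float, float, float]
    direction: tuple[float, float, float]
    length: float
    radius: float


def rasterize_tubes(grid: tuple[int, int, int],
                    tubes: Sequence[TubeSpec]) -> np.ndarray:
    """Boolean lumen mask: voxels whose centre lies within ``radius`` of a
    tube's axis segment."""
    coords = np.stack(
        np.meshgrid(*[np.arange(g, dtype=float) for g in grid], indexing="ij"),
        axis=-1,
    )
    mask = np.zeros(grid, dtype=bool)
    for tube in tubes:
        p0 = np.asarray(tube.start, dtype=float)
        d = np.asarray(tube.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValidationError("tube direction must be nonzero")
        d = d / norm
        rel = coords - p0
        t = rel @ d
        radial = np.linalg.norm(rel - t[..., None] * d, axis=-1)
        # flat end caps: axial extent [0, length], radial extent <= radius
        mask |= (t >= 0.0) & (t <= tube.length) & (radial <= tube.radius)
    return mask


def simulate_angiogram(
    grid: tuple[int, int, int],
    voxel_dims: tuple[float, float, float],
    tube_specs: Sequence[TubeSpec],
    background_level: float = 6000.0,
    vessel_level: float = 9000.0,
    noise_sd: float = 100.0,
    seed: int = 0,
) -> tuple[VolumeImage, int]:
    """Angiography phantom: tubes at ``vessel_level`` over a noisy background.

    Returns the intensity volume and the true lumen voxel count.
    """
    if not vessel_level > background_level:
        raise ValidationError("vessel_level must exceed background_level")
    rng = np.random.default_rng(seed)
    lumen = rasterize_tubes(grid, tube_specs)
    data = np.full(grid, background_level, dtype=np.float64)
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=grid)
    data[lumen] = vessel_level
    return VolumeImage(data=data, voxel_dims=voxel_dims), int(lumen.sum())


# ---------------------------------------------------------------------------
# Morphometry samples


def simulate_morphometry(
    mean_control: float,
    mean_ko: float,
    sd: float,
    n_per_group: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent normal samples (e.g. tadpole ventricular lengths)."""
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    control = rng.normal(mean_control, sd, size=n_per_group)
    ko = rng.normal(mean_ko, sd, size=n_per_group)
    return control, ko
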