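"""Atlas-based regional and total brain volumetry with group comparisons.

Volumes are voxel counts times voxel volume on pre-labelled grids.
Ventricle-flagged regions are excluded from "brain tissue" totals and
reported separately, so the tissue/fluid compartments can be compared
independently.  Normalisations: mm^3/g by body weight, or unitless fraction
of total brain volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .group_stats import two_sample_ttest
from .io_formats import AtlasLabelImage, SubjectMeta

log = logging.getLogger("mbmri")


@dataclass
class VolumetryTable:
    """Per-subject per-region volumes plus per-subject totals.

    ``regions``: columns (subject, label, name, is_ventricle, voxels,
    volume_mm3).  ``subjects``: columns (subject, brain_volume_mm3,
    ventricular_volume_mm3, body_weight_g).
    """

    regions: pd.DataFrame
    subjects: pd.DataFrame


def region_volumes(
    atlases: dict[str, AtlasLabelImage],
    metas: Sequence[SubjectMeta] | None = None,
) -> VolumetryTable:
    """Measure every region's volume for every subject.

    Total brain volume counts all labelled non-ventricle voxels; ventricle
    labels are totalled separately.  A region present in the table but
    absent from a grid gets a warning and zero volume.
    """
    weights = {m.subject: m.body_weight for m in metas} if metas else {}
    region_rows, subject_rows = [], []
    for subject, atlas in atlases.items():
        voxvol = atlas.voxel_volume
        counts = np.bincount(
            atlas.labels.reshape(-1),
            minlength=int(atlas.region_table["label"].max()) + 1,
        )
        brain = 0.0
        ventricular = 0.0
        for _, row in atlas.region_table.iterrows():
            label = int(row["label"])
            n_vox = int(counts[label]) if label < len(counts) else 0
            if n_vox == 0:
                log.warning(
                    "subject %s: region %d (%s) absent from label grid; "
                    "volume 0", subject, label, row["name"],
                )
            vol = n_vox * voxvol
            if row["is_ventricle"]:
                ventricular += vol
            else:
                brain += vol
            region_rows.append(
                {
                    "subject": subject,
                    "label": label,
                    "name": row["name"],
                    "is_ventricle": bool(row["is_ventricle"]),
                    "voxels": n_vox,
                    "volume_mm3": vol,
                }
            )
        subject_rows.append(
            {
                "subject": subject,
                "brain_volume_mm3": brain,
                "ventricular_volume_mm3": ventricular,
                "body_weight_g": weights.get(subject, np.nan),
            }
        )
    return VolumetryTable(
        regions=pd.DataFrame(region_rows), subjects=pd.DataFrame(subject_rows)
    )


def normalize_volumes(table: VolumetryTable, mode: str) -> pd.DataFrame:
    """Normalised per-region volumes.

    ``body_weight``: mm^3 per gram.  ``total_brain``: unitless fraction of
    the subject's brain tissue volume (ventricles excluded from the
    denominator).
    """
    if mode not in ("body_weight", "total_brain"):
        raise ValidationError(f"unknown normalization mode {mode!r}")
    out = table.regions.merge(table.subjects, on="subject")
    if mode == "body_weight":
        bad = out["body_weight_g"].isna() | (out["body_weight_g"] <= 0)
        if bad.any():
            subj = out.loc[bad, "subject"].iloc[0]
            raise ValidationError(
                f"subject {subj!r}: zero or missing body weight"
            )
        out["normalized"] = out["volume_mm3"] / out["body_weight_g"]
    else:
        bad = out["brain_volume_mm3"] <= 0
        if bad.any():
            subj = out.loc[bad, "subject"].iloc[0]
            raise ValidationError(f"subject {subj!r}: zero brain volume")
        out["normalized"] = out["volume_mm3"] / out["brain_volume_mm3"]
    return out[["subject", "label", "name", "is_ventricle", "volume_mm3",
                "normalized"]]


def percent_mean_difference(mean_ref: float, mean_alt: float) -> float:
    """Signed percent difference 100 (alt - ref) / ref, to one decimal."""
    if mean_ref == 0:
        raise ValidationError("zero reference mean")
    return round(100.0 * (mean_alt - mean_ref) / mean_ref, 1)


def group_volume_comparison(
    table: VolumetryTable,
    metas: Sequence[SubjectMeta],
    normalization: str | None = "total_brain",
    variance_mode: str = "pooled",
    group_by: str = "group",
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-region two-group comparison of (optionally normalised) volumes.

    Returns per region: group means, signed percent difference of the second
    group relative to the first, t, and two-sided p.  ``group_by`` may be
    ``group`` (control vs cko) or ``sex`` (M vs F) for the stratified
    variant.  No multiple-testing correction by default; ``fdr=True``
    appends Benjamini-Hochberg adjusted p-values.
    """
    if group_by == "group":
        labels = {m.subject: m.group for m in metas}
        level_a, level_b = "control", "cko"
    elif group_by == "sex":
        labels = {m.subject: m.sex for m in metas}
        level_a, level_b = "M", "F"
    else:
        raise ValidationError(f"unknown group_by {group_by!r}")

    if normalization is None:
        df = table.regions.copy()
        df["value"] = df["volume_mm3"]
    else:
        df = normalize_volumes(table, normalization)
        df["value"] = df["normalized"]
    df["grp"] = df["subject"].map(labels)
    if df["grp"].isna().any():
        missing = df.loc[df["grp"].isna(), "subject"].unique().tolist()
        raise ValidationError(f"subjects without metadata: {missing}")

    rows = []
    for label, sub in df.groupby("label", sort=True):
        a = sub.loc[sub["grp"] == level_a, "value"].to_numpy()
        b = sub.loc[sub["grp"] == level_b, "value"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValidationError(
                f"group with < 2 subjects for region {label}"
            )
        res = two_sample_ttest(a, b, variance_mode=variance_mode)
        rows.append(
            {
                "label": int(label),
                "name": sub["name"].iloc[0],
                f"mean_{level_a}": a.mean(),
                f"mean_{level_b}": b.mean(),
                "percent_difference": percent_mean_difference(a.mean(), b.mean())
                if a.mean() != 0 else np.nan,
                "t": res.statistic,
                "p": res.p,
            }
        )
    out = pd.DataFrame(rows)
    if fdr:
        log.info("applying Benjamini-Hochberg correction across regions")
        out["p_fdr"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
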