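"""Pairwise connectome difference matrices and group-discriminative networks.

The procedure characterises what distinguishes subjects: every connectome is
subtracted from every other, within group (control-control, cko-cko) and
between groups (oriented control - cko), yielding difference matrices.
Within/between-class similarity of those difference vectors separates a
subject-specific connectivity pattern (shared edge set on which individuals
differ, in both groups) from a group-specific pattern (edges that separate
control from conditional-knockout animals).  The group pattern is quantified
per edge as the squared point-biserial correlation between edge strength and
group membership, and binarised at a stated R^2 threshold into a
discriminative network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import Connectome, edge_classes, edge_pairs, upper_triangle_values
from .errors import DegenerateDataError, ValidationError
from .io_formats import SubjectMeta

log = logging.getLogger("mbmri")

COMPARISON_CLASSES = ("control-control", "cko-cko", "control-cko")


@dataclass
class DifferenceMatrixSet:
    """All pairwise connectome differences within one comparison class.

    Within-class pairs are unordered and counted once; between-class pairs
    are oriented control - cko.  ``diffs`` is pairs x edges in canonical edge
    order.
    """

    comparison: str
    pair_ids: list[tuple[str, str]]
    diffs: np.ndarray
    region_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.comparison not in COMPARISON_CLASSES:
            raise ValidationError(f"unknown comparison class {self.comparison!r}")
        self.diffs = np.atleast_2d(np.asarray(self.diffs, dtype=np.float64))
        if self.diffs.shape[0] != len(self.pair_ids):
            raise ValidationError("pair metadata does not match difference count")

    @property
    def n_pairs(self) -> int:
        return self.diffs.shape[0]


@dataclass
class ClassPattern:
    """Per-edge root-mean-square of difference values across a class's pairs."""

    comparison: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if (self.values < 0).any():
            raise ValidationError("RMS pattern must be non-negative")


@dataclass
class DiscriminativeNetwork:
    """Signed, binarised edge set distinguishing the groups.

    Edges are retained where the per-edge discrimination R^2 (squared
    point-biserial correlation between edge strength and group label across
    subjects) exceeds ``threshold``; sign +1 means higher synchrony in the
    conditional knockouts, -1 lower.
    """

    threshold: float
    edge_index: np.ndarray          # retained canonical edge indices
    r2: np.ndarray                  # R^2 of retained edges
    signs: np.ndarray               # +1 / -1 per retained edge
    pairs: np.ndarray               # (k, 2) region-order indices of retained edges
    region_ids: np.ndarray
    all_r2: np.ndarray = field(repr=False, default=None)

    @property
    def n_edges(self) -> int:
        return len(self.edge_index)

    @property
    def implicated_regions(self) -> np.ndarray:
        """Region ids touching at least one retained edge."""
        if self.n_edges == 0:
            return np.array([], dtype=int)
        idx = np.unique(self.pairs)
        return np.asarray(self.region_ids)[idx]


def exclude_flagged(
    connectomes: Sequence[Connectome], metas: Sequence[SubjectMeta]
) -> list[Connectome]:
    """Drop subjects flagged as excluded in the metadata before pairing."""
    dropped = {m.subject for m in metas if m.excluded}
    if dropped:
        log.info("excluding flagged subjects: %s", sorted(dropped))
    return [c for c in connectomes if c.subject not in dropped]


def difference_matrices(
    connectomes: Sequence[Connectome],
) -> dict[str, DifferenceMatrixSet]:
    """All pairwise difference vectors, split by comparison class."""
    groups = {"control": [], "cko": []}
    for c in connectomes:
        if c.group not in groups:
            raise ValidationError(f"unknown group {c.group!r}")
        groups[c.group].append(c)
    for g, members in groups.items():
        if len(members) < 2:
            raise ValidationError(
                f"group {g!r} has {len(members)} subject(s); need >= 2"
            )
    ref = connectomes[0].region_ids
    for c in connectomes:
        if not np.array_equal(c.region_ids, ref):
            raise ValidationError("connectomes have different region orderings")

    edges = {
        c.subject: upper_triangle_values(c.matrix) for c in connectomes
    }

    out: dict[str, DifferenceMatrixSet] = {}
    for comparison, members in (
        ("control-control", groups["control"]),
        ("cko-cko", groups["cko"]),
    ):
        pair_ids, diffs = [], []
        for a, b in combinations(members, 2):
            pair_ids.append((a.subject, b.subject))
            diffs.append(edges[a.subject] - edges[b.subject])
        out[comparison] = DifferenceMatrixSet(
            comparison=comparison, pair_ids=pair_ids,
            diffs=np.array(diffs), region_ids=ref,
        )
    pair_ids, diffs = [], []
    for a in groups["control"]:
        for b in groups["cko"]:
            pair_ids.append((a.subject, b.subject))
            diffs.append(edges[a.subject] - edges[b.subject])
    out["control-cko"] = DifferenceMatrixSet(
        comparison="control-cko", pair_ids=pair_ids,
        diffs=np.array(diffs), region_ids=ref,
    )
    return out


def _standardize_rows(m: np.ndarray) -> np.ndarray:
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise DegenerateDataError("degenerate pair: all-zero difference vector")
    return (m - mu) / sd


def pairwise_pattern_r2(
    set_a: DifferenceMatrixSet,
    set_b: DifferenceMatrixSet,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean squared Pearson correlation between difference vectors of two
    classes, with a permutation p-value.

    Every cross pair (one difference vector from each set) contributes one
    R^2; when both arguments are the same set, all distinct pairs of its
    vectors are used instead.  The null permutes edge labels of the second
    set's vectors (one shared permutation per draw) and recomputes the mean
    R^2; p = P(null >= observed) with the +1 correction.  Squaring makes the
    statistic invariant to pair orientation.
    """
    a = _standardize_rows(set_a.diffs)
    b = _standardize_rows(set_b.diffs)
    n_edges_ = a.shape[1]
    same = set_a is set_b

    def mean_r2(bm: np.ndarray) -> float:
        r = (a @ bm.T) / n_edges_
        if same:
            iu = np.triu_indices(r.shape[0], k=1)
            r = r[iu]
        return float(np.mean(r ** 2))

    observed = mean_r2(b)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n_edges_)
        if mean_r2(b[:, perm]) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return observed, p


def class_pattern(diffset: DifferenceMatrixSet) -> ClassPattern:
    """Per-edge RMS of difference values across the class's pairs
    (orientation-proof aggregate of what varies within the class)."""
    return ClassPattern(
        comparison=diffset.comparison,
        values=np.sqrt(np.mean(diffset.diffs ** 2, axis=0)),
    )


def class_pattern_correlation(
    pattern_a: ClassPattern, pattern_b: ClassPattern
) -> tuple[float, float, float]:
    """Pearson correlation across edges of two RMS class patterns.

    Returns (r, R^2, two-sided p) with p from the t-transform at
    df = E - 2.
    """
    va, vb = pattern_a.values, pattern_b.values
    if va.shape != vb.shape:
        raise ValidationError("patterns have different lengths")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise DegenerateDataError("constant class pattern")
    res = stats.pearsonr(va, vb)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def edge_group_r2(
    connectomes: Sequence[Connectome],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-edge discrimination R^2 and group mean difference.

    Returns (r2, mean_cko - mean_control, subject-by-edge matrix).  R^2 is
    the squared point-biserial correlation between edge strength and the
    binary group label across subjects; edges with zero variance across all
    subjects get R^2 = 0 with a logged warning.
    """
    y = np.array([1.0 if c.group == "cko" else 0.0 for c in connectomes])
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValidationError("need >= 2 subjects in each group")
    x = np.array([upper_triangle_values(c.matrix) for c in connectomes])
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    dead = sx == 0
    if dead.any():
        log.warning(
            "%d edge(s) have zero variance across subjects; assigned R^2 = 0",
            int(dead.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r = np.where(dead, 0.0, r)
    mean_diff = x[y == 1].mean(axis=0) - x[y == 0].mean(axis=0)
    return r ** 2, mean_diff, x


def group_discriminative_edges(
    connectomes: Sequence[Connectome],
    threshold: float = 0.2,
) -> DiscriminativeNetwork:
    """Binarise the per-edge discrimination pattern at R^2 > ``threshold``."""
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie in (0, 1)")
    r2, mean_diff, _ = edge_group_r2(connectomes)
    retained = np.flatnonzero(r2 > threshold)
    region_ids = connectomes[0].region_ids
    pairs = edge_pairs(len(region_ids))
    signs = np.sign(mean_diff[retained]).astype(int)
    signs[signs == 0] = 1
    return DiscriminativeNetwork(
        threshold=threshold,
        edge_index=retained,
        r2=r2[retained],
        signs=signs,
        pairs=pairs[retained],
        region_ids=np.asarray(region_ids),
        all_r2=r2,
    )


def map_edges_to_regions(
    net: DiscriminativeNetwork, region_table: pd.DataFrame
) -> pd.DataFrame:
    """Per macro-region tally of retained edges, split by sign and by
    hemisphere class."""
    macro = dict(
        zip(region_table["label"].astype(int), region_table["macro_region"])
    )
    classes = edge_classes(net.region_ids, region_table)
    rows: dict[str, dict] = {}
    for m in sorted(set(macro.values())):
        rows[m] = {
            "macro_region": m, "n_edges": 0, "n_increase": 0, "n_decrease": 0,
            "intra-left": 0, "intra-right": 0, "inter-hemisphere": 0,
        }
    for k, (i, j) in zip(net.edge_index, net.pairs):
        touched = {
            macro[int(net.region_ids[i])], macro[int(net.region_ids[j])]
        }
        for m in touched:
            row = rows[m]
            row["n_edges"] += 1
            sign = net.signs[np.flatnonzero(net.edge_index == k)[0]]
            row["n_increase" if sign > 0 else "n_decrease"] += 1
            row[classes[k]] += 1
    return pd.DataFrame(list(rows.values()))


def network_edge_table(
    net: DiscriminativeNetwork, region_table: pd.DataFrame
) -> pd.DataFrame:
    """Long-format edge list of a discriminative network."""
    name = dict(zip(region_table["label"].astype(int), region_table["name"]))
    classes = edge_classes(net.region_ids, region_table)
    rows = []
    for pos, (k, (i, j)) in enumerate(zip(net.edge_index, net.pairs)):
        rid_i = int(net.region_ids[i])
        rid_j = int(net.region_ids[j])
        rows.append(
            {
                "edge": int(k),
                "region_i": rid_i,
                "region_j": rid_j,
                "name_i": name[rid_i],
                "name_j": name[rid_j],
                "class": classes[k],
                "r2": float(net.r2[pos]),
                "sign": int(net.signs[pos]),
            }
        )
    return pd.DataFrame(
        rows, columns=["edge", "region_i", "region_j", "name_i", "name_j",
                       "class", "r2", "sign"]
    )
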