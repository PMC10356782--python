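"""Distance and density analytics in 2D and 3D, plus the study's statistics.

Distances are measured from cell centroids to the nearest structure-positive
voxel (a blood-vessel mask for the vasculature frame, or the skin-surface
boundary). Each cell is referenced to its section plane, so same-section
structure voxels sit at zero z-offset: the 2D candidate set is then a subset
of the 3D one and ``d3d <= d2d`` holds cell by cell, the geometric mechanism
behind shorter vessel distances in 3D.

The nearest-neighbor search uses an axis-pruning filter: while scanning
candidates, any voxel whose |dx|, |dy| or |dz| already exceeds the current
minimum distance cannot improve it and is skipped before the square root is
taken. The result is exactly the exhaustive minimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .reconstruct import Cell3D, Volume3D

__all__ = [
    "SpatialCell",
    "DistanceRecord",
    "ClusterDensityRecord",
    "StatResult",
    "spatial_cells_from_cell3d",
    "pruned_nearest",
    "structure_voxel_table",
    "nearest_structure_distance",
    "distance_to_skin_surface",
    "cluster_density",
    "ks_two_sample",
    "spearman_bh",
    "wilcoxon_two_group",
]

T_CELL_PHENOTYPES = ("Thelper", "Tkiller", "Treg")
IMMUNE_PHENOTYPES = ("Thelper", "Tkiller", "Treg", "macrophage")


@dataclass(frozen=True)
class SpatialCell:
    """Cell referenced to its section plane for distance analytics."""

    id: int
    phenotype: str
    x_um: float
    y_um: float
    z_um: float  # slab z of the assigned section
    section: int  # retained index


@dataclass
class DistanceRecord:
    cell_id: int
    phenotype: str
    d2d_um: float
    d3d_um: float
    witness_2d: tuple[float, float, float] | None
    witness_3d: tuple[float, float, float] | None
    no_target_in_section: bool = False


@dataclass
class ClusterDensityRecord:
    cell_id: int
    radius_um: float
    count_2d: int
    count_3d: int


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    adjusted_p: float | None = None
    label: str = ""


def spatial_cells_from_cell3d(
    cells: Sequence[Cell3D], z_of_section: dict[int, float]
) -> list[SpatialCell]:
    """Reference each fused 3D cell to its nearest member section plane."""
    out = []
    for c in cells:
        x, y, z = c.centroid_um
        sec = min(
            (m[0] for m in c.members),
            key=lambda s: (abs(z_of_section[s] - z), s),
        )
        out.append(
            SpatialCell(
                id=c.id, phenotype=c.phenotype, x_um=x, y_um=y,
                z_um=z_of_section[sec], section=sec,
            )
        )
    return out


# ------------------------------------------------------------------ nearest structure


def pruned_nearest(
    point: np.ndarray, candidates: np.ndarray, chunk: int = 2048
) -> tuple[float, int]:
    """Nearest candidate to ``point`` with the axis-pruning filter.

    Candidates whose per-axis offset exceeds the current minimum distance
    are discarded before the Euclidean distance is evaluated. Returns
    ``(distance, index)``; ties are broken toward the candidate with the
    lexicographically smallest ``(z, y, x)`` coordinates, identically to an
    exhaustive scan.
    """
    point = np.asarray(point, dtype=float)
    candidates = np.asarray(candidates, dtype=float)
    if candidates.size == 0:
        raise ValueError("empty candidate set")
    best_d2 = np.inf
    best_idx = -1
    ndim = candidates.shape[1]
    for start in range(0, len(candidates), chunk):
        q = candidates[start : start + chunk]
        diff = np.abs(q - point)
        if np.isfinite(best_d2):
            keep = np.all(diff * diff <= best_d2, axis=1)
            if not keep.any():
                continue
            idx_local = np.flatnonzero(keep)
            d2 = np.einsum("ij,ij->i", diff[keep], diff[keep])
        else:
            idx_local = np.arange(len(q))
            d2 = np.einsum("ij,ij->i", diff, diff)
        jmin = d2.min()
        winners = idx_local[d2 == jmin]
        # lexicographic tie-break on (z, y, x) i.e. reversed coordinate order
        cand_coords = q[winners][:, ::-1] if ndim == 3 else q[winners][:, ::-1]
        order = np.lexsort(cand_coords.T[::-1])
        w = winners[order[0]]
        w_global = start + w
        if jmin < best_d2 or (
            jmin == best_d2
            and best_idx >= 0
            and tuple(candidates[w_global][::-1]) < tuple(candidates[best_idx][::-1])
        ):
            best_d2 = jmin
            best_idx = int(w_global)
    return float(np.sqrt(best_d2)), best_idx


def structure_voxel_table(mask_volume: Volume3D) -> tuple[np.ndarray, np.ndarray]:
    """Physical coordinates of structure-positive voxels.

    Returns ``(coords_um (N, 3) as (x, y, z), section_index (N,))``, ordered
    so that lexicographic (z, y, x) ties resolve deterministically.
    """
    dx, dy, _ = mask_volume.spacing_um
    coords = []
    secs = []
    for i, z in enumerate(mask_volume.z_positions_um):
        rr, cc = np.nonzero(mask_volume.data[i])
        if rr.size == 0:
            continue
        order = np.lexsort((cc, rr))
        coords.append(
            np.column_stack([cc[order] * dx, rr[order] * dy, np.full(rr.size, z)])
        )
        secs.append(np.full(rr.size, i, dtype=int))
    if not coords:
        return np.empty((0, 3)), np.empty((0,), dtype=int)
    return np.vstack(coords), np.concatenate(secs)


def nearest_structure_distance(
    cells: Sequence[SpatialCell],
    structure_mask: Volume3D,
) -> list[DistanceRecord]:
    """Distance from each cell to the nearest structure voxel, in-plane
    (2D, same section only) and through the full volume (3D).

    A cell whose own section holds no structure voxel gets a flagged record
    (``no_target_in_section``) with ``d2d = nan``; such records are excluded
    from 2D summaries. ``d3d <= d2d`` holds whenever both are defined.
    """
    coords, secs = structure_voxel_table(structure_mask)
    if coords.size == 0:
        raise ValueError("structure mask is empty")
    by_section = {s: coords[secs == s] for s in np.unique(secs)}
    out: list[DistanceRecord] = []
    for cell in cells:
        p3 = np.array([cell.x_um, cell.y_um, cell.z_um])
        d3, i3 = pruned_nearest(p3, coords)
        w3 = tuple(coords[i3])
        same = by_section.get(cell.section)
        if same is None or len(same) == 0:
            out.append(
                DistanceRecord(
                    cell_id=cell.id, phenotype=cell.phenotype,
                    d2d_um=float("nan"), d3d_um=d3,
                    witness_2d=None, witness_3d=w3, no_target_in_section=True,
                )
            )
            continue
        d2, i2 = pruned_nearest(p3[:2], same[:, :2])
        out.append(
            DistanceRecord(
                cell_id=cell.id, phenotype=cell.phenotype,
                d2d_um=d2, d3d_um=d3,
                witness_2d=tuple(same[i2]), witness_3d=w3,
            )
        )
    return out


def distance_to_skin_surface(
    cells: Sequence[SpatialCell],
    surface_by_section: dict[int, np.ndarray],  # retained -> (N, 2) (row, col) px
    z_of_section: dict[int, float],
    pixel_size_um: float,
) -> list[DistanceRecord]:
    """In-plane distance from each (3D-referenced) cell to the skin surface
    of its nearest retained section.

    The skin surface is non-uniform section to section, so the distance is
    computed against the 2D surface polyline of the nearest section rather
    than a 3D surface mesh. Ties between equidistant surface points resolve
    to the lexicographically smallest (row, col) witness.
    """
    usable = {
        s: pts for s, pts in surface_by_section.items() if pts is not None and len(pts)
    }
    if not usable:
        raise ValueError("no surface points in any section")
    out: list[DistanceRecord] = []
    for cell in cells:
        sec = min(usable, key=lambda s: (abs(z_of_section[s] - cell.z_um), s))
        pts = usable[sec]
        xy = np.column_stack([pts[:, 1] * pixel_size_um, pts[:, 0] * pixel_size_um])
        # lexicographic (y, x) witness order == (row, col)
        order = np.lexsort((xy[:, 0], xy[:, 1]))
        xy_sorted = xy[order]
        d, idx = pruned_nearest(np.array([cell.x_um, cell.y_um]), xy_sorted)
        wx, wy = xy_sorted[idx]
        out.append(
            DistanceRecord(
                cell_id=cell.id, phenotype=cell.phenotype,
                d2d_um=d, d3d_um=d,
                witness_2d=(wx, wy, z_of_section[sec]),
                witness_3d=(wx, wy, z_of_section[sec]),
            )
        )
    return out


# ------------------------------------------------------------------ cluster density


def cluster_density(
    index_cells: Sequence[SpatialCell],
    neighbor_cells: Sequence[SpatialCell],
    radius_um: float,
) -> list[ClusterDensityRecord]:
    """Number of neighbor cells within ``radius_um`` of each index cell.

    2D counts use in-plane distance within the index cell's own section;
    3D counts use the full volume. The index cell itself never counts, and
    since same-section neighbors are a subset of all neighbors at equal
    distance, ``count_3d >= count_2d`` for every record.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    out: list[ClusterDensityRecord] = []
    if not neighbor_cells:
        return [
            ClusterDensityRecord(cell_id=c.id, radius_um=radius_um, count_2d=0, count_3d=0)
            for c in index_cells
        ]
    npos = np.array([[c.x_um, c.y_um, c.z_um] for c in neighbor_cells])
    nsec = np.array([c.section for c in neighbor_cells])
    nkey = [(c.phenotype, c.id) for c in neighbor_cells]
    tree3 = cKDTree(npos)
    trees2: dict[int, tuple[cKDTree, np.ndarray]] = {}
    for s in np.unique(nsec):
        idx = np.flatnonzero(nsec == s)
        trees2[int(s)] = (cKDTree(npos[idx, :2]), idx)
    for cell in index_cells:
        p = np.array([cell.x_um, cell.y_um, cell.z_um])
        hits3 = tree3.query_ball_point(p, radius_um)
        c3 = sum(1 for i in hits3 if nkey[i] != (cell.phenotype, cell.id))
        c2 = 0
        if cell.section in trees2:
            tree2, idx = trees2[cell.section]
            hits2 = tree2.query_ball_point(p[:2], radius_um)
            c2 = sum(1 for j in hits2 if nkey[idx[j]] != (cell.phenotype, cell.id))
        out.append(
            ClusterDensityRecord(
                cell_id=cell.id, radius_um=radius_um, count_2d=c2, count_3d=c3
            )
        )
    return out


# ------------------------------------------------------------------ statistics


def ks_two_sample(a: Sequence[float], b: Sequence[float], label: str = "") -> StatResult:
    """Two-sample Kolmogorov-Smirnov test (two-sided, asymptotic p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return StatResult(
        test="ks_two_sample", statistic=float(res.statistic),
        p_value=float(res.pvalue), n=(a.size, b.size), label=label,
    )


def spearman_bh(
    family: dict[str, tuple[Sequence[float], Sequence[float]]]
) -> list[StatResult]:
    """Spearman rank correlations for a family of hypotheses with
    Benjamini-Hochberg adjustment within the family."""
    results: list[StatResult] = []
    for label, (x, y) in family.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 4 or x.size != y.size:
            raise ValueError(f"family member {label!r} needs n >= 4 paired samples")
        rho, p = stats.spearmanr(x, y)
        results.append(
            StatResult(
                test="spearman", statistic=float(rho), p_value=float(p),
                n=(x.size,), label=label,
            )
        )
    if results:
        pvals = [r.p_value for r in results]
        _, adj, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(results, adj):
            r.adjusted_p = float(q)
    return results


def wilcoxon_two_group(
    a: Sequence[float], b: Sequence[float], label: str = ""
) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test between independent
    groups; exact p for small tie-free samples, normal approximation
    otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return StatResult(
        test="wilcoxon_rank_sum", statistic=float(res.statistic),
        p_value=float(res.pvalue), n=(a.size, b.size), label=label,
    )
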