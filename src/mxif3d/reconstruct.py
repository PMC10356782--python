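"""Assembly of registered sections into physical 3D volumes and fusion of
per-section nuclei into 3D cells.

A nucleus sliced at 5 µm typically appears on more than one serial section;
counting per-section detections would overcount cells. Fusion paints each
2D nucleus as a one-slab-thick set of voxels at its section's physical z
and merges voxel-overlapping footprints in adjacent slabs by 3D connected
components (26-connectivity by default, so diagonal inter-slab contact
merges). Slabs further apart than ``max_z_gap_um`` — e.g. across skipped
physical sections — are never merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .sections import Section

__all__ = [
    "Volume3D",
    "Cell3D",
    "stack_sections",
    "fuse_cells_3d",
    "compute_tissue_volume",
    "density_per_cm3",
]


@dataclass
class Volume3D:
    """Stack of registered slabs at their physical z positions.

    ``data`` is ``(n_slabs, rows, cols)``; ``z_positions_um[i]`` is slab i's
    physical z (``physical_index * thickness``), so skipped sections appear
    as gaps in z rather than interpolated slabs.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float]  # (dx, dy, dz)
    z_positions_um: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.z_positions_um = np.asarray(self.z_positions_um, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D (z, row, col)")
        if len(self.z_positions_um) != self.data.shape[0]:
            raise ValueError("z_positions length must match slab count")
        if np.any(np.diff(self.z_positions_um) <= 0):
            raise ValueError("z_positions must be strictly increasing")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing must be positive")

    @property
    def z_extent_um(self) -> float:
        return float(self.z_positions_um[-1] - self.z_positions_um[0])


@dataclass
class Cell3D:
    """A fused 3D cell: one or more per-section nuclei joined by overlap."""

    id: int
    phenotype: str
    members: list[tuple[int, int]]  # (retained_index, nucleus_id)
    centroid_um: tuple[float, float, float]  # (x, y, z), voxel-weighted
    voxel_count: int
    n_sections_spanned: int


def stack_sections(
    sections: list[Section],
    channel: str,
    thickness_um: float = 5.0,
    registered_channels: list[np.ndarray] | None = None,
) -> Volume3D:
    """Stack one channel of registered sections into a physical volume.

    Slab z is ``physical_index * thickness_um``; skipped physical sections
    leave gaps in z (no interpolation). ``registered_channels`` overrides
    the stored channel data (e.g. with transformed rasters).
    """
    if not sections:
        raise ValueError("empty stack")
    phys = [s.physical_index for s in sections]
    if len(set(phys)) != len(phys):
        raise ValueError("duplicate physical indices in stack")
    order = np.argsort(phys)
    if registered_channels is None:
        slabs = [np.asarray(sections[i].channels[channel]) for i in order]
    else:
        slabs = [np.asarray(registered_channels[i]) for i in order]
    shapes = {s.shape for s in slabs}
    if len(shapes) != 1:
        raise ValueError("sections must share a common shape")
    px = sections[0].pixel_size_um
    z = np.array([phys[i] * thickness_um for i in order], dtype=float)
    return Volume3D(
        data=np.stack(slabs),
        spacing_um=(px, px, thickness_um),
        z_positions_um=z,
    )


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=int)
    if connectivity == 6:
        return ndi.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def fuse_cells_3d(
    label_volume: Volume3D,
    phenotype: str,
    max_z_gap_um: float = 5.0,
    connectivity: int = 26,
    label_phenotypes: dict[int, str] | None = None,
    id_offset: int = 0,
) -> list[Cell3D]:
    """Fuse per-section nucleus labels into 3D cells by connected components.

    ``label_volume`` holds one slab of 2D nucleus labels (0 = background)
    per retained section; each volume carries a single phenotype. Slabs
    whose physical z differ by more than ``max_z_gap_um`` are separated by
    an empty spacer slab before labeling, so cells never merge across
    unobserved gaps. Every 2D nucleus is assigned to exactly one 3D cell,
    hence the 3D count never exceeds the 2D count.
    """
    labels = np.asarray(label_volume.data)
    if label_phenotypes is not None:
        present = {label_phenotypes[int(v)] for v in np.unique(labels) if v != 0}
        if len(present) > 1:
            raise ValueError(f"mixed phenotypes within one input volume: {sorted(present)}")
    z = label_volume.z_positions_um
    dx, dy, dz = label_volume.spacing_um

    # insert spacer slabs where the z gap forbids merging
    slab_rows: list[np.ndarray] = [labels[0]]
    slab_index: list[int] = [0]  # original slab index, -1 for spacer
    for i in range(1, labels.shape[0]):
        if z[i] - z[i - 1] > max_z_gap_um:
            slab_rows.append(np.zeros_like(labels[0]))
            slab_index.append(-1)
        slab_rows.append(labels[i])
        slab_index.append(i)
    stacked = np.stack(slab_rows)

    comp, n = ndi.label(stacked > 0, structure=_connectivity_structure(connectivity))
    cells: list[Cell3D] = []
    if n == 0:
        return cells
    objects = ndi.find_objects(comp)
    for cid in range(1, n + 1):
        sl = objects[cid - 1]
        sub = comp[sl] == cid
        zz, rr, cc = np.nonzero(sub)
        zz = zz + sl[0].start
        rr = rr + sl[1].start
        cc = cc + sl[2].start
        orig = np.array([slab_index[k] for k in zz])
        lab_vals = stacked[zz, rr, cc]
        members = sorted({(int(o), int(v) - 1) for o, v in zip(orig, lab_vals)})
        zpos = z[orig]
        cells.append(
            Cell3D(
                id=id_offset + cid - 1,
                phenotype=phenotype,
                members=members,
                centroid_um=(
                    float(cc.mean() * dx),
                    float(rr.mean() * dy),
                    float(zpos.mean()),
                ),
                voxel_count=int(len(zz)),
                n_sections_spanned=int(len(set(orig.tolist()))),
            )
        )
    return cells


def compute_tissue_volume(mask_volume: Volume3D) -> tuple[float, float]:
    """Tissue volume from a binary mask volume: voxel count x dx·dy·dz.

    Returns ``(µm³, cm³)``; 1 cm³ = 1e12 µm³.
    """
    dx, dy, dz = mask_volume.spacing_um
    n = int(np.count_nonzero(mask_volume.data))
    um3 = n * dx * dy * dz
    return um3, um3 * 1e-12


def density_per_cm3(cell_count: int, volume_cm3: float) -> float:
    """Cell density normalized by the region-of-interest volume."""
    if volume_cm3 <= 0:
        raise ValueError("volume must be positive")
    return cell_count / volume_cm3
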