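"""File I/O: TIFF section stacks with JSON sidecars, CSV tables, truth dumps.

Section filenames follow ``S{physical_index:03d}_{channel}.tif``; a
``stack.json`` sidecar records pixel size, section thickness and the channel
list so a stack directory round-trips losslessly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import tifffile

from .phantom import PhantomTruth
from .reconstruct import Cell3D
from .sections import Section
from .segment import CellRecord2D
from .spatial import ClusterDensityRecord, DistanceRecord

__all__ = [
    "write_section_stack",
    "read_section_stack",
    "write_tables",
    "cells2d_to_table",
    "cells3d_to_table",
    "distances_to_table",
    "cluster_density_to_table",
    "write_truth",
]

SIDECAR = "stack.json"


def write_section_stack(
    directory: str | Path, sections: Sequence[Section], section_thickness_um: float
) -> Path:
    """Write one TIFF per section per channel plus the ``stack.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    channels = list(sections[0].channels)
    for sec in sections:
        for name, img in sec.channels.items():
            tifffile.imwrite(
                directory / f"S{sec.physical_index:03d}_{name}.tif", np.asarray(img)
            )
    sidecar = {
        "pixel_size_um": sections[0].pixel_size_um,
        "section_thickness_um": section_thickness_um,
        "channels": channels,
        "physical_indices": [s.physical_index for s in sections],
        "shape": list(sections[0].shape),
    }
    (directory / SIDECAR).write_text(json.dumps(sidecar, indent=1))
    return directory


def read_section_stack(
    directory: str | Path, channel_map: dict[str, str] | None = None
) -> tuple[list[Section], dict]:
    """Read a section stack directory written by :func:`write_section_stack`.

    ``channel_map`` renames file channels to canonical names (e.g.
    ``{"dapi_ch0": "DAPI"}``). Sections are sorted by physical index;
    duplicate indices and inconsistent shapes are errors.
    """
    directory = Path(directory)
    sidecar_path = directory / SIDECAR
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    phys = meta["physical_indices"]
    if len(set(phys)) != len(phys):
        raise ValueError("duplicate physical index in sidecar")
    if not phys:
        raise ValueError("empty stack")
    channel_map = channel_map or {}
    sections: list[Section] = []
    shape = tuple(meta["shape"])
    for ridx, pidx in enumerate(sorted(phys)):
        channels: dict[str, np.ndarray] = {}
        for name in meta["channels"]:
            path = directory / f"S{pidx:03d}_{name}.tif"
            if not path.exists():
                raise FileNotFoundError(f"missing channel file {path}")
            img = tifffile.imread(path)
            if img.shape != shape:
                raise ValueError(
                    f"inconsistent shape in {path.name}: {img.shape} != {shape}"
                )
            channels[channel_map.get(name, name)] = img
        sections.append(
            Section(
                channels=channels,
                pixel_size_um=meta["pixel_size_um"],
                retained_index=ridx,
                physical_index=pidx,
            )
        )
    return sections, meta


def write_tables(records: Sequence[Any], path: str | Path, sort_by: str | None = None) -> Path:
    """Write records (dicts or dataclasses) as CSV with a fixed header,
    deterministic row order and floats at 6 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [asdict(r) if is_dataclass(r) else dict(r) for r in records]
    df = pd.DataFrame(rows)
    if not df.empty:
        key = sort_by or df.columns[0]
        df = df.sort_values(key, kind="stable").reset_index(drop=True)
    df.to_csv(path, index=False, float_format="%.6g", encoding="utf-8")
    return path


def cells2d_to_table(cells: Sequence[CellRecord2D], retained_index: int | None = None) -> list[dict]:
    rows = []
    for c in cells:
        row: dict[str, Any] = {
            "cell_id": c.nucleus.id,
            "section": retained_index if retained_index is not None else c.nucleus.retained_index,
            "x_um": c.nucleus.centroid_um[0],
            "y_um": c.nucleus.centroid_um[1],
            "area_px": c.nucleus.area_px,
            "phenotype": c.phenotype,
            "ambiguous": c.ambiguous,
        }
        for marker, call in sorted(c.calls.items()):
            row[f"{marker}_p"] = call.p
            row[f"{marker}_positive"] = call.positive
        rows.append(row)
    return rows


def cells3d_to_table(cells: Sequence[Cell3D]) -> list[dict]:
    return [
        {
            "cell_id": c.id,
            "phenotype": c.phenotype,
            "x_um": c.centroid_um[0],
            "y_um": c.centroid_um[1],
            "z_um": c.centroid_um[2],
            "voxel_count": c.voxel_count,
            "n_sections_spanned": c.n_sections_spanned,
            "members": ";".join(f"{s}:{n}" for s, n in c.members),
        }
        for c in cells
    ]


def distances_to_table(records: Sequence[DistanceRecord]) -> list[dict]:
    return [
        {
            "cell_id": r.cell_id,
            "phenotype": r.phenotype,
            "d2d_um": r.d2d_um,
            "d3d_um": r.d3d_um,
            "no_target_in_section": r.no_target_in_section,
        }
        for r in records
    ]


def cluster_density_to_table(records: Sequence[ClusterDensityRecord]) -> list[dict]:
    return [
        {
            "cell_id": r.cell_id,
            "radius_um": r.radius_um,
            "count_2d": r.count_2d,
            "count_3d": r.count_3d,
        }
        for r in records
    ]


def write_truth(directory: str | Path, truth: PhantomTruth) -> None:
    """Dump phantom ground truth: cells as CSV, transforms/config as JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "cell_id": c.id,
            "phenotype": c.phenotype,
            "x_um": c.centroid_um[0],
            "y_um": c.centroid_um[1],
            "z_um": c.centroid_um[2],
            "radius_um": c.radius_um,
            "markers": ";".join(sorted(c.markers)),
            "n_footprints": len(c.footprints),
        }
        for c in truth.cells
    ]
    write_tables(rows, directory / "truth_cells.csv", sort_by="cell_id")
    cfg = asdict(truth.config)
    cfg["channels"] = list(cfg["channels"])
    payload = {
        "config": cfg,
        "section_map": {str(k): v for k, v in truth.section_map.items()},
        "transforms": [t.to_dict() for t in truth.transforms],
    }
    (directory / "truth_meta.json").write_text(json.dumps(payload, indent=1))
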