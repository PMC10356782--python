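"""End-to-end orchestration: preprocess -> segment -> register -> reconstruct
-> spatial, with validation up front and deterministic outputs.

The pipeline consumes either a section-stack directory or a phantom
configuration (in which case the stack is generated in memory). Each stage
writes its tables under the output directory; a rerun with the same
configuration and seed reproduces every table bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as mio
from .phantom import PhantomConfig, generate_phantom
from .preprocess import normalize_zmuv
from .reconstruct import (
    Volume3D,
    compute_tissue_volume,
    density_per_cm3,
    fuse_cells_3d,
    stack_sections,
)
from .register import register_stack
from .sections import Section
from .segment import (
    REQUIRED_PHENOTYPE_MARKERS,
    call_marker_on_nuclei,
    fit_gmm_two_class,
    phenotype_cells,
    segment_nuclei,
    segment_structure_mask,
)
from .spatial import (
    IMMUNE_PHENOTYPES,
    T_CELL_PHENOTYPES,
    cluster_density,
    nearest_structure_distance,
    spatial_cells_from_cell3d,
)

log = logging.getLogger("mxif3d")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    output_dir: str
    input_dir: str | None = None
    phantom: PhantomConfig | None = None
    channel_map: dict[str, str] = field(default_factory=dict)
    section_thickness_um: float = 5.0
    reference_index: int | None = None
    prob_threshold: float = 0.5
    overlap_threshold: float = 0.1
    marker_threshold_overrides: dict[str, float] = field(default_factory=dict)
    cluster_radii_um: tuple[float, float] = (15.0, 30.0)
    max_z_gap_um: float = 5.0
    nuclei_response_threshold: float = 0.3
    seed: int = 0
    markers: tuple[str, ...] = REQUIRED_PHENOTYPE_MARKERS + ("AE1",)
    deformable: bool = True

    def validate(self, available_channels: set[str] | None = None) -> None:
        if (self.input_dir is None) == (self.phantom is None):
            raise ValueError("exactly one of input_dir or phantom must be set")
        for name, thr in {
            "prob_threshold": self.prob_threshold,
            "overlap_threshold": self.overlap_threshold,
            **self.marker_threshold_overrides,
        }.items():
            if not 0.0 <= thr <= 1.0:
                raise ValueError(f"threshold {name} must be in [0, 1], got {thr}")
        if self.section_thickness_um <= 0:
            raise ValueError("section_thickness_um must be positive")
        if any(r <= 0 for r in self.cluster_radii_um):
            raise ValueError("cluster radii must be positive")
        if available_channels is not None:
            needed = set(self.markers) | {"DAPI", "AF"}
            missing = needed - available_channels
            if missing:
                raise ValueError(f"missing channels in input: {sorted(missing)}")


@dataclass
class RunReport:
    stages: dict[str, str] = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    cell_counts_2d: dict[str, int] = field(default_factory=dict)
    cell_counts_3d: dict[str, int] = field(default_factory=dict)
    densities_per_cm3: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    output_hashes: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "qc": self.qc,
            "cell_counts_2d": self.cell_counts_2d,
            "cell_counts_3d": self.cell_counts_3d,
            "densities_per_cm3": self.densities_per_cm3,
            "warnings": self.warnings,
            "output_hashes": self.output_hashes,
        }


def _load_sections(config: PipelineConfig) -> list[Section]:
    if config.phantom is not None:
        sections, _ = generate_phantom(config.phantom)
        return sections
    sections, _ = mio.read_section_stack(config.input_dir, config.channel_map)
    return sections


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages; any stage failure aborts with the stage name and
    leaves partial outputs plus a report with status ``failed``."""
    report = RunReport()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    sections = _load_sections(config)
    config.validate(available_channels=set(sections[0].channels))
    px = sections[0].pixel_size_um
    thickness = config.section_thickness_um

    stage = "register"
    try:
        transforms, qc = register_stack(
            sections,
            reference_index=config.reference_index,
            deformable=config.deformable,
        )
        report.qc["registration"] = qc.to_dict()
        report.stages[stage] = "ok"
    except Exception as exc:
        report.stages[stage] = "failed"
        _write_report(out, report)
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    stage = "segment"
    try:
        cells2d_per_section = []
        label_images = []
        structure_masks = {"CD31": [], "AE1": []}
        for sec in sections:
            dapi = normalize_zmuv(np.asarray(sec.channels["DAPI"], dtype=float))
            nuclei = segment_nuclei(
                dapi,
                response_threshold=config.nuclei_response_threshold,
                pixel_size_um=px,
                retained_index=sec.retained_index,
            )
            calls = []
            for marker in config.markers:
                img = normalize_zmuv(
                    np.asarray(sec.channels[marker], dtype=float), mask=sec.af_mask
                )
                fit = fit_gmm_two_class(img, mask=sec.af_mask, seed=config.seed)
                thr = config.marker_threshold_overrides.get(marker, config.prob_threshold)
                if marker in config.marker_threshold_overrides:
                    report.warnings.append(f"threshold override applied for {marker}: {thr}")
                calls.extend(
                    call_marker_on_nuclei(
                        fit, nuclei, marker,
                        prob_threshold=thr,
                        overlap_threshold=config.overlap_threshold,
                    )
                )
                if marker in structure_masks:
                    structure_masks[marker].append(segment_structure_mask(fit))
            records = phenotype_cells(nuclei, calls)
            cells2d_per_section.append(records)
            lab = np.zeros(sec.shape, dtype=np.int32)
            for rec in records:
                pxs = rec.nucleus.pixels
                lab[pxs[:, 0], pxs[:, 1]] = rec.nucleus.id + 1
            label_images.append(lab)
        report.stages[stage] = "ok"
    except Exception as exc:
        report.stages[stage] = "failed"
        _write_report(out, report)
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    stage = "reconstruct"
    try:
        reg_masks = [
            t.resample(s.af_mask.astype(np.uint8), px, interpolation="nearest") > 0
            for t, s in zip(transforms, sections)
        ]
        tissue_vol = stack_sections(sections, "AF", thickness, registered_channels=reg_masks)
        um3, cm3 = compute_tissue_volume(tissue_vol)
        report.qc["tissue_volume_um3"] = um3

        cells3d = []
        next_id = 0
        for phen in set(r.phenotype for recs in cells2d_per_section for r in recs):
            phen_labels = []
            for sec, recs, lab, t in zip(
                sections, cells2d_per_section, label_images, transforms
            ):
                keep = np.isin(
                    lab, [r.nucleus.id + 1 for r in recs if r.phenotype == phen]
                )
                reg_lab = t.resample(
                    np.where(keep, lab, 0).astype(np.int32), px, interpolation="nearest"
                )
                phen_labels.append(reg_lab)
            vol = stack_sections(sections, "AF", thickness, registered_channels=phen_labels)
            fused = fuse_cells_3d(
                vol, phen, max_z_gap_um=config.max_z_gap_um, id_offset=next_id
            )
            next_id += len(fused)
            cells3d.extend(fused)

        for recs in cells2d_per_section:
            for r in recs:
                report.cell_counts_2d[r.phenotype] = (
                    report.cell_counts_2d.get(r.phenotype, 0) + 1
                )
        for c in cells3d:
            report.cell_counts_3d[c.phenotype] = report.cell_counts_3d.get(c.phenotype, 0) + 1
        for phen, count in sorted(report.cell_counts_3d.items()):
            report.densities_per_cm3[phen] = density_per_cm3(count, cm3)
        report.stages[stage] = "ok"
    except Exception as exc:
        report.stages[stage] = "failed"
        _write_report(out, report)
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    stage = "spatial"
    try:
        z_of_section = {
            s.retained_index: s.physical_index * thickness for s in sections
        }
        scells = spatial_cells_from_cell3d(cells3d, z_of_section)
        immune = [c for c in scells if c.phenotype in IMMUNE_PHENOTYPES]
        vessel_vol = stack_sections(
            sections, "AF", thickness, registered_channels=[
                t.resample(m.astype(np.uint8), px, interpolation="nearest") > 0
                for t, m in zip(transforms, structure_masks["CD31"])
            ],
        )
        distances = []
        if immune and np.any(vessel_vol.data):
            distances = nearest_structure_distance(immune, vessel_vol)
        tcells = [c for c in scells if c.phenotype in T_CELL_PHENOTYPES]
        helpers = [c for c in scells if c.phenotype == "Thelper"]
        density_records = []
        for radius in config.cluster_radii_um:
            density_records.extend(cluster_density(helpers, tcells, radius))
        report.stages[stage] = "ok"
    except Exception as exc:
        report.stages[stage] = "failed"
        _write_report(out, report)
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    stage = "write"
    rows2d = [
        row
        for recs in cells2d_per_section
        for row in mio.cells2d_to_table(recs)
    ]
    tables = {
        "cells_2d.csv": (rows2d, "cell_id"),
        "cells_3d.csv": (mio.cells3d_to_table(cells3d), "cell_id"),
        "distances.csv": (mio.distances_to_table(distances), "cell_id"),
        "cluster_density.csv": (mio.cluster_density_to_table(density_records), "cell_id"),
    }
    for name, (rows, key) in tables.items():
        path = mio.write_tables(rows, out / name, sort_by=key if rows else None)
        report.output_hashes[name] = _hash_file(path)
    report.stages[stage] = "ok"
    _write_report(out, report)
    return report


def _write_report(out: Path, report: RunReport) -> None:
    (out / "run_report.json").write_text(json.dumps(report.to_dict(), indent=1))
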