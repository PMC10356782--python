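"""Synthetic serial-section phantoms with known ground truth.

The generator emulates a stack of 5 µm serial skin sections imaged by
multiplexed immunofluorescence: a tissue band with a sinusoidal skin
surface, an epidermis layer, tubular CD31+ vessels running through the
stack, nuclei rendered as Gaussian blobs whose 3D extent intersects 1-3
adjacent sections, marker intensities with a two-component (background vs
positive) structure, and per-section affine jitter + smooth B-spline
deformation + Gaussian noise. Every stochastic choice is driven by a single
seeded generator, so one seed fully determines the stack and its truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .sections import Section
from .transforms import TransformPair, make_affine, make_random_bspline

__all__ = [
    "PHENOTYPES",
    "PHENOTYPE_MARKERS",
    "DEFAULT_CHANNELS",
    "PhantomConfig",
    "Footprint",
    "TruthCell",
    "PhantomTruth",
    "generate_phantom",
    "warp_section",
]

PHENOTYPES = ("Thelper", "Tkiller", "Treg", "macrophage", "endothelial", "epithelial", "other")

#: Marker positivity implied by each phenotype (nuclear/peri-nuclear markers).
PHENOTYPE_MARKERS: dict[str, frozenset[str]] = {
    "Thelper": frozenset({"CD3", "CD4"}),
    "Tkiller": frozenset({"CD3", "CD8"}),
    "Treg": frozenset({"CD3", "CD4", "FOXP3"}),
    "macrophage": frozenset({"CD68"}),
    "endothelial": frozenset({"CD31"}),
    "epithelial": frozenset({"AE1"}),
    "other": frozenset(),
}

DAMAGE_MARKERS = ("p53", "Ki67", "DDB2")

DEFAULT_CHANNELS = (
    "DAPI", "AF", "CD3", "CD4", "CD8", "FOXP3", "CD68", "CD31", "AE1",
    "p53", "Ki67", "DDB2",
)

_UINT16_SCALE = 10000.0  # float [0, ~1.5] -> uint16 counts


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic stack.

    Defaults emulate the acquisition this package targets: ~24 retained
    sections cut at 5 µm, 20x-like sampling, moderate immune-cell densities
    and a marker signal-to-noise ratio of 6 (positive nuclei 6 noise-SDs
    above background).
    """

    n_sections: int = 24
    section_thickness_um: float = 5.0
    skipped_pattern: list[int] | None = None  # retained physical indices
    image_shape: tuple[int, int] = (256, 320)
    pixel_size_um: float = 1.0
    cell_density_per_type: dict[str, int] = field(
        default_factory=lambda: {
            "Thelper": 60,
            "Tkiller": 10,
            "Treg": 15,
            "macrophage": 20,
            "endothelial": 25,
            "epithelial": 40,
            "other": 20,
        }
    )
    vessel_count: int = 4
    marker_snr: float = 6.0
    affine_jitter: tuple[float, float] = (3.0, 10.0)  # (max rotation deg, max translation px)
    deform_max_px: float = 10.0
    noise_sigma: float = 0.05
    damage_positive_fraction: float = 0.25
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if self.section_thickness_um <= 0:
            raise ValueError("section_thickness_um must be positive")
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("zero image area")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.skipped_pattern is None:
            self.skipped_pattern = list(range(self.n_sections))
        if len(self.skipped_pattern) != self.n_sections:
            raise ValueError("skipped_pattern length must equal n_sections")
        if sorted(self.skipped_pattern) != self.skipped_pattern or len(
            set(self.skipped_pattern)
        ) != self.n_sections:
            raise ValueError("skipped_pattern must be strictly increasing physical indices")
        gaps = np.diff(self.skipped_pattern)
        if self.n_sections > 1 and gaps.max(initial=1) > 3:
            raise ValueError("at most 2 physical sections may be skipped between retained ones")
        unknown = set(self.cell_density_per_type) - set(PHENOTYPES)
        if unknown:
            raise ValueError(f"unknown phenotypes in cell_density_per_type: {sorted(unknown)}")
        if any(v < 0 for v in self.cell_density_per_type.values()):
            raise ValueError("cell densities must be non-negative")
        if self.marker_snr <= 0:
            raise ValueError("marker_snr must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for name in ("DAPI", "AF"):
            if name not in self.channels:
                raise ValueError(f"channels must include {name}")

    @property
    def physical_extent_um(self) -> float:
        return (self.skipped_pattern[-1] + 1) * self.section_thickness_um


@dataclass
class Footprint:
    """2D Gaussian-blob footprint of a nucleus on one retained section,
    in reference-frame pixel coordinates."""

    retained_index: int
    center_rc: tuple[float, float]
    sigma_px: float
    amplitude: float

    @property
    def radius_px(self) -> float:
        # support radius at ~20% of peak amplitude
        return 1.8 * self.sigma_px

    def pixel_set(self, shape: tuple[int, int]) -> np.ndarray:
        """(N, 2) array of (row, col) pixels inside the footprint disk."""
        r0, c0 = self.center_rc
        rad = self.radius_px
        rlo, rhi = max(0, int(r0 - rad)), min(shape[0], int(r0 + rad) + 2)
        clo, chi = max(0, int(c0 - rad)), min(shape[1], int(c0 + rad) + 2)
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        keep = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        return np.column_stack([rr[keep], cc[keep]])


@dataclass
class TruthCell:
    id: int
    phenotype: str
    centroid_um: tuple[float, float, float]  # (x, y, z) reference frame
    radius_um: float
    markers: frozenset[str]
    marker_level: float = 1.0  # per-nucleus draw from the positive component
    footprints: list[Footprint] = field(default_factory=list)


@dataclass
class PhantomTruth:
    """Everything the generator knows and downstream stages must recover."""

    cells: list[TruthCell]
    vessel_voxels: np.ndarray  # (N, 3) int: (physical_index, row, col)
    skin_surface: dict[int, np.ndarray]  # retained_index -> (N, 2) (row, col)
    transforms: list[TransformPair]
    section_map: dict[int, int]  # retained -> physical
    tissue_mask: np.ndarray
    epidermis_mask: np.ndarray
    config: PhantomConfig

    def cells_of_type(self, phenotype: str) -> list[TruthCell]:
        return [c for c in self.cells if c.phenotype == phenotype]

    def footprint_labels(self, retained_index: int) -> np.ndarray:
        """Reference-frame label image for one section; pixel value = cell id + 1."""
        lab = np.zeros(self.config.image_shape, dtype=np.int32)
        for cell in self.cells:
            for fp in cell.footprints:
                if fp.retained_index == retained_index:
                    px = fp.pixel_set(self.config.image_shape)
                    lab[px[:, 0], px[:, 1]] = cell.id + 1
        return lab

    def marker_truth_for_section(self, retained_index: int, marker: str) -> dict[int, bool]:
        """cell id -> truth positivity, for cells with a footprint on the section."""
        out: dict[int, bool] = {}
        for cell in self.cells:
            if any(fp.retained_index == retained_index for fp in cell.footprints):
                out[cell.id] = marker in cell.markers
        return out


# --------------------------------------------------------------------------- geometry


def _tissue_geometry(config: PhantomConfig, rng: np.random.Generator):
    rows, cols = config.image_shape
    phase = rng.uniform(0, 2 * np.pi)
    amp = 0.05 * rows
    x = np.arange(cols)
    surface_row = 0.14 * rows + amp * np.sin(2 * np.pi * 2.0 * x / cols + phase)
    bottom = rows - max(4, int(0.03 * rows))
    rr = np.arange(rows)[:, None]
    tissue = (rr >= surface_row[None, :]) & (rr < bottom)
    epi_depth_px = 40.0 / config.pixel_size_um
    epidermis = tissue & (rr < (surface_row[None, :] + epi_depth_px))
    return tissue, epidermis, surface_row


def _surface_points(tissue: np.ndarray) -> np.ndarray:
    """Topmost tissue pixel per column -> (N, 2) (row, col)."""
    rows_idx = np.argmax(tissue, axis=0)
    has = tissue.any(axis=0)
    cols = np.flatnonzero(has)
    return np.column_stack([rows_idx[cols], cols])


def _af_volume(config: PhantomConfig, tissue: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth random AF texture: a z-persistent structural component
    (collagen-like anatomy that survives the whole block, giving every
    section common texture with any chosen reference) plus a z-varying
    component with ~1-section correlation length."""
    n = config.n_sections
    persistent = ndi.gaussian_filter(rng.standard_normal(config.image_shape), 6.0)
    persistent = (persistent - persistent.mean()) / (persistent.std() + 1e-12)
    noise = rng.standard_normal((n + 4, *config.image_shape))
    varying = ndi.gaussian_filter(noise, sigma=(1.2, 6.0, 6.0))
    varying = varying[2 : n + 2]
    varying = (varying - varying.mean()) / (varying.std() + 1e-12)
    field = 0.65 * persistent[None, :, :] + 0.35 * varying
    field = (field - field.mean()) / (field.std() + 1e-12)
    # tissue AF sits well above the background so Otsu masking recovers the
    # tissue region, as it does on real (unquenched) autofluorescence
    af = 0.55 + 0.18 * field
    af = np.clip(af, 0.3, 1.2)
    af = af * tissue[None, :, :]
    af += 0.02  # faint background glass signal
    return af


def _make_vessels(config: PhantomConfig, tissue: np.ndarray, epidermis: np.ndarray,
                  rng: np.random.Generator):
    """Smooth tubes roughly along z with sinusoidal in-plane drift."""
    rows, cols = config.image_shape
    n_phys = config.skipped_pattern[-1] + 1
    dermis = tissue & ~epidermis
    dermis_rows = np.flatnonzero(dermis.any(axis=1))
    centers_per_section: list[list[tuple[float, float, float]]] = [[] for _ in range(n_phys)]
    for _ in range(config.vessel_count):
        r0 = rng.uniform(dermis_rows.min() + 10, dermis_rows.max() - 10)
        c0 = rng.uniform(12, cols - 12)
        amp_r, amp_c = rng.uniform(3, 12, size=2)
        ph_r, ph_c = rng.uniform(0, 2 * np.pi, size=2)
        period = rng.uniform(1.5, 3.0) * n_phys
        radius = rng.uniform(3.0, 5.0)
        for p in range(n_phys):
            rr = r0 + amp_r * np.sin(2 * np.pi * p / period + ph_r)
            cc = c0 + amp_c * np.sin(2 * np.pi * p / period + ph_c)
            centers_per_section[p].append((rr, cc, radius))
    vox: list[tuple[int, int, int]] = []
    masks = np.zeros((n_phys, rows, cols), dtype=bool)
    rr_grid, cc_grid = np.mgrid[0:rows, 0:cols]
    for p in range(n_phys):
        for (rr, cc, radius) in centers_per_section[p]:
            m = (rr_grid - rr) ** 2 + (cc_grid - cc) ** 2 <= radius**2
            masks[p] |= m & tissue
    for p in range(n_phys):
        pr, pc = np.nonzero(masks[p])
        vox.extend(zip([p] * len(pr), pr, pc))
    vessel_voxels = np.array(vox, dtype=int) if vox else np.empty((0, 3), dtype=int)
    return vessel_voxels, masks, centers_per_section


# --------------------------------------------------------------------------- cells


def _place_cells(config: PhantomConfig, tissue, epidermis, vessel_centers, rng):
    rows, cols = config.image_shape
    px = config.pixel_size_um
    z_extent = config.physical_extent_um
    dermis = tissue & ~epidermis
    cells: list[TruthCell] = []
    placed: list[tuple[float, float, float, float]] = []  # (row, col, z_um, r_um)

    region_pixels = {
        "epidermis": np.column_stack(np.nonzero(epidermis)),
        "dermis": np.column_stack(np.nonzero(dermis)),
    }

    def sample_position(phenotype: str, prefer_vessel: bool) -> tuple[float, float, float]:
        if phenotype == "epithelial":
            pool = region_pixels["epidermis"]
        else:
            pool = region_pixels["dermis"]
        if pool.size == 0:
            raise ValueError(f"no tissue area available for phenotype {phenotype}")
        z = rng.uniform(0, z_extent)
        if phenotype == "endothelial" and prefer_vessel and vessel_centers:
            p = min(int(z / config.section_thickness_um), len(vessel_centers) - 1)
            choices = vessel_centers[p]
            if choices:
                rr, cc, radius = choices[rng.integers(len(choices))]
                ang = rng.uniform(0, 2 * np.pi)
                d = radius + rng.uniform(1.5, 3.0)
                r, c = rr + d * np.sin(ang), cc + d * np.cos(ang)
                if 1 <= r < rows - 1 and 1 <= c < cols - 1 and tissue[int(r), int(c)]:
                    return r, c, z
        idx = pool[rng.integers(len(pool))]
        return float(idx[0]), float(idx[1]), z

    cell_id = 0
    for phenotype in PHENOTYPES:
        want = config.cell_density_per_type.get(phenotype, 0)
        for _ in range(want):
            for attempt in range(6000):
                # endothelial cells line vessels, but fall back to the dermis
                # pool if the perivascular ring is saturated
                r, c, z = sample_position(phenotype, prefer_vessel=attempt < 2000)
                r_um = rng.uniform(4.0, 7.5)
                ok = True
                for (pr, pc, pz, prad) in placed:
                    # slab discretization can place two cells' footprints in
                    # adjacent slabs even when their spheres are disjoint in
                    # z, so pad the conflict window by two slab thicknesses
                    if abs(pz - z) < (prad + r_um) + 2 * config.section_thickness_um:
                        # footprint radius is 1.8*sigma with sigma floored at
                        # 1.3 px; keep z-overlapping nuclei clear of
                        # 26-connected contact between their largest footprints
                        sep = (
                            max(1.8 * 1.3, 1.2 * prad / px)
                            + max(1.8 * 1.3, 1.2 * r_um / px)
                            + 2.0
                        )
                        if (pr - r) ** 2 + (pc - c) ** 2 < sep**2:
                            ok = False
                            break
                if ok:
                    break
            else:
                raise ValueError(
                    f"cell density for phenotype {phenotype!r} exceeds packable area"
                )
            placed.append((r, c, z, r_um))
            markers = set(PHENOTYPE_MARKERS[phenotype])
            if phenotype == "epithelial":
                for dm in DAMAGE_MARKERS:
                    if dm in config.channels and rng.uniform() < config.damage_positive_fraction:
                        markers.add(dm)
            cells.append(
                TruthCell(
                    id=cell_id,
                    phenotype=phenotype,
                    centroid_um=(c * px, r * px, z),
                    radius_um=r_um,
                    markers=frozenset(markers),
                    marker_level=float(np.clip(rng.normal(1.0, 0.15), 0.4, None)),
                )
            )
            cell_id += 1
    return cells


def _assign_footprints(config: PhantomConfig, cells: list[TruthCell], rng: np.random.Generator):
    px = config.pixel_size_um
    t = config.section_thickness_um
    for cell in cells:
        x, y, z = cell.centroid_um
        amp = rng.uniform(0.7, 1.0)
        for ridx, pidx in enumerate(config.skipped_pattern):
            z_mid = pidx * t + t / 2
            dz = z - z_mid
            if abs(dz) >= cell.radius_um:
                continue
            rad_um = np.sqrt(cell.radius_um**2 - dz**2)
            sigma = max(1.3, (rad_um / px) / 1.5)
            cell.footprints.append(
                Footprint(
                    retained_index=ridx,
                    center_rc=(y / px, x / px),
                    sigma_px=float(sigma),
                    amplitude=float(amp * rad_um / cell.radius_um),
                )
            )


def _paint_disks(
    image: np.ndarray, footprints_levels: list[tuple[Footprint, float]], scale: float
) -> None:
    """Flat-disk painting for marker channels: every footprint pixel takes the
    nucleus's drawn positive-component intensity (two-component mixture
    structure, rather than a blob profile decaying into background)."""
    shape = image.shape
    for fp, level in footprints_levels:
        px = fp.pixel_set(shape)
        if len(px) == 0:
            continue
        np.maximum.at(image, (px[:, 0], px[:, 1]), scale * level)


def _paint_blobs(image: np.ndarray, footprints: list[Footprint], scale: float = 1.0) -> None:
    rows, cols = image.shape
    for fp in footprints:
        r0, c0 = fp.center_rc
        ext = int(np.ceil(3 * fp.sigma_px))
        rlo, rhi = max(0, int(r0) - ext), min(rows, int(r0) + ext + 1)
        clo, chi = max(0, int(c0) - ext), min(cols, int(c0) + ext + 1)
        if rlo >= rhi or clo >= chi:
            continue
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        blob = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * fp.sigma_px**2))
        np.maximum(image[rlo:rhi, clo:chi], scale * fp.amplitude * blob,
                   out=image[rlo:rhi, clo:chi])


# --------------------------------------------------------------------------- API


def warp_section(
    image: np.ndarray,
    transform: TransformPair,
    noise_sigma: float,
    seed: int,
    pixel_size_um: float = 1.0,
    interpolation: str = "linear",
) -> np.ndarray:
    """Resample ``image`` through ``transform`` and add Gaussian noise.

    An identity transform with zero noise returns the input bit-exactly.
    """
    image = np.asarray(image)
    extent = max(image.shape) * pixel_size_um
    if np.abs(transform.affine[:, 2]).max() >= extent:
        raise ValueError("transform displacement exceeds image extent")
    out = transform.resample(image.astype(float), pixel_size_um, interpolation=interpolation)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sigma, size=out.shape)
    elif transform.is_identity:
        return image.copy()
    return out


def generate_phantom(config: PhantomConfig) -> tuple[list[Section], PhantomTruth]:
    """Generate a serial-section stack and its ground truth.

    Returns one :class:`Section` per retained section (channels stored as
    uint16, microscopy TIFF convention) and the :class:`PhantomTruth`
    describing cells, vessels, the skin surface, and the per-section
    perturbation transforms that registration must undo.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.image_shape
    px = config.pixel_size_um

    tissue, epidermis, _ = _tissue_geometry(config, rng)
    af = _af_volume(config, tissue, rng)
    vessel_voxels, vessel_masks, vessel_centers = _make_vessels(config, tissue, epidermis, rng)
    cells = _place_cells(config, tissue, epidermis, vessel_centers, rng)
    _assign_footprints(config, cells, rng)

    marker_amp = config.marker_snr * max(config.noise_sigma, 0.02)

    # per-section perturbations
    max_rot, max_trans = config.affine_jitter
    transforms: list[TransformPair] = []
    for ridx in range(config.n_sections):
        if max_rot == 0 and max_trans == 0 and config.deform_max_px == 0:
            transforms.append(TransformPair.identity())
            continue
        rot = rng.uniform(-max_rot, max_rot)
        trans = rng.uniform(-max_trans, max_trans, size=2) * px
        center = (cols * px / 2, rows * px / 2)
        aff = make_affine(rotation_deg=rot, translation=tuple(trans), center=center)
        bspl = None
        if config.deform_max_px > 0:
            bspl = make_random_bspline(
                config.image_shape, px, config.deform_max_px * px, rng=rng
            )
        transforms.append(TransformPair(affine=aff, bspline=bspl))

    noise_seeds = rng.integers(0, 2**31 - 1, size=config.n_sections)

    sections: list[Section] = []
    surface_pts = _surface_points(tissue)
    skin_surface: dict[int, np.ndarray] = {}
    for ridx, pidx in enumerate(config.skipped_pattern):
        ref_channels: dict[str, np.ndarray] = {}
        fps = [fp for c in cells for fp in c.footprints if fp.retained_index == ridx]
        for name in config.channels:
            if name == "AF":
                ref_channels[name] = af[ridx].copy()
                continue
            img = np.zeros((rows, cols), dtype=float)
            if name == "DAPI":
                _paint_blobs(img, fps)
            else:
                pos_fps = [
                    (fp, c.marker_level)
                    for c in cells
                    if name in c.markers
                    for fp in c.footprints
                    if fp.retained_index == ridx
                ]
                _paint_disks(img, pos_fps, scale=marker_amp)
                if name == "CD31":
                    img = np.maximum(img, marker_amp * 0.9 * vessel_masks[pidx])
                if name == "AE1":
                    img = np.maximum(img, marker_amp * 0.6 * epidermis)
            # baseline background fluorescence keeps the intensity mixture
            # two-component (no clipped zero spike) as on real detectors
            ref_channels[name] = img + 0.15

        t = transforms[ridx]
        sec_rng = np.random.default_rng(noise_seeds[ridx])
        channels: dict[str, np.ndarray] = {}
        for name, ref_img in ref_channels.items():
            warped = t.resample(ref_img, px, interpolation="linear")
            if config.noise_sigma > 0:
                warped = warped + sec_rng.normal(0.0, config.noise_sigma, size=warped.shape)
            channels[name] = np.clip(warped * _UINT16_SCALE, 0, 65535).astype(np.uint16)
        sections.append(
            Section(
                channels=channels,
                pixel_size_um=px,
                retained_index=ridx,
                physical_index=pidx,
            )
        )
        skin_surface[ridx] = surface_pts.copy()

    truth = PhantomTruth(
        cells=cells,
        vessel_voxels=vessel_voxels,
        skin_surface=skin_surface,
        transforms=transforms,
        section_map={r: p for r, p in enumerate(config.skipped_pattern)},
        tissue_mask=tissue,
        epidermis_mask=epidermis,
        config=config,
    )
    return sections, truth
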