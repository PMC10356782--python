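# Methods

`mxif3d` reconstructs a 3D tissue volume from 2D multiplexed
immunofluorescence (MxIF) serial sections and computes spatial cell
analytics on the result. This note documents the models, the choices made
where the design was open, and what the synthetic phantoms do and do not
demonstrate.

## Problem setting

A fixed tissue block is cut into serial sections (default thickness 5 µm),
and a subset of high-quality sections is retained for staining and imaging
(up to two consecutive physical sections may be skipped between retained
ones). Each retained section yields a multichannel raster: DAPI (nuclei),
an unstained autofluorescence (AF) channel acquired before any staining
round, and N biomarker channels (CD3/CD4/CD8/FOXP3 for T-cell subsets,
CD68 for macrophages, CD31 for vascular endothelium, AE1/CK26 cytokeratin
cocktails for the epidermis, p53/Ki67/DDB2 for damage/proliferation).
Because sections are cut, mounted and cycled independently, each is
arbitrarily rotated, shifted and locally deformed relative to its
neighbors; and because a ~5–10 µm nucleus is thicker than one section, the
same cell appears on 1–3 consecutive sections. Reconstruction must undo
the per-section geometry and merge the redundant per-section detections.

## Preprocessing

- **Illumination correction** follows the flat-field forward model
  `observed = truth × nonuniformity + background×(exposure ratio)`;
  correction subtracts the exposure-scaled background frame and divides by
  the unit-mean non-uniformity field, clipping at zero.
- **Normalization** is per-slide zero-mean/unit-variance (zmuv), computed
  inside the tissue mask when one is available. It is affine and
  order-preserving, so mixture fitting downstream sees relative, not
  absolute, intensities; slide-to-slide intensity drift is removed.
- **AF tissue mask**: Otsu threshold (256 bins over the observed range,
  maximizing between-class variance), morphological closing (disk, default
  radius 5 px; no radius is canonical), largest 8-connected component
  (area ties broken by first pixel in raster order). The threshold adapts
  per section, which is what makes AF masking robust to section-to-section
  AF variation.

## Nuclei and marker classification

- **Nuclei** (default backend): scale-normalized multiscale
  Laplacian-of-Gaussian (negated, so bright blobs peak positive), maximum
  over scales (default 2/3/4/6 µm), threshold (default 0.3 on zmuv input),
  4-connected components, optional marker-controlled watershed split of
  components containing >1 interior LoG maximum, and an area gate
  (default 20–2000 px at 20×-like sampling). The backend is deterministic
  and training-free; a learned segmentation model can be plugged in via
  the `backend` callable (it must return a label raster), keeping the
  rest of the pipeline unchanged.
- **Marker probability**: a two-component Gaussian mixture on pixel
  intensities of each zmuv-normalized marker channel (scikit-learn EM,
  tol 1e-6, max 300 iterations, deterministic seeding). The higher-mean
  component is the positive class; its posterior responsibility is the
  per-pixel positivity probability. Default covariance is *tied* so the
  posterior is a logistic function of intensity and provably monotone;
  `"full"` is available when per-class variances matter. Initialization
  uses the intensity quantiles (25th percentile vs 99.9th): rare positive
  classes (e.g. vessels occupying <1% of tissue) are otherwise missed by
  centroid-based initialization, which prefers splitting the dominant
  background mode.
- **Calling**: per nucleus, `p` = mean positive probability over footprint
  pixels and `overlap` = fraction of footprint pixels above the
  probability threshold. A call is positive iff `p ≥ 0.5` and
  `overlap ≥ 0.1` (defaults; both overridable globally and per marker).
  The overlap gate rejects debris/artefacts that touch a nucleus over a
  small area. The exact fusion rule between pixel probabilities and the
  nucleus mask is an open design point; mean-over-footprint was chosen
  for robustness to single-pixel outliers, with the overlap fraction
  carrying the spatial-consistency information.
- **Structure masks** (vessels, epidermis): Otsu threshold applied to the
  probability values themselves; no largest-component filter (vessels are
  legitimately multiple). A guard returns an empty mask with a warning
  when no probability reaches 0.2 (no structure present in the section).
- **Phenotypes**, in precedence order: CD31+ → endothelial; CD3+CD4+FOXP3+
  → T regulatory; CD3+CD4+ → T helper; CD3+CD8+ → T killer; CD68+ →
  macrophage; AE1/CK26+ → epithelial; else other. CD4/CD8 double-positive
  T cells resolve toward the larger mean probability and are flagged
  ambiguous.

## Registration

All sections are registered to one reference section (user-chosen; default
middle). The AF channel is the substrate because it is imaged before
staining and therefore independent of biomarker signal.

- **Block-matching affine**: the masked reference AF is tiled into 64 px
  blocks at 50% stride; blocks with <25% in-mask pixels are skipped. Each
  block is matched in the moving image by normalized cross-correlation
  within a 32 px search radius (FFT-based template matching with parabolic
  sub-pixel refinement); the best match defines one displacement vector. A
  full 6-parameter affine is fit by least squares, refit after dropping
  the worst 20% of residuals, and the whole procedure is iterated against
  the affinely resampled moving image (up to 10 times, stopping when the
  update is negligible) — a single pure-translation block search
  underestimates rotations on smooth texture and the fixed-point iteration
  removes that bias. Exactly identical inputs short-circuit to identity.
- **B-spline deformable**: cubic B-spline control grid (default 32 px
  spacing), optimized by L-BFGS-B against a 32-bin Mattes mutual-
  information metric over a two-level pyramid (SimpleITK). Control-point
  displacements are bounded (default 30 px). Our own 32-bin NMI
  (`(H(A)+H(B))/H(A,B)`) is evaluated before and after: if the deformable
  stage fails to improve it, the zero-displacement transform is returned
  and the section is marked non-converged, so the stage can never degrade
  the affine alignment.
- **Transform model**: `TransformPair` maps reference-frame points to
  moving-frame points (resampling convention, µm units). Points are mapped
  forward analytically; the inverse inverts the affine in closed form and
  the deformation by fixed-point iteration (converges for the bounded
  smooth fields used here; round-trip error < 0.1 µm in-domain). Label
  images must be resampled with nearest-neighbor interpolation;
  out-of-domain fill is 0.
- **QC**: per-section DSC between the registered AF mask and the reference
  mask, and NCC between adjacent registered AF sections within the
  intersection of their masks (masking before correlation removes
  background pixels that would inflate the score).
- **Volume refinement**: an optional global 3D affine registers the
  reconstructed AF volume to an external reference volume of the intact
  block (e.g. micro-CT). Serial registration alone propagates small errors
  and straightens genuinely curved anatomy (the "banana effect"); one
  global affine against an independent volume restores low-frequency
  geometry.

## Reconstruction and 3D fusion

Registered sections are stacked at their physical z
(`physical_index × thickness`); skipped sections leave real gaps — no
interpolation. Each 2D nucleus is painted one slab thick (sections are
5 µm; nuclei 5–10 µm), and 3D cells are the 26-connected components of the
painted voxels per phenotype (26 rather than 6 so diagonal inter-slab
contact merges; 6 available by flag). Slabs whose z positions differ by
more than `max_z_gap_um` (default 5 µm, i.e. only physically adjacent
sections) are separated by an empty spacer slab before labeling: merging
across unobserved gaps would overcorrect, so cells split by a skipped
section are counted twice rather than invented. Every 2D nucleus belongs
to exactly one 3D cell, hence 3D counts never exceed 2D counts and equal
them only when nothing overlaps. Tissue volume is the voxel count times
`dx·dy·dz`; densities are cells per cm³ (1 cm³ = 1e12 µm³).

## Spatial analytics

Cells are referenced to their section plane (z = slab z). This makes
same-section structure voxels a zero-z-offset subset of the full 3D voxel
set, so per cell `d3D ≤ d2D` and `count3D ≥ count2D` hold by construction
— these inequalities are the mechanism behind shorter vessel distances and
higher neighbor counts in 3D, and they are asserted as invariants.

- **Nearest-structure distance**: Euclidean distance from the cell
  centroid to the nearest structure-positive voxel center (within half a
  voxel of the true structure edge — explicit boundary extraction is not
  worth its complexity at 1–2 µm pixels). The search scans candidates with
  an axis-pruning filter: any voxel whose |dx|, |dy| or |dz| exceeds the
  current minimum cannot win and is skipped before the square root. The
  result — distance and witness voxel — is exactly the exhaustive
  minimum; ties break to the lexicographically smallest (z, y, x) witness.
  Cells whose own section holds no structure are flagged and excluded
  from 2D summaries.
- **Skin-surface distance**: because the skin surface is non-uniform, the
  distance from a (3D-referenced) cell is computed in-plane against the
  surface polyline of its nearest retained section, rather than against a
  meshed 3D surface.
- **Cluster density**: number of neighbor cells within a radius of each
  index T helper cell, at 15 and 30 µm by default. The neighbor set
  defaults to T cells (helper+killer+regulatory) and can be widened to all
  immune cells; the index cell never counts itself. Implemented with a
  k-d tree and verified against an all-pairs oracle.
- **Statistics**: two-sided two-sample Kolmogorov–Smirnov (asymptotic p),
  Spearman rank correlation with Benjamini–Hochberg adjustment within each
  hypothesis family, and the two-sided Wilcoxon rank-sum test (exact for
  small tie-free samples). All delegate to scipy/statsmodels; tests verify
  them against hand-written oracles (ECDF scan, BH step-up, enumeration).

## The phantom generator

The generator produces stacks with known truth: a tissue band with a
sinusoidal skin surface and an epidermis layer; a smooth 3D random AF
field (Gaussian-filtered noise, correlation length ~6 px in-plane and
~1 section in z) with tissue intensity well above background so Otsu
masking recovers the tissue region, as on real unquenched AF; CD31+
vessel tubes drifting smoothly through the stack; nuclei as Gaussian
blobs (σ 3–6 px) whose spherical extent (radius 4–7.5 µm) intersects 1–3
sections; marker channels painted as flat disks at a per-nucleus intensity
drawn from the positive component, `marker_snr` noise-SDs above a nonzero
baseline (so the pixel mixture is genuinely two-component, without a
clipped-at-zero artifact); per-section random affine jitter (default ≤3°,
≤10 px), bounded random B-spline deformation (default ≤10 px) and Gaussian
noise. Intensities are stored as uint16. A single seed determines
everything bit-exactly.

What the phantom does **not** emulate: realistic tissue texture, hair
follicles and adnexal structures, staining artefacts beyond Gaussian
noise, autofluorescence quenching, inter-FOV stitching seams, or
overlapping/touching nuclei at real packing densities (cells are placed
with separation that keeps distinct nuclei from fusing in 3D). Passing
benchmarks therefore demonstrates correctness of the algorithms under the
stated geometric and intensity model, not performance on real slides.
Published human-skin quantities (median T-cell counts, absolute vessel
distances) depend on real anatomy and are out of reach of a phantom; the
benchmarks reproduce the *methodological* quality metrics instead.

## Benchmarks (scripts/acceptance.py)

- Registration: 24-section phantom, per-section perturbations ≤3°
  rotation, ≤10 px translation, ≤10 px deformation; report mean
  registered-mask DSC vs the reference (the reference section is excluded
  from the mean — it would only inflate it) and mean adjacent-section NCC.
  Typical values ≈ 0.98 and ≈ 0.65; runs in ~3 minutes on one CPU.
- Classification: one 640×800 px section with 500 nuclei, 40%
  truth-positive at SNR 6; zmuv → GMM → calling at default thresholds;
  report accuracy/sensitivity/specificity vs truth in percent. Typical
  values ≈ 99/99/100; runs in seconds.

Problem sizes were chosen as the smallest stacks at which the metrics are
stable across seeds.

## Known limitations

- The deformable stage optimizes Mattes mutual information (the standard
  ITK implementation) while NMI is the reported quality measure and
  monotonicity guard; the two are strongly correlated but not identical.
- Whole-cell/membrane segmentation is out of scope: classification is
  limited to nuclear and peri-nuclear markers.
- The learned nuclei backend is an interface only; no training tooling is
  shipped.
- `refine_to_reference_volume` expects volumes that already overlap
  substantially after center initialization; it is a refinement, not a
  global search.
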