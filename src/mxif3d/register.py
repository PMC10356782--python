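"""Serial-section registration against a reference section.

Every section's masked autofluorescence (AF) image is aligned to a chosen
reference section in two stages: a block-matching affine (sparse
correspondences from local normalized cross-correlation, fit by trimmed
least squares) followed by a cubic B-spline deformable refinement driven by
mutual information. Registration quality is tracked as the Dice similarity
coefficient (DSC) between each registered tissue mask and the reference
mask, and the normalized cross correlation (NCC) between adjacent
registered AF sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from skimage.feature import match_template

from .preprocess import compute_af_mask
from .sections import Section
from .transforms import (
    TransformPair,
    apply_transform_image,
    apply_transform_points,
)

__all__ = [
    "RegistrationQC",
    "dice",
    "ncc",
    "nmi",
    "block_matching_affine",
    "bspline_deformable",
    "register_stack",
    "refine_to_reference_volume",
    "apply_transform_image",
    "apply_transform_points",
    "TransformPair",
]


# ------------------------------------------------------------------ similarity metrics


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A|+|B|)`` for binary rasters."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("shapes do not match")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("both masks empty")
    return 2.0 * int((a & b).sum()) / (na + nb)


def ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Pearson correlation of co-located intensities (optionally in-mask)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shapes do not match")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        av, bv = a[mask], b[mask]
    else:
        av, bv = a.ravel(), b.ravel()
    if av.size < 2 or np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ValueError("constant image in NCC computation")
    av = av - av.mean()
    bv = bv - bv.mean()
    return float(np.dot(av, bv) / (np.linalg.norm(av) * np.linalg.norm(bv)))


def nmi(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None, bins: int = 32) -> float:
    """Normalized mutual information ``(H(A)+H(B)) / H(A,B)`` from a joint
    histogram of in-mask intensities."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        av, bv = a[mask], b[mask]
    else:
        av, bv = a.ravel(), b.ravel()
    joint, _, _ = np.histogram2d(av, bv, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
    hxy = -np.sum(pxy[pxy > 0] * np.log(pxy[pxy > 0]))
    if hxy == 0:
        return 2.0
    return float((hx + hy) / hxy)


# ------------------------------------------------------------------ block matching


def _subpixel_peak(score: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Parabolic refinement of an integer NCC peak, one axis at a time."""

    def refine(vm: float, v0: float, vp: float) -> float:
        denom = vm - 2 * v0 + vp
        if denom >= 0 or abs(denom) < 1e-12:
            return 0.0
        return float(np.clip(0.5 * (vm - vp) / denom, -0.5, 0.5))

    dr = dc = 0.0
    if 0 < r < score.shape[0] - 1:
        dr = refine(score[r - 1, c], score[r, c], score[r + 1, c])
    if 0 < c < score.shape[1] - 1:
        dc = refine(score[r, c - 1], score[r, c], score[r, c + 1])
    return dr, dc


def _match_blocks(
    ref: np.ndarray,
    mov: np.ndarray,
    ref_mask: np.ndarray,
    block_size_px: int,
    search_radius_px: int,
    min_coverage: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """For each grid block of the reference with enough in-mask content,
    find the best NCC match in the moving image within the search radius.
    Returns (ref_centers, mov_centers, peak_ncc) in (row, col) pixels."""
    rows, cols = ref.shape
    bs, sr = block_size_px, search_radius_px
    stride = max(1, bs // 2)
    ref_pts, mov_pts, scores = [], [], []
    for r0 in range(0, rows - bs + 1, stride):
        for c0 in range(0, cols - bs + 1, stride):
            block_mask = ref_mask[r0 : r0 + bs, c0 : c0 + bs]
            if block_mask.mean() < min_coverage:
                continue
            block = ref[r0 : r0 + bs, c0 : c0 + bs]
            if block.std() < 1e-9:
                continue
            wr0, wc0 = max(0, r0 - sr), max(0, c0 - sr)
            wr1, wc1 = min(rows, r0 + bs + sr), min(cols, c0 + bs + sr)
            window = mov[wr0:wr1, wc0:wc1]
            if window.shape[0] < bs or window.shape[1] < bs or window.std() < 1e-9:
                continue
            score = match_template(window, block, pad_input=False)
            pr, pc = np.unravel_index(np.argmax(score), score.shape)
            dr, dc = _subpixel_peak(score, pr, pc)
            match_r = wr0 + pr + dr
            match_c = wc0 + pc + dc
            ref_pts.append((r0 + bs / 2, c0 + bs / 2))
            mov_pts.append((match_r + bs / 2, match_c + bs / 2))
            scores.append(float(score[pr, pc]))
    return np.array(ref_pts), np.array(mov_pts), np.array(scores)


def _fit_affine_trimmed(
    ref_xy: np.ndarray, mov_xy: np.ndarray, trim_fraction: float = 0.2
) -> np.ndarray:
    """Least-squares 2x3 affine mov = A(ref), refit after dropping the worst
    ``trim_fraction`` of correspondences by residual."""
    def lsq(rp: np.ndarray, mp: np.ndarray) -> np.ndarray:
        H = np.column_stack([rp, np.ones(len(rp))])
        sol, *_ = np.linalg.lstsq(H, mp, rcond=None)
        return sol.T  # (2, 3)

    A = lsq(ref_xy, mov_xy)
    if trim_fraction > 0 and len(ref_xy) >= 5:
        pred = ref_xy @ A[:, :2].T + A[:, 2]
        res = np.linalg.norm(pred - mov_xy, axis=1)
        keep = res <= np.quantile(res, 1.0 - trim_fraction)
        if keep.sum() >= 3:
            A = lsq(ref_xy[keep], mov_xy[keep])
    return A


def block_matching_affine(
    ref: np.ndarray,
    mov: np.ndarray,
    ref_mask: np.ndarray | None = None,
    block_size_px: int = 64,
    search_radius_px: int = 32,
    min_blocks: int = 6,
    min_coverage: float = 0.25,
    n_refine: int = 10,
    pixel_size_um: float = 1.0,
) -> np.ndarray:
    """Affine (2x3, µm frame, ref -> mov) from block correspondences.

    Each reference block with at least ``min_coverage`` in-mask pixels is
    matched by normalized cross correlation within ``search_radius_px`` of
    its position; the displacement of the best-matching block defines one
    correspondence. A trimmed least-squares affine is fit to all
    correspondences, and the procedure is iterated (up to ``n_refine``
    times, stopping once the update is negligible) against the affinely
    resampled moving image: a single pure-translation block search
    underestimates rotations on smooth texture, and the fixed-point
    iteration removes that bias.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref_mask is None:
        ref_mask = ref > 0
    if not ref_mask.any() or not np.any(mov):
        raise ValueError("empty mask: nothing to register")
    if ref.shape == mov.shape and np.array_equal(ref, mov):
        return np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    affine_px = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    for _ in range(max(1, n_refine)):
        if np.allclose(affine_px, [[1, 0, 0], [0, 1, 0]]):
            mov_cur = mov
        else:
            pair = TransformPair(affine=affine_px)  # px units within this loop
            mov_cur = pair.resample(mov, 1.0, interpolation="linear")
        ref_pts, mov_pts, _ = _match_blocks(
            ref, mov_cur, ref_mask, block_size_px, search_radius_px, min_coverage
        )
        if len(ref_pts) < min_blocks:
            raise ValueError(
                f"insufficient texture: only {len(ref_pts)} usable blocks "
                f"(need {min_blocks})"
            )
        # (row, col) -> (x, y)
        ref_xy = ref_pts[:, ::-1]
        mov_xy = mov_pts[:, ::-1]
        B = _fit_affine_trimmed(ref_xy, mov_xy)
        # compose: total = current ∘ B  (B applied first)
        M = affine_px[:, :2] @ B[:, :2]
        t = affine_px[:, :2] @ B[:, 2] + affine_px[:, 2]
        affine_px = np.column_stack([M, t])
        if (
            np.abs(B[:, :2] - np.eye(2)).max() < 5e-4
            and np.abs(B[:, 2]).max() < 0.05
        ):
            break
    out = affine_px.copy()
    out[:, 2] *= pixel_size_um
    return out


# ------------------------------------------------------------------ deformable stage


def bspline_deformable(
    ref: np.ndarray,
    mov_affine_aligned: np.ndarray,
    grid_spacing_px: int = 32,
    nmi_bins: int = 32,
    max_iter: int = 60,
    pixel_size_um: float = 1.0,
    mask: np.ndarray | None = None,
    max_displacement_px: float = 30.0,
) -> tuple[sitk.BSplineTransform, dict]:
    """Cubic B-spline deformation of the affinely aligned pair.

    Control-point displacements are optimized (L-BFGS-B, bounded by
    ``max_displacement_px``) to maximize a mutual-information criterion over
    a two-level coarse-to-fine pyramid. The returned QC dict reports the
    normalized mutual information before and after; if the optimization
    fails to improve it, a zero-displacement transform is returned and
    ``converged`` is False, so the stage never degrades the affine result.
    """
    if grid_spacing_px < 4:
        raise ValueError("grid spacing must be >= 4 px")
    ref = np.asarray(ref, dtype=np.float32)
    mov = np.asarray(mov_affine_aligned, dtype=np.float32)
    nmi_before = nmi(ref, mov, mask=mask, bins=nmi_bins)

    fixed = sitk.GetImageFromArray(ref)
    moving = sitk.GetImageFromArray(mov)
    for img in (fixed, moving):
        img.SetSpacing((pixel_size_um, pixel_size_um))

    mesh = [max(2, s // grid_spacing_px) for s in ref.shape[::-1]]
    tx0 = sitk.BSplineTransformInitializer(fixed, mesh)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=nmi_bins)
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(0.5, seed=12345)
    reg.SetInterpolator(sitk.sitkLinear)
    bound = max_displacement_px * pixel_size_um
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=1e-7,
        numberOfIterations=max_iter,
        maximumNumberOfCorrections=5,
        maximumNumberOfFunctionEvaluations=2000,
        costFunctionConvergenceFactor=1e7,
        lowerBound=-bound,
        upperBound=bound,
    )
    reg.SetInitialTransform(tx0, inPlace=True)
    reg.SetShrinkFactorsPerLevel([2, 1])
    reg.SetSmoothingSigmasPerLevel([1, 0])
    try:
        result = reg.Execute(fixed, moving)
    except RuntimeError:
        result = tx0
    bspline = sitk.BSplineTransform(result)

    warped = sitk.GetArrayFromImage(
        sitk.Resample(moving, fixed, bspline, sitk.sitkLinear, 0.0)
    )
    nmi_after = nmi(ref, warped, mask=mask, bins=nmi_bins)
    qc = {
        "nmi_before": nmi_before,
        "nmi_after": nmi_after,
        "iterations": max_iter,
        "converged": True,
    }
    if nmi_after < nmi_before - 1e-9:
        # best-so-far is the affine alignment itself
        zero = sitk.BSplineTransformInitializer(fixed, mesh)
        qc["converged"] = False
        qc["nmi_after"] = nmi_before
        return zero, qc
    return bspline, qc


# ------------------------------------------------------------------ stack registration


@dataclass
class RegistrationQC:
    """Per-section DSC against the reference mask and NCC between adjacent
    registered AF sections (within the intersection of their masks)."""

    reference_index: int
    dsc: list[float] = field(default_factory=list)
    ncc_adjacent: list[float] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)
    iterations: int = 0

    @property
    def mean_dsc(self) -> float:
        vals = [d for i, d in enumerate(self.dsc) if i != self.reference_index]
        return float(np.mean(vals)) if vals else 1.0

    @property
    def mean_ncc(self) -> float:
        return float(np.mean(self.ncc_adjacent)) if self.ncc_adjacent else 1.0

    def to_dict(self) -> dict:
        return {
            "reference_index": self.reference_index,
            "dsc": self.dsc,
            "ncc_adjacent": self.ncc_adjacent,
            "converged": self.converged,
            "mean_dsc": self.mean_dsc,
            "mean_ncc": self.mean_ncc,
        }


def register_stack(
    sections: list[Section],
    reference_index: int | None = None,
    block_size_px: int = 64,
    search_radius_px: int = 32,
    grid_spacing_px: int = 32,
    nmi_bins: int = 32,
    max_iter: int = 60,
    closing_radius_px: int = 5,
    deformable: bool = True,
) -> tuple[list[TransformPair], RegistrationQC]:
    """Register every section's masked AF image to the reference section.

    Returns one :class:`TransformPair` per section (identity for the
    reference) plus registration QC. Tissue masks are computed on the AF
    channel (Otsu + closing + largest component) and stored on each section.
    """
    if not sections:
        raise ValueError("empty stack")
    if reference_index is None:
        reference_index = len(sections) // 2
    if not 0 <= reference_index < len(sections):
        raise ValueError(f"reference_index {reference_index} out of range")
    px = sections[0].pixel_size_um

    afs, masks = [], []
    for sec in sections:
        af = np.asarray(sec.channels["AF"], dtype=float)
        mask = compute_af_mask(af, closing_radius_px=closing_radius_px)
        sec.af_mask = mask
        afs.append(af)
        masks.append(mask)

    ref_af = afs[reference_index] * masks[reference_index]
    ref_mask = masks[reference_index]

    transforms: list[TransformPair] = []
    qc = RegistrationQC(reference_index=reference_index, iterations=max_iter)
    warped_afs: list[np.ndarray] = []
    warped_masks: list[np.ndarray] = []
    for i, sec in enumerate(sections):
        if i == reference_index:
            pair = TransformPair.identity()
            qc.converged.append(True)
        else:
            mov_af = afs[i] * masks[i]
            try:
                affine = block_matching_affine(
                    ref_af,
                    mov_af,
                    ref_mask=ref_mask,
                    block_size_px=block_size_px,
                    search_radius_px=search_radius_px,
                    pixel_size_um=px,
                )
            except ValueError as exc:
                raise RuntimeError(
                    f"affine registration failed for section {i} "
                    f"(physical {sec.physical_index}): {exc}"
                ) from exc
            affine_pair = TransformPair(affine=affine)
            mov_aligned = affine_pair.resample(mov_af, px, interpolation="linear")
            if deformable:
                bspline, bqc = bspline_deformable(
                    ref_af,
                    mov_aligned,
                    grid_spacing_px=grid_spacing_px,
                    nmi_bins=nmi_bins,
                    max_iter=max_iter,
                    pixel_size_um=px,
                    mask=ref_mask,
                )
                pair = TransformPair(affine=affine, bspline=bspline)
                qc.converged.append(bool(bqc["converged"]))
            else:
                pair = affine_pair
                qc.converged.append(True)
        transforms.append(pair)
        w_mask = pair.resample(masks[i].astype(np.uint8), px, interpolation="nearest") > 0
        w_af = pair.resample(afs[i], px, interpolation="linear")
        warped_masks.append(w_mask)
        warped_afs.append(w_af)
        qc.dsc.append(dice(w_mask, ref_mask))

    for i in range(len(sections) - 1):
        inter = warped_masks[i] & warped_masks[i + 1]
        if inter.sum() < 16:
            qc.ncc_adjacent.append(0.0)
            continue
        qc.ncc_adjacent.append(ncc(warped_afs[i], warped_afs[i + 1], mask=inter))
    return transforms, qc


# ------------------------------------------------------------------ volume refinement


def refine_to_reference_volume(
    reconstructed: np.ndarray,
    reference: np.ndarray,
    spacing_um: tuple[float, float, float],
    max_iter: int = 100,
) -> tuple[np.ndarray, dict]:
    """3D affine refinement of a reconstructed stack against an external
    reference volume (e.g. micro-CT of the block before sectioning).

    Serial-section registration alone can straighten genuinely curved
    anatomy ("banana effect"); a single global 3D affine to an
    independently acquired volume restores low-frequency geometry. Returns
    a 3x4 affine (reference-volume frame -> reconstructed frame, µm,
    resampling convention) and a QC dict.
    """
    recon = np.asarray(reconstructed, dtype=np.float32)
    ref = np.asarray(reference, dtype=np.float32)
    if recon.size == 0 or ref.size == 0:
        raise ValueError("empty volume")
    dx, dy, dz = spacing_um
    fixed = sitk.GetImageFromArray(ref)
    moving = sitk.GetImageFromArray(recon)
    for img in (fixed, moving):
        img.SetSpacing((dx, dy, dz))

    tx0 = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.AffineTransform(3),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(0.5, seed=12345)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=1e-8,
        numberOfIterations=max_iter,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(tx0, inPlace=True)
    reg.SetShrinkFactorsPerLevel([2, 1])
    reg.SetSmoothingSigmasPerLevel([1, 0])
    result = reg.Execute(fixed, moving)
    aff = sitk.AffineTransform(result)
    M = np.array(aff.GetMatrix()).reshape(3, 3)
    c = np.array(aff.GetCenter())
    t = np.array(aff.GetTranslation()) + c - M @ c
    metric = reg.GetMetricValue()
    overlap_check = sitk.GetArrayFromImage(
        sitk.Resample(moving, fixed, aff, sitk.sitkLinear, 0.0)
    )
    if not np.any(overlap_check):
        raise RuntimeError("volumes do not overlap after initialization")
    return np.column_stack([M, t]), {"metric": float(metric), "iterations": max_iter}
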