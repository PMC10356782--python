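"""Spatial transform model shared by the phantom generator and the registration stage.

A section-to-reference mapping is represented as a :class:`TransformPair`:
an invertible 2D affine followed by a cubic B-spline free-form deformation.
Both pieces act in the *resampling* (pull-back) convention: the pair maps a
point in the reference frame to the corresponding point in the moving
(unregistered) section, so resampling a moving image through the pair
produces its registered counterpart.

All coordinates are physical, in micrometres, with ``x = col * pixel_size``
and ``y = row * pixel_size`` (images are row-major ``(row, col)`` arrays).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "TransformPair",
    "make_affine",
    "make_random_bspline",
    "apply_transform_image",
    "apply_transform_points",
]

_IDENTITY_AFFINE = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


def make_affine(
    rotation_deg: float = 0.0,
    translation: tuple[float, float] = (0.0, 0.0),
    center: tuple[float, float] = (0.0, 0.0),
    scale: float = 1.0,
) -> np.ndarray:
    """Build a 2x3 affine (rotation about ``center``, then translation).

    Parameters are in physical units; ``translation`` and ``center`` are
    ``(x, y)`` in µm.
    """
    th = np.deg2rad(rotation_deg)
    R = scale * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    cx, cy = center
    t = np.asarray(translation, dtype=float) + np.array([cx, cy]) - R @ np.array([cx, cy])
    return np.column_stack([R, t])


def make_random_bspline(
    image_shape: tuple[int, int],
    pixel_size_um: float,
    max_displacement_um: float,
    mesh_size: tuple[int, int] = (4, 4),
    rng: np.random.Generator | None = None,
) -> sitk.BSplineTransform:
    """Random smooth cubic B-spline deformation bounded by ``max_displacement_um``.

    Coefficients are drawn uniformly; because cubic B-spline basis functions
    form a partition of unity, the per-axis displacement never exceeds the
    largest coefficient magnitude, so the Euclidean bound is enforced by
    scaling each axis to ``max_displacement_um / sqrt(2)``.
    """
    rng = rng or np.random.default_rng()
    rows, cols = image_shape
    tx = sitk.BSplineTransform(2, 3)
    tx.SetTransformDomainOrigin((0.0, 0.0))
    tx.SetTransformDomainPhysicalDimensions((cols * pixel_size_um, rows * pixel_size_um))
    tx.SetTransformDomainMeshSize(mesh_size)
    tx.SetTransformDomainDirection((1.0, 0.0, 0.0, 1.0))
    n = len(tx.GetParameters())
    bound = max_displacement_um / np.sqrt(2.0)
    tx.SetParameters(tuple(rng.uniform(-bound, bound, size=n)))
    return tx


def _bspline_to_state(tx: sitk.BSplineTransform) -> dict:
    return {
        "fixed_parameters": list(tx.GetFixedParameters()),
        "parameters": list(tx.GetParameters()),
    }


def _bspline_from_state(state: dict) -> sitk.BSplineTransform:
    tx = sitk.BSplineTransform(2, 3)
    tx.SetFixedParameters(state["fixed_parameters"])
    tx.SetParameters(state["parameters"])
    return tx


@dataclass
class TransformPair:
    """Affine + B-spline deformable mapping, reference frame -> moving frame.

    ``affine`` is a 2x3 matrix in µm. ``bspline`` (optional) acts in the
    reference frame before the affine: ``T(p) = A(D(p))``, matching the
    registration order "affine first, then deformable refinement of the
    affinely aligned pair".
    """

    affine: np.ndarray = field(default_factory=lambda: _IDENTITY_AFFINE.copy())
    bspline: sitk.BSplineTransform | None = None

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (2, 3):
            raise ValueError("affine must be a 2x3 matrix")
        if not np.all(np.isfinite(self.affine)):
            raise ValueError("non-finite affine parameters")
        if abs(np.linalg.det(self.affine[:, :2])) <= 1e-6:
            raise ValueError("affine is not invertible")
        if self.bspline is not None and not np.all(
            np.isfinite(np.asarray(self.bspline.GetParameters()))
        ):
            raise ValueError("non-finite B-spline parameters")

    # ------------------------------------------------------------------ basics
    @classmethod
    def identity(cls) -> "TransformPair":
        return cls()

    @property
    def is_identity(self) -> bool:
        if not np.allclose(self.affine, _IDENTITY_AFFINE):
            return False
        if self.bspline is None:
            return True
        return not np.any(np.asarray(self.bspline.GetParameters()))

    def to_sitk(self) -> sitk.Transform:
        aff = sitk.AffineTransform(2)
        aff.SetMatrix(self.affine[:, :2].ravel())
        aff.SetTranslation(self.affine[:, 2])
        if self.bspline is None:
            return aff
        comp = sitk.CompositeTransform(2)
        comp.AddTransform(aff)          # applied second
        comp.AddTransform(self.bspline)  # applied first
        return comp

    # ------------------------------------------------------------------ points
    def transform_points(self, points_um: np.ndarray, direction: str = "forward") -> np.ndarray:
        """Map ``(N, 2)`` physical points through the pair.

        ``forward`` maps reference-frame points into the moving frame (the
        resampling direction); ``inverse`` maps moving-frame points (e.g.
        cell centroids measured on an unregistered section) into the
        reference frame. The B-spline inverse is computed by fixed-point
        iteration, which converges for the bounded, smooth deformations used
        here.
        """
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        if pts.shape[1] != 2:
            raise ValueError("points must be (N, 2)")
        if not np.all(np.isfinite(pts)):
            raise ValueError("non-finite points")
        if direction == "forward":
            out = pts
            if self.bspline is not None:
                out = np.array([self.bspline.TransformPoint(tuple(p)) for p in out])
            return out @ self.affine[:, :2].T + self.affine[:, 2]
        if direction != "inverse":
            raise ValueError(f"unknown direction {direction!r}")
        A = self.affine[:, :2]
        out = np.linalg.solve(A, (pts - self.affine[:, 2]).T).T
        if self.bspline is not None:
            out = np.array([self._invert_bspline_point(p) for p in out])
        return out

    def _invert_bspline_point(self, q: np.ndarray, max_iter: int = 50, tol: float = 1e-4) -> np.ndarray:
        # solve p + u(p) = q by p <- q - u(p)
        assert self.bspline is not None
        p = np.asarray(q, dtype=float)
        for _ in range(max_iter):
            disp = np.asarray(self.bspline.TransformPoint(tuple(p))) - p
            p_new = q - disp
            if np.max(np.abs(p_new - p)) < tol:
                return p_new
            p = p_new
        return p

    # ------------------------------------------------------------------ images
    def resample(
        self,
        image: np.ndarray,
        pixel_size_um: float,
        interpolation: str = "linear",
        inverse: bool = False,
    ) -> np.ndarray:
        """Resample ``image`` through the pair (or its inverse).

        The identity pair is a bit-exact no-op for either interpolator.
        """
        if interpolation not in ("nearest", "linear"):
            raise ValueError(f"unknown interpolation {interpolation!r}")
        if self.is_identity:
            return image.copy()
        img = sitk.GetImageFromArray(np.ascontiguousarray(image))
        img.SetSpacing((pixel_size_um, pixel_size_um))
        tx: sitk.Transform = self.to_sitk()
        if inverse:
            tx = self._inverse_sitk(image.shape, pixel_size_um)
        interp = sitk.sitkNearestNeighbor if interpolation == "nearest" else sitk.sitkLinear
        out = sitk.Resample(img, img, tx, interp, 0.0, img.GetPixelID())
        return sitk.GetArrayFromImage(out)

    def _inverse_sitk(self, shape: tuple[int, int], pixel_size_um: float) -> sitk.Transform:
        """Dense inverse of the full pair over the image domain."""
        rows, cols = shape
        fld = sitk.TransformToDisplacementField(
            self.to_sitk(),
            sitk.sitkVectorFloat64,
            (cols, rows),
            (0.0, 0.0),
            (pixel_size_um, pixel_size_um),
            (1.0, 0.0, 0.0, 1.0),
        )
        inv = sitk.InvertDisplacementField(
            fld,
            maximumNumberOfIterations=50,
            meanErrorToleranceThreshold=1e-4,
            maxErrorToleranceThreshold=1e-3,
            enforceBoundaryCondition=True,
        )
        return sitk.DisplacementFieldTransform(inv)

    def inverted(self, shape: tuple[int, int], pixel_size_um: float) -> "TransformPair":
        """Approximate inverse pair (affine inverted exactly; deformation
        inverted as a dense field refit is not needed for resampling, so the
        inverse is exposed through :meth:`resample` with ``inverse=True``)."""
        A = self.affine[:, :2]
        Ainv = np.linalg.inv(A)
        aff = np.column_stack([Ainv, -Ainv @ self.affine[:, 2]])
        if self.bspline is None:
            return TransformPair(affine=aff)
        raise NotImplementedError("use resample(..., inverse=True) for deformable pairs")

    # ------------------------------------------------------------------ (de)serialization
    def to_dict(self) -> dict:
        d: dict = {"affine": self.affine.tolist()}
        if self.bspline is not None:
            d["bspline"] = _bspline_to_state(self.bspline)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TransformPair":
        bspline = _bspline_from_state(d["bspline"]) if "bspline" in d else None
        return cls(affine=np.asarray(d["affine"]), bspline=bspline)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "TransformPair":
        return cls.from_dict(json.loads(s))


def apply_transform_points(
    points_um: np.ndarray, t: TransformPair, direction: str = "forward"
) -> np.ndarray:
    """Functional alias for :meth:`TransformPair.transform_points`."""
    return t.transform_points(points_um, direction=direction)


def apply_transform_image(
    image: np.ndarray,
    t: TransformPair,
    pixel_size_um: float = 1.0,
    interpolation: str = "linear",
    inverse: bool = False,
) -> np.ndarray:
    """Resample an intensity or label raster through a transform pair.

    Label images must use ``nearest`` so the label set is preserved.
    """
    return t.resample(image, pixel_size_um, interpolation=interpolation, inverse=inverse)
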