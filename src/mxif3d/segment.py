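"""Nuclei detection, GMM marker classification and phenotype assignment.

Marker positivity is decided without manual gating: a two-component Gaussian
mixture is fit to the pixel intensities of each marker channel, the
component with the larger mean is taken as the positive class, and its
posterior responsibility becomes a per-pixel positivity probability. Calls
are then made per nucleus by fusing the probability map with the nucleus
footprint (mean probability + fraction of footprint pixels above threshold);
a low overlap fraction rejects imaging artefacts and debris that produce
high probabilities on only a sliver of a nucleus.

Nuclei come from a classical multiscale Laplacian-of-Gaussian detector with
optional watershed splitting. The detector is deliberately deterministic and
training-free; a learned encoder-decoder backend can be plugged in through
``segment_nuclei(..., backend=...)`` for users with annotated data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed
from sklearn.mixture import GaussianMixture

__all__ = [
    "NucleusInstance",
    "MarkerCall",
    "CellRecord2D",
    "GMMFit",
    "multiscale_log",
    "segment_nuclei",
    "nuclei_from_labels",
    "fit_gmm_two_class",
    "call_marker_on_nuclei",
    "segment_structure_mask",
    "phenotype_cells",
]

REQUIRED_PHENOTYPE_MARKERS = ("CD3", "CD4", "CD8", "FOXP3", "CD68", "CD31")
EPITHELIAL_MARKERS = ("AE1", "CK26")


@dataclass
class NucleusInstance:
    """One segmented nucleus on one section."""

    id: int
    retained_index: int
    pixels: np.ndarray  # (N, 2) (row, col)
    centroid_um: tuple[float, float]  # (x, y)
    area_px: int


@dataclass
class MarkerCall:
    nucleus_id: int
    marker: str
    p: float  # mean positive-class probability over the nucleus
    overlap_fraction: float
    positive: bool


@dataclass
class CellRecord2D:
    nucleus: NucleusInstance
    calls: dict[str, MarkerCall]
    phenotype: str
    ambiguous: bool = False


@dataclass
class GMMFit:
    """Two-component intensity mixture for one marker channel."""

    means: np.ndarray  # (2,) sorted ascending: (background, positive)
    variances: np.ndarray
    weights: np.ndarray
    prob_map: np.ndarray  # positive-class responsibility per pixel
    mask: np.ndarray | None
    log_likelihood: list[float]
    converged: bool
    seed: int

    @property
    def positive_mean(self) -> float:
        return float(self.means[1])

    def is_monotone(self, n_check: int = 512) -> bool:
        """Empirical check that probability is non-decreasing in intensity."""
        vals = self.prob_map if self.mask is None else self.prob_map[self.mask]
        src = self._source if self.mask is None else self._source[self.mask]
        order = np.argsort(src.ravel(), kind="stable")
        p_sorted = vals.ravel()[order]
        idx = np.linspace(0, p_sorted.size - 1, min(n_check, p_sorted.size)).astype(int)
        sub = p_sorted[idx]
        return bool(np.all(np.diff(sub) >= -1e-9))

    _source: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


# ------------------------------------------------------------------ LoG features


def multiscale_log(
    image: np.ndarray, scales_um: Sequence[float], pixel_size_um: float = 1.0
) -> np.ndarray:
    """Scale-normalized Laplacian-of-Gaussian responses, one per scale.

    Responses are ``-sigma^2 * LoG`` so bright blobs produce positive peaks;
    for a Gaussian blob the strongest response across scales occurs at the
    scale matching the blob width. The operator is linear, and a constant
    image yields identically zero responses.
    """
    image = np.asarray(image, dtype=float)
    if len(scales_um) == 0:
        raise ValueError("empty scale list")
    scales = np.asarray(scales_um, dtype=float)
    if np.any(scales <= 0) or np.any(np.diff(scales) < 0):
        raise ValueError("scales must be positive and sorted ascending")
    out = np.empty((len(scales), *image.shape))
    for i, s_um in enumerate(scales):
        s_px = s_um / pixel_size_um
        out[i] = -(s_px**2) * ndi.gaussian_laplace(image, sigma=s_px)
    return out


def _centroid_um(pixels: np.ndarray, pixel_size_um: float) -> tuple[float, float]:
    r, c = pixels[:, 0].mean(), pixels[:, 1].mean()
    return (float(c * pixel_size_um), float(r * pixel_size_um))


def nuclei_from_labels(
    label_image: np.ndarray, pixel_size_um: float, retained_index: int
) -> list[NucleusInstance]:
    """Build nucleus instances from a label raster (0 = background).

    Instance ids are the label values minus one, so truth label images
    round-trip cell identities.
    """
    out: list[NucleusInstance] = []
    for lab in np.unique(label_image):
        if lab == 0:
            continue
        px = np.column_stack(np.nonzero(label_image == lab))
        out.append(
            NucleusInstance(
                id=int(lab) - 1,
                retained_index=retained_index,
                pixels=px,
                centroid_um=_centroid_um(px, pixel_size_um),
                area_px=len(px),
            )
        )
    return out


def segment_nuclei(
    dapi: np.ndarray,
    log_scales_um: Sequence[float] = (2.0, 3.0, 4.0, 6.0),
    response_threshold: float = 0.3,
    min_area_px: int = 20,
    max_area_px: int = 2000,
    split: bool = True,
    pixel_size_um: float = 1.0,
    retained_index: int = 0,
    backend: Callable[[np.ndarray], np.ndarray] | None = None,
) -> list[NucleusInstance]:
    """Detect nuclei on a zero-mean/unit-variance DAPI image.

    Default backend: threshold the maximum-over-scales LoG response, take
    4-connected components, optionally split components containing more than
    one interior LoG maximum with a marker-controlled watershed, and filter
    by area. ``backend`` may replace the foreground/label step with any
    callable returning a label raster (e.g. a trained encoder-decoder
    model); the area filter and centroid computation still apply.
    """
    dapi = np.asarray(dapi, dtype=float)
    if backend is not None:
        labels = np.asarray(backend(dapi))
    else:
        resp = multiscale_log(dapi, log_scales_um, pixel_size_um).max(axis=0)
        fg = resp > response_threshold
        labels, _ = ndi.label(fg, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        if split:
            labels = _watershed_split(resp, labels, response_threshold)
    out: list[NucleusInstance] = []
    next_id = 0
    for lab in range(1, labels.max() + 1):
        px = np.column_stack(np.nonzero(labels == lab))
        if not (min_area_px <= len(px) <= max_area_px):
            continue
        out.append(
            NucleusInstance(
                id=next_id,
                retained_index=retained_index,
                pixels=px,
                centroid_um=_centroid_um(px, pixel_size_um),
                area_px=len(px),
            )
        )
        next_id += 1
    return out


def _watershed_split(resp: np.ndarray, labels: np.ndarray, threshold: float) -> np.ndarray:
    """Split components with more than one interior LoG maximum."""
    out = labels.copy()
    next_label = labels.max() + 1
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        peaks = peak_local_max(
            np.where(comp, resp, -np.inf),
            min_distance=3,
            threshold_abs=threshold,
            exclude_border=False,
        )
        if len(peaks) <= 1:
            continue
        markers = np.zeros_like(labels)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        ws = watershed(-resp, markers=markers, mask=comp)
        for i in range(1, len(peaks) + 1):
            piece = ws == i
            if i == 1:
                out[piece] = lab
            else:
                out[piece] = next_label
                next_label += 1
    return out


# ------------------------------------------------------------------ GMM classification


def fit_gmm_two_class(
    marker: np.ndarray,
    mask: np.ndarray | None = None,
    seed: int = 0,
    covariance_type: str = "tied",
    max_iter: int = 300,
    tol: float = 1e-6,
    max_fit_pixels: int = 200_000,
) -> GMMFit:
    """Fit a two-component Gaussian mixture to pixel intensities.

    The higher-mean component is the positive class and its posterior
    responsibility is returned as a probability raster (zero outside the
    mask). With the default tied covariance the posterior is a logistic
    function of intensity and therefore strictly monotone; ``"full"``
    allows per-component variances at the cost of guaranteed monotonicity.
    """
    marker = np.asarray(marker, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        vals = marker[mask]
    else:
        vals = marker.ravel()
    if vals.size < 2 or np.ptp(vals) == 0:
        raise ValueError("constant marker intensities: cannot fit mixture")
    rng = np.random.default_rng(seed)
    fit_vals = vals
    if vals.size > max_fit_pixels:
        fit_vals = rng.choice(vals, size=max_fit_pixels, replace=False)
    # initialize means from the background bulk and the bright tail: markers
    # with a rare positive class (e.g. vessels covering <1% of tissue) are
    # otherwise missed by centroid-based initialization, which prefers
    # splitting the background
    lo, hi = np.quantile(fit_vals, [0.25, 0.999])
    if hi <= lo:
        lo, hi = float(fit_vals.min()), float(fit_vals.max())
    gm = GaussianMixture(
        n_components=2,
        covariance_type=covariance_type,
        max_iter=max_iter,
        tol=tol,
        n_init=1,
        means_init=[[lo], [hi]],
        weights_init=[0.9, 0.1],
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    gm.fit(fit_vals.reshape(-1, 1))
    if not gm.converged_:
        raise RuntimeError(
            f"EM did not converge after {max_iter} iterations "
            f"(lower bound {gm.lower_bound_:.6g})"
        )
    means = gm.means_.ravel()
    order = np.argsort(means)
    if covariance_type == "tied":
        variances = np.array([gm.covariances_[0, 0]] * 2)
    else:
        variances = gm.covariances_.reshape(-1)[order]
    prob = np.zeros(marker.shape, dtype=float)
    target = marker[mask] if mask is not None else marker.ravel()
    resp = gm.predict_proba(target.reshape(-1, 1))[:, order[1]]
    if mask is not None:
        prob[mask] = resp
    else:
        prob = resp.reshape(marker.shape)
    return GMMFit(
        means=means[order],
        variances=variances,
        weights=gm.weights_[order],
        prob_map=prob,
        mask=mask,
        log_likelihood=[float(gm.lower_bound_)],
        converged=bool(gm.converged_),
        seed=seed,
        _source=marker,
    )


def call_marker_on_nuclei(
    fit: GMMFit,
    nuclei: Sequence[NucleusInstance],
    marker: str,
    prob_threshold: float = 0.5,
    overlap_threshold: float = 0.1,
) -> list[MarkerCall]:
    """Fuse a marker probability map with nucleus footprints.

    Per nucleus: ``p`` is the mean positive-class probability over footprint
    pixels; ``overlap_fraction`` is the fraction of footprint pixels whose
    probability reaches ``prob_threshold``. A call is positive only if both
    thresholds are met, which removes debris and artefacts touching a
    nucleus over a small area.
    """
    prob = fit.prob_map
    rows, cols = prob.shape
    out: list[MarkerCall] = []
    for nuc in nuclei:
        px = nuc.pixels
        if px[:, 0].min() < 0 or px[:, 1].min() < 0 or px[:, 0].max() >= rows or px[:, 1].max() >= cols:
            raise ValueError(f"nucleus {nuc.id} outside probability raster bounds")
        vals = prob[px[:, 0], px[:, 1]]
        p = float(vals.mean())
        overlap = float((vals >= prob_threshold).mean())
        out.append(
            MarkerCall(
                nucleus_id=nuc.id,
                marker=marker,
                p=p,
                overlap_fraction=overlap,
                positive=bool(p >= prob_threshold and overlap >= overlap_threshold),
            )
        )
    return out


def segment_structure_mask(fit: GMMFit, background_guard: float = 0.2) -> np.ndarray:
    """Binary mask of a contiguous structure (vessels, epithelium) from a
    marker probability map, independent of nuclei.

    The probability values are thresholded with Otsu's criterion; no
    largest-component filter is applied since structures such as vessels are
    legitimately multiple. If no probability reaches ``background_guard``
    the section holds no structure and an empty mask is returned with a
    warning.
    """
    prob = fit.prob_map
    vals = prob[fit.mask] if fit.mask is not None else prob.ravel()
    if np.ptp(vals) == 0:
        raise ValueError("constant probabilities: cannot threshold")
    if vals.max() < background_guard:
        warnings.warn("all probabilities below background guard; empty structure mask")
        return np.zeros(prob.shape, dtype=bool)
    thresh = threshold_otsu(vals, nbins=256)
    mask = prob > thresh
    if fit.mask is not None:
        mask &= fit.mask
    return mask


# ------------------------------------------------------------------ phenotyping


def phenotype_cells(
    nuclei: Sequence[NucleusInstance],
    calls: Sequence[MarkerCall],
) -> list[CellRecord2D]:
    """Assign one phenotype per nucleus from its marker calls.

    Precedence: CD31+ endothelial; else CD3+CD4+FOXP3+ T reg; else CD3+CD4+
    T helper; else CD3+CD8+ T killer; else CD68+ macrophage; else epithelial
    if a cytokeratin cocktail (AE1/CK26) is positive; else other. A
    CD4/CD8 double-positive T cell is resolved toward the marker with the
    larger mean probability and flagged ambiguous.
    """
    by_nucleus: dict[int, dict[str, MarkerCall]] = {}
    for call in calls:
        by_nucleus.setdefault(call.nucleus_id, {})[call.marker] = call
    out: list[CellRecord2D] = []
    for nuc in nuclei:
        ncalls = by_nucleus.get(nuc.id, {})
        missing = [m for m in REQUIRED_PHENOTYPE_MARKERS if m not in ncalls]
        if missing:
            raise ValueError(f"nucleus {nuc.id} missing marker calls: {missing}")
        pos = {m for m, c in ncalls.items() if c.positive}
        ambiguous = False
        if "CD31" in pos:
            phen = "endothelial"
        elif "CD3" in pos and "CD4" in pos and "CD8" in pos:
            ambiguous = True
            if ncalls["CD8"].p > ncalls["CD4"].p:
                phen = "Tkiller"
            else:
                phen = "Treg" if "FOXP3" in pos else "Thelper"
        elif "CD3" in pos and "CD4" in pos and "FOXP3" in pos:
            phen = "Treg"
        elif "CD3" in pos and "CD4" in pos:
            phen = "Thelper"
        elif "CD3" in pos and "CD8" in pos:
            phen = "Tkiller"
        elif "CD68" in pos:
            phen = "macrophage"
        elif pos & set(EPITHELIAL_MARKERS):
            phen = "epithelial"
        else:
            phen = "other"
        out.append(CellRecord2D(nucleus=nuc, calls=ncalls, phenotype=phen, ambiguous=ambiguous))
    return out
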