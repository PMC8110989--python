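"""Reference comparison segmenters: point-wise, multilevel Otsu, Derivatives-Sum.

These are the three conventional pipelines the wavelet method is benchmarked
against.  All three are deterministic given a volume and configuration, and
all emit the same result type as :func:`wavenuc.segmentation.segment` so that
evaluation is method-agnostic.

* **point-wise** — mean-smooth with a 9x9x3 kernel, suppress shallow extrema
  with an h-maxima transform, merge surviving local maxima closer than 6 px,
  report centres with the mean intensity over a 6x6x3 ellipsoidal
  neighbourhood.  A pure detector: it yields centres, not masks.
* **Otsu** — per slice: Gaussian low-pass, unsharp sharpening, adaptive
  Wiener denoising, then multilevel Otsu thresholding (brightest class =
  foreground); 3D 26-connected components become nuclei.
* **Derivatives-Sum (DS)** — per slice: Gaussian denoise, combine gradient
  magnitude, Laplacian and Hessian determinant (each min-max normalized)
  into a mask function F with user weights, Otsu-binarize F, then chain the
  2D masks across z into 3D nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage import feature, filters, measure, morphology

from .segmentation import Mask2D, Nucleus3D, SegmentationResult, expected_nucleus_volume

__all__ = [
    "DSWeights",
    "pointwise_segment",
    "otsu_segment",
    "ds_segment",
    "PointwiseResult",
]


@dataclass(frozen=True)
class DSWeights:
    """Weights combining the three derivative maps into the DS mask function."""

    w_grad: float = 1.0
    w_lap: float = 1.0
    w_hess: float = 1.0

    def __post_init__(self) -> None:
        if self.w_grad == self.w_lap == self.w_hess == 0:
            raise ValueError("at least one DS weight must be nonzero")


@dataclass
class PointwiseResult:
    """Detected centres and intensities of the point-wise method."""

    centroids: np.ndarray  # (n, 3), columns x, y, z
    intensities: np.ndarray

    label_volume = None  # the method yields points, not masks


def pointwise_segment(volume: np.ndarray, h_frac: float = 0.10) -> PointwiseResult:
    """Point-wise centre detection.

    ``h_frac`` sets the h-maxima suppression depth as a fraction of the
    smoothed volume's dynamic range (default 10%).
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3 or min(vol.shape) < 3 or vol.shape[1] < 9 or vol.shape[2] < 9:
        raise ValueError("volume must be 3D and at least 9x9 laterally, 3 axially")
    smooth = ndimage.uniform_filter(vol, size=(3, 9, 9))
    rng = float(smooth.max() - smooth.min())
    if rng <= 0:
        return PointwiseResult(np.empty((0, 3)), np.empty(0))
    h = h_frac * rng
    peaks = morphology.h_maxima(smooth, h)
    lab, n = ndimage.label(peaks)
    if n == 0:
        return PointwiseResult(np.empty((0, 3)), np.empty(0))
    czyx = np.array(ndimage.center_of_mass(peaks, lab, range(1, n + 1)))
    centers = czyx[:, ::-1]  # -> (x, y, z)

    # merge maxima closer than 6 px (greedy, brightest first; merged group
    # is replaced by its centroid)
    vals = np.array([smooth[int(round(z)), int(round(y)), int(round(x))]
                     for x, y, z in centers])
    order = np.argsort(-vals)
    merged: list[np.ndarray] = []
    groups: list[list[int]] = []
    for i in order:
        c = centers[i]
        for gi, g in enumerate(merged):
            if np.linalg.norm(c - g) < 6.0:
                groups[gi].append(i)
                pts = centers[groups[gi]]
                merged[gi] = pts.mean(axis=0)
                break
        else:
            merged.append(c.copy())
            groups.append([i])
    centers = np.array(merged)

    # intensity over a 6x6x3 ellipsoidal neighbourhood
    zz, yy, xx = np.mgrid[-1:2, -3:4, -3:4]
    ball = (xx / 3.0) ** 2 + (yy / 3.0) ** 2 + (zz / 1.0) ** 2 <= 1.0
    nzyx = np.argwhere(ball) - np.array([1, 3, 3])
    nz_, ny_, nx_ = vol.shape
    intensities = []
    for x, y, z in centers:
        pz, py, px = int(round(z)), int(round(y)), int(round(x))
        coords = nzyx + np.array([pz, py, px])
        good = (
            (coords[:, 0] >= 0) & (coords[:, 0] < nz_)
            & (coords[:, 1] >= 0) & (coords[:, 1] < ny_)
            & (coords[:, 2] >= 0) & (coords[:, 2] < nx_)
        )
        c = coords[good]
        intensities.append(float(vol[c[:, 0], c[:, 1], c[:, 2]].mean()))
    return PointwiseResult(centroids=centers, intensities=np.array(intensities))


def _min_volume(radius: float | None, min_size_frac: float) -> float:
    """Minimum object volume in voxels; same outlier rule as the wavelet path."""
    if radius is None:
        return 0.0
    return min_size_frac * expected_nucleus_volume(radius)


def _components_to_result(
    foreground: np.ndarray, params: dict, min_volume: float = 0.0
) -> SegmentationResult:
    """3D connected components (26-connectivity) as a SegmentationResult."""
    lab = measure.label(foreground, connectivity=3)
    nuclei = []
    label_out = np.zeros_like(lab, dtype=np.uint16 if lab.max() < 65536 else np.int32)
    next_id = 1
    for region in measure.regionprops(lab):
        if region.area < min_volume:
            continue
        zs = sorted({int(z) for z, _, _ in region.coords})
        masks = []
        for z in zs:
            pts = region.coords[region.coords[:, 0] == z]
            cy, cx = pts[:, 1].mean(), pts[:, 2].mean()
            masks.append(
                Mask2D(
                    z_index=int(z),
                    pixels=frozenset((int(x), int(y)) for _, y, x in pts),
                    center=(float(cx), float(cy)),
                    mean_scale=0.0,
                )
            )
        # components may skip slices; split into consecutive runs
        runs: list[list[Mask2D]] = [[masks[0]]]
        for m in masks[1:]:
            if m.z_index == runs[-1][-1].z_index + 1:
                runs[-1].append(m)
            else:
                runs.append([m])
        for run in runs:
            if sum(m.area for m in run) < min_volume:
                continue
            nuc = Nucleus3D(id=next_id, masks=run, center_intensity=0.0)
            for m in run:
                for x, y in m.pixels:
                    label_out[m.z_index, y, x] = next_id
            nuclei.append(nuc)
            next_id += 1
    return SegmentationResult(nuclei=nuclei, label_volume=label_out, params=params)


def otsu_segment(
    volume: np.ndarray,
    radius: float | None = None,
    min_size_frac: float = 0.20,
    classes: int = 3,
    gaussian_sigma: float = 2.0,
    sharpen_radius: float = 2.0,
    sharpen_amount: float = 1.0,
    wiener_window: int = 5,
) -> SegmentationResult:
    """Threshold-based baseline built on per-slice multilevel Otsu.

    Everything runs slice by slice: symmetric Gaussian low-pass, unsharp
    sharpening, pixel-wise adaptive Wiener filter, then multilevel Otsu
    thresholding of the slice (default 3 classes, i.e. two thresholds) with
    the brightest class as foreground.  Foreground voxels are grouped by 3D
    26-connected components.  When the expected nucleus ``radius`` is given,
    components below ``min_size_frac`` of the expected nucleus volume are
    discarded (the same outlier rule the wavelet pipeline applies), which
    removes threshold speckle.

    Per-slice thresholds are the method's stated design and also its known
    weakness: slices without nuclei threshold their own noise, so foreground
    speckle (and merging through it) grows quickly with noise level.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("volume must be 3D")
    if vol.max() == vol.min():
        raise ValueError("constant volume cannot be thresholded")
    fg = np.zeros(vol.shape, dtype=bool)
    for z in range(vol.shape[0]):
        sl = ndimage.gaussian_filter(vol[z], gaussian_sigma)
        sl = filters.unsharp_mask(
            sl, radius=sharpen_radius, amount=sharpen_amount, preserve_range=True
        )
        if sl.std() > 0:
            with np.errstate(invalid="ignore", divide="ignore"):
                w = signal.wiener(sl, mysize=wiener_window)
            # locally flat neighbourhoods divide by zero variance
            sl = np.where(np.isfinite(w), w, sl)
        if np.ptp(sl) == 0:
            continue  # featureless slice: all background
        try:
            th = filters.threshold_multiotsu(sl, classes=classes)
        except ValueError:  # too few distinct values for the class count
            continue
        fg[z] = sl > th[-1]
    params = {
        "method": "otsu",
        "classes": classes,
        "gaussian_sigma": gaussian_sigma,
        "sharpen_radius": sharpen_radius,
        "sharpen_amount": sharpen_amount,
        "wiener_window": wiener_window,
        "radius": radius,
        "min_size_frac": min_size_frac,
    }
    return _components_to_result(fg, params, _min_volume(radius, min_size_frac))


def _ds_mask_function(sl: np.ndarray, weights: DSWeights, sigma: float) -> np.ndarray:
    den = ndimage.gaussian_filter(sl, sigma)
    gx = ndimage.sobel(den, axis=1)
    gy = ndimage.sobel(den, axis=0)
    grad = np.hypot(gx, gy)
    # negated Laplacian: bright blob interiors have a negative Laplacian, and
    # the mask function must reward them
    lap = -ndimage.laplace(den)
    hrr, hrc, hcc = feature.hessian_matrix(
        den, sigma=1.0, order="rc", use_gaussian_derivatives=False
    )
    hess = hrr * hcc - hrc**2

    def norm(a: np.ndarray) -> np.ndarray:
        rng = np.ptp(a)
        return (a - a.min()) / rng if rng > 0 else np.zeros_like(a)

    return weights.w_grad * norm(grad) + weights.w_lap * norm(lap) + weights.w_hess * norm(hess)


def ds_segment(
    volume: np.ndarray,
    weights: DSWeights | None = None,
    radius: float | None = None,
    min_size_frac: float = 0.20,
    gaussian_sigma: float = 2.0,
    chain_overlap: float = 0.5,
) -> SegmentationResult:
    """Derivatives-Sum baseline.

    Per slice, a mask function F combines the (min-max normalized) gradient
    magnitude, Laplacian and Hessian determinant of the denoised image with
    the given weights; F is Otsu-binarized, and the per-slice masks are
    chained across z (adjacent masks join when their intersection exceeds
    ``chain_overlap`` of the smaller area).  As in :func:`otsu_segment`,
    passing the expected ``radius`` removes objects below ``min_size_frac``
    of the expected nucleus volume.
    """
    w = weights or DSWeights()
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("volume must be 3D")
    fg = np.zeros(vol.shape, dtype=bool)
    for z in range(vol.shape[0]):
        F = _ds_mask_function(vol[z], w, gaussian_sigma)
        if np.ptp(F) == 0:
            continue
        fg[z] = F > filters.threshold_otsu(F)

    # chain 2D components across z by mask overlap
    slice_labels = [measure.label(fg[z], connectivity=1) for z in range(vol.shape[0])]
    masks_by_slice: list[list[Mask2D]] = []
    for z, lab in enumerate(slice_labels):
        masks = []
        for region in measure.regionprops(lab):
            ys, xs = region.coords[:, 0], region.coords[:, 1]
            masks.append(
                Mask2D(
                    z_index=z,
                    pixels=frozenset(zip(xs.tolist(), ys.tolist())),
                    center=(float(xs.mean()), float(ys.mean())),
                    mean_scale=0.0,
                )
            )
        masks_by_slice.append(masks)

    chains: list[list[Mask2D]] = []
    open_idx: list[int] = []
    for z, masks in enumerate(masks_by_slice):
        still_open = []
        used = set()
        for ci in open_idx:
            prev = chains[ci][-1]
            best, best_i = 0, None
            for mi, m in enumerate(masks):
                if mi in used:
                    continue
                inter = len(prev.pixels & m.pixels)
                if inter > chain_overlap * min(prev.area, m.area) and inter > best:
                    best, best_i = inter, mi
            if best_i is not None:
                chains[ci].append(masks[best_i])
                used.add(best_i)
                still_open.append(ci)
        for mi, m in enumerate(masks):
            if mi not in used:
                chains.append([m])
                still_open.append(len(chains) - 1)
        open_idx = still_open

    min_vol = _min_volume(radius, min_size_frac)
    nuclei = []
    label_out = np.zeros(vol.shape, dtype=np.uint16 if len(chains) < 65536 else np.int32)
    next_id = 1
    for chain in chains:
        if sum(m.area for m in chain) < min_vol:
            continue
        nuc = Nucleus3D(id=next_id, masks=chain, center_intensity=0.0)
        for m in chain:
            for x, y in m.pixels:
                label_out[m.z_index, y, x] = next_id
        nuclei.append(nuc)
        next_id += 1
    params = {
        "method": "ds",
        "weights": [w.w_grad, w.w_lap, w.w_hess],
        "gaussian_sigma": gaussian_sigma,
        "chain_overlap": chain_overlap,
        "radius": radius,
        "min_size_frac": min_size_frac,
    }
    return SegmentationResult(nuclei=nuclei, label_volume=label_out, params=params)
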