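"""2D continuous wavelet transform with the Mexican-hat mother wavelet.

The transform correlates each z-slice of a fluorescence stack with dilated
copies of a radially symmetric Mexican-hat kernel.  A bright, roughly
Gaussian nucleus produces a single strong positive response extremum at
scales comparable to its radius, surrounded by a closed zero-level contour
that tracks the object's footprint; that geometry is what the segmentation
stage consumes.

Conventions
-----------
* The coefficient at translation ``(a, b)`` and scale ``s`` is

      K(s, a, b) = s^{-1/2} * sum_{x,y} f(x, y) * psi((x-a)/s, (y-b)/s)

  evaluated on the discrete pixel grid, i.e. a plain correlation of the
  slice with the dilated kernel times ``1/sqrt(s)``.
* ``psi`` is the closed-form Mexican hat of :func:`mexican_hat_2d`.  The
  sampled, truncated kernel is shifted to exact zero sum (see
  :class:`MexicanHatKernel`), so constant image regions are annihilated.
* Image boundaries are handled by symmetric reflection, which avoids the
  spurious edge extrema that zero padding would create.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
import math

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "MOTHER_SIGMA",
    "mexican_hat_2d",
    "MexicanHatKernel",
    "WaveletScaleSet",
    "CoefficientMap",
    "cwt2d",
    "cwt_volume",
]

#: Width (sigma, in pixels) of the mother wavelet at scale 1.  Dilation by a
#: scale factor ``s`` gives an effective kernel width of ``s * MOTHER_SIGMA``
#: pixels.  The value is chosen small relative to the scale so that the
#: zero-level contour of the response to a blob-like object is dominated by
#: the object's own extent rather than by the kernel footprint; that is the
#: property the multi-scale area-similarity test of the segmentation stage
#: relies on to separate real objects from kernel-sized noise structure.
MOTHER_SIGMA: float = 0.35


def mexican_hat_2d(dx: float, dy: float, sigma: float) -> float:
    """Evaluate the 2D Mexican-hat wavelet at offset ``(dx, dy)``.

    .. math::

        \\psi(x, y) = \\frac{1}{\\pi\\sigma^2}
            \\left(1 - \\frac{x^2 + y^2}{2\\sigma^2}\\right)
            e^{-(x^2 + y^2)/\\sigma^2}

    The function is maximal (``1/(pi*sigma^2)``) at the origin, crosses zero
    on the circle ``dx**2 + dy**2 == 2*sigma**2`` and is negative outside it.
    Accepts scalars or numpy arrays for ``dx``/``dy``.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    r2 = (np.asarray(dx, dtype=float) ** 2 + np.asarray(dy, dtype=float) ** 2) / sigma**2
    out = (1.0 / (math.pi * sigma**2)) * (1.0 - 0.5 * r2) * np.exp(-r2)
    if np.isscalar(dx) and np.isscalar(dy):
        return float(out)
    return out


@dataclass(frozen=True)
class MexicanHatKernel:
    """Sampled, truncated 2D Mexican-hat kernel.

    Parameters
    ----------
    sigma:
        Kernel width in pixels (the sigma of :func:`mexican_hat_2d`).
    support_radius:
        Truncation radius in pixels; the sampled grid is
        ``(2*support_radius+1)`` squared.  Must be at least ``3*sigma`` so
        the truncated tail is negligible.

    The analytic wavelet integrates to ``1/2`` rather than zero, so the raw
    samples are shifted by their mean.  This restores the zero-mean
    admissibility condition a wavelet needs (a DC offset in the image must
    not leak into the coefficients) and simultaneously absorbs the small
    truncation residue.
    """

    sigma: float
    support_radius: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.support_radius < 3 * self.sigma:
            raise ValueError(
                f"support_radius {self.support_radius} below 3*sigma={3 * self.sigma:.2f}"
            )

    @classmethod
    def for_scale(cls, scale: float, mother_sigma: float = MOTHER_SIGMA) -> "MexicanHatKernel":
        """Kernel of the mother wavelet dilated by ``scale``."""
        sigma = scale * mother_sigma
        radius = max(int(math.ceil(4.0 * sigma)), 2)
        return cls(sigma=sigma, support_radius=radius)

    @property
    def values(self) -> np.ndarray:
        """Zero-sum sampled kernel, shape ``(2R+1, 2R+1)``."""
        return _sampled_kernel(self.sigma, self.support_radius)


@lru_cache(maxsize=64)
def _sampled_kernel(sigma: float, support_radius: int) -> np.ndarray:
    r = support_radius
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    k = mexican_hat_2d(xx, yy, sigma)
    k = k - k.mean()
    k.flags.writeable = False
    return k


def _dilated_kernel(scale: float, mother_sigma: float = MOTHER_SIGMA) -> np.ndarray:
    """Literal samples of ``psi(x/s, y/s)`` (zero-sum corrected).

    Identical in shape to ``MexicanHatKernel.for_scale(scale).values`` but
    carries the ``s**2`` amplitude of the dilation, so that correlating with
    it implements the coefficient definition verbatim.
    """
    kern = MexicanHatKernel.for_scale(scale, mother_sigma)
    return kern.values * float(scale) ** 2


@dataclass(frozen=True)
class WaveletScaleSet:
    """Ordered set of wavelet scale factors, typically bracketing the radius.

    The default construction for an expected nucleus radius ``r`` uses the
    three scales ``{r-1, r, r+1}`` (clipped below at 2) so that genuine
    nuclei respond consistently across the whole set while kernel-sized
    noise structure does not.
    """

    scales: tuple[float, ...]
    derived_from_radius: float | None = None

    def __post_init__(self) -> None:
        s = self.scales
        if len(s) < 2:
            raise ValueError("need at least 2 scales")
        if any(a <= 0 for a in s):
            raise ValueError("scales must be positive")
        if any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("scales must be strictly increasing")

    @classmethod
    def from_radius(cls, radius: float) -> "WaveletScaleSet":
        if radius < 2:
            raise ValueError(f"nucleus radius must be >= 2 px, got {radius}")
        scales = tuple(sorted({max(radius - 1, 2.0), float(radius), radius + 1.0}))
        return cls(scales=scales, derived_from_radius=float(radius))

    def __iter__(self):
        return iter(self.scales)

    def __len__(self) -> int:
        return len(self.scales)


@dataclass
class CoefficientMap:
    """Wavelet coefficient matrix of one slice at one scale."""

    values: np.ndarray
    scale: float
    z_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("coefficient map must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("coefficient map contains non-finite values")


# Use the FFT route once the direct-correlation cost (pixels x kernel taps)
# crosses this many multiply-adds; both routes agree to float precision.
_FFT_COST_THRESHOLD = 1 << 21


def cwt2d(
    slice_: np.ndarray,
    scale: float,
    padding: str = "reflect",
    z_index: int = 0,
    mother_sigma: float = MOTHER_SIGMA,
) -> CoefficientMap:
    """2D CWT of a single slice at one scale factor.

    Returns a :class:`CoefficientMap` of the same height/width as the input.
    ``padding`` currently supports ``"reflect"`` (symmetric) only, declared
    explicitly because the boundary convention is part of the contract.
    """
    f = np.asarray(slice_, dtype=float)
    if f.ndim != 2 or f.size == 0:
        raise ValueError("slice must be a non-empty 2D array")
    if scale < 1:
        raise ValueError(f"scale must be >= 1, got {scale}")
    if padding != "reflect":
        raise ValueError(f"unsupported padding mode {padding!r}")

    kernel = _dilated_kernel(scale, mother_sigma)
    norm = 1.0 / math.sqrt(scale)
    if f.size * kernel.size <= _FFT_COST_THRESHOLD:
        vals = ndimage.correlate(f, kernel, mode="reflect") * norm
    else:
        r = kernel.shape[0] // 2
        padded = np.pad(f, r, mode="symmetric")
        # correlation == convolution with the (symmetric) kernel; 'valid'
        # on the padded slice restores the original shape
        vals = signal.fftconvolve(padded, kernel[::-1, ::-1], mode="valid") * norm
    return CoefficientMap(values=vals, scale=float(scale), z_index=z_index)


def cwt_volume(
    volume: np.ndarray,
    scales: WaveletScaleSet,
    mother_sigma: float = MOTHER_SIGMA,
) -> list[list[CoefficientMap]]:
    """Per-slice, per-scale coefficient maps of a z-stack.

    ``volume`` is indexed ``[z, y, x]``.  Slices are transformed
    independently: axial resolution generally differs from lateral
    resolution, so a single 3D scale factor would be ill-defined.

    Returns a list over slices, each a list over scales (in the order of
    ``scales``).
    """
    v = np.asarray(volume, dtype=float)
    if v.ndim != 3 or v.shape[0] < 1:
        raise ValueError("volume must be a 3D array with at least one slice")
    return [
        [cwt2d(v[z], s, z_index=z, mother_sigma=mother_sigma) for s in scales]
        for z in range(v.shape[0])
    ]
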