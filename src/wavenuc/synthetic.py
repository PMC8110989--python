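"""Synthetic 3D nuclei volumes with ground truth.

Emulates confocal z-stacks of fluorescently labelled nuclei: each nucleus is
an isotropic 3D Gaussian blob (peak at the nucleus centre, standard
deviation ``0.4 * radius``), blobs superpose additively, and the stack is
degraded by a base level of white Gaussian noise plus one user-selected
regime — extra Gaussian noise, salt-and-pepper impulses, or a lateral
intensity-attenuation ramp.  Placement enforces a minimum centre spacing of
``1.5 * radius`` (to the boundary as well); a forced-overlap mode instead
*requires* the second half of the nuclei to land closer than that, to probe
a segmenter's ability to divide touching objects.

What this does not emulate: optics (no PSF, nuclei are soft Gaussian blobs,
not textured chromatin), photon statistics (no Poisson noise), and axial
anisotropy (voxels are generated isotropic).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np

__all__ = [
    "NoiseSpec",
    "SyntheticSpec",
    "GroundTruth",
    "place_nuclei",
    "place_overlapping",
    "render",
    "add_noise",
    "generate_dataset",
]

_NOISE_KINDS = ("none", "gaussian", "salt_pepper", "attenuation")
_MAX_ATTEMPTS = 10_000


@dataclass(frozen=True)
class NoiseSpec:
    """Noise regime applied on top of the rendered blobs.

    ``nd`` is the regime's noise density/level: variance of the extra
    Gaussian component, corrupted-voxel fraction for salt-and-pepper, or the
    left-edge intensity multiplier for the attenuation ramp.
    ``base_white_variance`` is the variance of the always-present white
    Gaussian noise; ``None`` defers to 1% of the squared nominal intensity
    at generation time.
    """

    kind: str = "none"
    nd: float = 0.0
    base_white_variance: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; expected one of {_NOISE_KINDS}")
        if self.nd < 0:
            raise ValueError("nd must be non-negative")
        if self.kind == "salt_pepper" and not 0 <= self.nd <= 1:
            raise ValueError("salt-and-pepper nd must lie in [0, 1]")
        if self.base_white_variance is not None and self.base_white_variance < 0:
            raise ValueError("base_white_variance must be non-negative")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``dims`` is ``(Nx, Ny, Nz)`` in voxels.  ``radius_randomness`` /
    ``intensity_randomness`` are the rho in ``r_i = r +/- U(0,1)*rho*r``
    (sign equiprobable per nucleus).
    """

    dims: tuple[int, int, int] = (128, 128, 40)
    n_nuclei: int = 20
    radius: float = 9.0
    intensity: float = 1000.0
    radius_randomness: float = 0.2
    intensity_randomness: float = 0.2
    min_spacing_factor: float = 1.5
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    overlap_mode: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.radius_randomness <= 1 and 0 <= self.intensity_randomness <= 1):
            raise ValueError("randomness factors must lie in [0, 1]")
        if self.radius < 2:
            raise ValueError("radius must be >= 2 px")
        if self.n_nuclei < 1:
            raise ValueError("need at least one nucleus")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must be positive")
        margin = self.min_spacing_factor * self.radius
        if any(d <= 2 * margin for d in self.dims):
            raise ValueError(
                f"dims {self.dims} cannot host nuclei at boundary margin {margin:.1f} px"
            )


@dataclass
class GroundTruth:
    """True centres/radii/intensities emitted alongside a synthetic volume.

    Centres are ``(x, y, z)`` in 0-based voxel coordinates.
    """

    centers: np.ndarray  # (n, 3) float, columns x, y, z
    radii: np.ndarray  # (n,)
    intensities: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.asarray(self.radii, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        n = len(self.centers)
        if n < 1 or self.centers.shape[1] != 3:
            raise ValueError("centers must be a non-empty (n, 3) array")
        if len(self.radii) != n or len(self.intensities) != n:
            raise ValueError("centers/radii/intensities length mismatch")

    def __len__(self) -> int:
        return len(self.centers)

    def label_volume(self, dims: tuple[int, int, int]) -> np.ndarray:
        """True mask volume: voxels within the realized radius of a centre.

        Where spheres overlap the nearest centre wins.  Returned grid is
        indexed ``[z, y, x]`` with labels ``1..n`` (0 = background).
        """
        nx, ny, nz = dims
        labels = np.zeros((nz, ny, nx), dtype=np.uint16)
        dist = np.full((nz, ny, nx), np.inf)
        for i, ((cx, cy, cz), r) in enumerate(zip(self.centers, self.radii), start=1):
            zlo, zhi = max(0, int(cz - r)), min(nz, int(cz + r) + 2)
            ylo, yhi = max(0, int(cy - r)), min(ny, int(cy + r) + 2)
            xlo, xhi = max(0, int(cx - r)), min(nx, int(cx + r) + 2)
            zz, yy, xx = np.mgrid[zlo:zhi, ylo:yhi, xlo:xhi]
            d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2)
            box = (slice(zlo, zhi), slice(ylo, yhi), slice(xlo, xhi))
            closer = (d <= r) & (d < dist[box])
            labels[box][closer] = i
            dist[box][closer] = d[closer]
        return labels


def _perturbed(nominal: float, rho: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Realize ``nominal +/- U(0,1) * rho * nominal`` with equiprobable sign."""
    sign = rng.choice([-1.0, 1.0], size=n)
    return nominal * (1.0 + sign * rng.uniform(0.0, 1.0, size=n) * rho)


def place_nuclei(spec: SyntheticSpec, rng: np.random.Generator) -> GroundTruth:
    """Rejection-sample nucleus centres with minimum spacing.

    Every pairwise centre distance and every distance to the volume boundary
    is at least ``min_spacing_factor * radius`` (nominal radius).  Raises if
    a nucleus cannot be placed within 10,000 attempts.
    """
    nx, ny, nz = spec.dims
    margin = spec.min_spacing_factor * spec.radius
    lo = np.array([margin, margin, margin])
    hi = np.array([nx - 1 - margin, ny - 1 - margin, nz - 1 - margin])
    centers: list[np.ndarray] = []
    for i in range(spec.n_nuclei):
        for _ in range(_MAX_ATTEMPTS):
            c = rng.uniform(lo, hi)
            if not centers:
                break
            if np.min(np.linalg.norm(np.array(centers) - c, axis=1)) >= margin:
                break
        else:
            raise RuntimeError(
                f"could not place nucleus {i + 1}/{spec.n_nuclei}: minimum spacing "
                f"{margin:.1f} px infeasible in dims {spec.dims}"
            )
        centers.append(c)
    return GroundTruth(
        centers=np.array(centers),
        radii=_perturbed(spec.radius, spec.radius_randomness, spec.n_nuclei, rng),
        intensities=_perturbed(spec.intensity, spec.intensity_randomness, spec.n_nuclei, rng),
    )


def place_overlapping(spec: SyntheticSpec, rng: np.random.Generator) -> GroundTruth:
    """Forced-overlap placement.

    The first ``ceil(n/2)`` nuclei follow :func:`place_nuclei`; each of the
    remaining nuclei is accepted only when its distance to the nearest
    already-placed nucleus is *smaller* than ``min_spacing_factor * radius``,
    guaranteeing touching/overlapping pairs.
    """
    if spec.n_nuclei < 2:
        raise ValueError("overlap mode needs at least 2 nuclei")
    n_first = math.ceil(spec.n_nuclei / 2)
    base = place_nuclei(replace(spec, n_nuclei=n_first), rng)
    nx, ny, nz = spec.dims
    margin = spec.min_spacing_factor * spec.radius
    lo = np.array([margin, margin, margin])
    hi = np.array([nx - 1 - margin, ny - 1 - margin, nz - 1 - margin])
    centers = list(base.centers)
    for i in range(spec.n_nuclei - n_first):
        for _ in range(_MAX_ATTEMPTS):
            c = rng.uniform(lo, hi)
            d = np.min(np.linalg.norm(np.array(centers) - c, axis=1))
            # forced overlap, but not degenerate coincidence
            if 1.0 <= d < margin:
                break
        else:
            raise RuntimeError(f"could not place overlapping nucleus {n_first + i + 1}")
        centers.append(c)
    n_extra = spec.n_nuclei - n_first
    return GroundTruth(
        centers=np.array(centers),
        radii=np.concatenate(
            [base.radii, _perturbed(spec.radius, spec.radius_randomness, n_extra, rng)]
        ),
        intensities=np.concatenate(
            [base.intensities, _perturbed(spec.intensity, spec.intensity_randomness, n_extra, rng)]
        ),
    )


def render(truth: GroundTruth, spec: SyntheticSpec) -> np.ndarray:
    """Render ground truth as additive 3D Gaussian blobs.

    Each nucleus contributes ``I_i * exp(-||v - c_i||^2 / (2 (0.4 r_i)^2))``;
    overlapping blobs superpose.  Background is 0 before noise.  Returns a
    float volume indexed ``[z, y, x]``.
    """
    nx, ny, nz = spec.dims
    vol = np.zeros((nz, ny, nx), dtype=float)
    for (cx, cy, cz), r, inten in zip(truth.centers, truth.radii, truth.intensities):
        if not (0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz):
            raise ValueError(f"centre ({cx}, {cy}, {cz}) outside dims {spec.dims}")
        sigma = 0.4 * r
        ext = int(math.ceil(4.5 * sigma))
        zlo, zhi = max(0, int(cz) - ext), min(nz, int(cz) + ext + 1)
        ylo, yhi = max(0, int(cy) - ext), min(ny, int(cy) + ext + 1)
        xlo, xhi = max(0, int(cx) - ext), min(nx, int(cx) + ext + 1)
        zz = np.arange(zlo, zhi, dtype=float)[:, None, None]
        yy = np.arange(ylo, yhi, dtype=float)[None, :, None]
        xx = np.arange(xlo, xhi, dtype=float)[None, None, :]
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
        vol[zlo:zhi, ylo:yhi, xlo:xhi] += inten * np.exp(-d2 / (2.0 * sigma**2))
    return vol


def add_noise(
    volume: np.ndarray,
    noise: NoiseSpec,
    rng: np.random.Generator,
    nominal_intensity: float | None = None,
) -> np.ndarray:
    """Apply base white noise plus the selected regime, clipped to range.

    White Gaussian noise of ``base_white_variance`` is always added (default:
    1% of the squared nominal intensity, taken from ``nominal_intensity`` or
    the volume maximum).  Then:

    * ``gaussian`` — extra zero-mean Gaussian noise of variance ``nd``;
    * ``salt_pepper`` — a fraction ``nd`` of voxels forced to the volume
      maximum (salt) or 0 (pepper), equiprobably;
    * ``attenuation`` — each voxel multiplied by a linear lateral ramp equal
      to ``nd`` at ``x = 0`` and 1 at ``x = Nx - 1``.

    Output is clipped to the dtype range (floats: non-negative).
    """
    vol = np.asarray(volume)
    dtype = vol.dtype
    out = vol.astype(float, copy=True)
    peak = float(out.max()) if out.size else 0.0
    nominal = float(nominal_intensity) if nominal_intensity is not None else peak

    base_var = noise.base_white_variance
    if base_var is None:
        base_var = 0.01 * nominal**2
    if base_var > 0:
        out += rng.normal(0.0, math.sqrt(base_var), size=out.shape)

    if noise.kind == "gaussian" and noise.nd > 0:
        out += rng.normal(0.0, math.sqrt(noise.nd), size=out.shape)
    elif noise.kind == "salt_pepper" and noise.nd > 0:
        n_bad = round(noise.nd * out.size)
        flat = rng.choice(out.size, size=n_bad, replace=False)
        salt = rng.random(n_bad) < 0.5
        hi = float(np.iinfo(dtype).max) if np.issubdtype(dtype, np.integer) else peak
        out.flat[flat[salt]] = hi
        out.flat[flat[~salt]] = 0.0
    elif noise.kind == "attenuation" and noise.nd > 0:
        nx_ = out.shape[2]
        x = np.arange(nx_, dtype=float)
        ramp = noise.nd + (1.0 - noise.nd) * (x / max(nx_ - 1, 1))
        out *= ramp[None, None, :]

    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return np.clip(np.rint(out), info.min if info.min > 0 else 0, info.max).astype(dtype)
    return np.clip(out, 0.0, None)


def generate_dataset(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    """Place, render and degrade one synthetic volume, reproducibly.

    All randomness derives from ``spec.seed``; the same spec yields a
    bit-identical volume.  Returns ``(volume[z, y, x], truth)``.
    """
    rng = np.random.default_rng(spec.seed)
    truth = place_overlapping(spec, rng) if spec.overlap_mode else place_nuclei(spec, rng)
    vol = render(truth, spec)
    vol = add_noise(vol, spec.noise, rng, nominal_intensity=spec.intensity)
    return vol, truth
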