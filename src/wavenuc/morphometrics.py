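"""3D topology features and cell-cycle shape classification for nuclei.

Features per nucleus (pixel units throughout):

* ``size`` — voxel count of the segmented nucleus.
* ``density3d`` / ``density2d`` — number of other nuclei with centre closer
  than 30 px (2D variant restricted to the same depth level, which corrects
  the systematic underestimation near the embryo's outermost and innermost
  layers).
* ``neighbor3d`` / ``neighbor2d`` — mean distance to the two closest other
  nuclei (again, the 2D variant stays within the depth level); an outlier
  detector.
* ``depth_level`` — integer layer index from the embryo surface inward:
  nuclei are grouped into radial columns about the embryo centroid and
  binned along the radius by the nominal nucleus diameter, outermost = 1.
* ``thickness`` — perpendicular distance from the locally fitted innermost
  layer: the innermost shell is divided into 360 azimuthal sub-regions, a
  plane is least-squares fitted to each sub-region's nuclei, and every
  nucleus measures its distance to its sub-region's plane.
* ``h_sorting`` — bins of 500 nuclei from the embryo top downward.
* ``evl_outer`` / ``evl_inner`` — flags for the enveloping-layer candidates:
  depth level 1 (outermost) resp. the maximum level (innermost).

Shape classification uses the circularity ("sphericity") 4*pi*area /
perimeter^2 and the min/max extent ratio ("aspect") of the three central
cross-sections (xy, yz, xz): mean sphericity > 0.9 -> spherical; otherwise
mean aspect > 0.7 -> irregular; otherwise elliptical, or dividing when the
nucleus is smaller than the embryo mean radius and forms a mutual
nearest-neighbour pair with another such nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import measure

__all__ = [
    "FeatureTable",
    "ShapeRecord",
    "density_features",
    "neighbor_features",
    "thickness_and_depth",
    "h_sorting",
    "evl_flags",
    "shape_metrics",
    "classify_shape",
    "pair_detection",
    "feature_table",
    "shape_table",
]

DENSITY_RADIUS = 30.0  # px
H_SORTING_BIN = 500  # nuclei per height bin
SPHERICITY_THRESH = 0.90
ASPECT_THRESH = 0.70
N_AZIMUTH_REGIONS = 360


@dataclass
class ShapeRecord:
    """Cross-section shape metrics of one nucleus (None = degenerate plane)."""

    sphericity_xy: float | None
    sphericity_yz: float | None
    sphericity_xz: float | None
    aspect_xy: float | None
    aspect_yz: float | None
    aspect_xz: float | None

    @property
    def mean_sphericity(self) -> float | None:
        vals = [v for v in (self.sphericity_xy, self.sphericity_yz, self.sphericity_xz)
                if v is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def mean_aspect(self) -> float | None:
        vals = [v for v in (self.aspect_xy, self.aspect_yz, self.aspect_xz)
                if v is not None]
        return float(np.mean(vals)) if vals else None


# alias used in table headers
FeatureTable = pd.DataFrame


def _as_centroids(centroids) -> np.ndarray:
    c = np.atleast_2d(np.asarray(centroids, dtype=float))
    if c.shape[1] != 3:
        raise ValueError("centroids must be an (n, 3) array of (x, y, z)")
    return c


def density_features(
    centroids,
    depth_levels=None,
    radius_px: float = DENSITY_RADIUS,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of other nuclei within ``radius_px`` (3D, and same-layer 2D)."""
    c = _as_centroids(centroids)
    n = len(c)
    levels = np.asarray(depth_levels) if depth_levels is not None else np.ones(n, int)
    if len(levels) != n:
        raise ValueError("depth_levels length mismatch")
    tree = cKDTree(c)
    pairs = tree.query_pairs(radius_px, output_type="ndarray")
    d3 = np.zeros(n, dtype=int)
    d2 = np.zeros(n, dtype=int)
    for i, j in pairs:
        # query_pairs uses strict "< radius" semantics via <=? enforce strict
        if np.linalg.norm(c[i] - c[j]) >= radius_px:
            continue
        d3[i] += 1
        d3[j] += 1
        if levels[i] == levels[j]:
            d2[i] += 1
            d2[j] += 1
    return d3, d2


def neighbor_features(
    centroids, depth_levels=None
) -> tuple[np.ndarray, np.ndarray]:
    """Mean distance to the two closest other nuclei (3D and in-layer 2D).

    Entries are NaN where fewer than two other nuclei exist (globally or in
    the layer).
    """
    c = _as_centroids(centroids)
    n = len(c)
    levels = np.asarray(depth_levels) if depth_levels is not None else np.ones(n, int)

    def mean2(pts: np.ndarray, idx: np.ndarray) -> np.ndarray:
        out = np.full(len(idx), np.nan)
        if len(pts) >= 3:
            tree = cKDTree(pts)
            d, _ = tree.query(pts, k=3)
            out = d[:, 1:3].mean(axis=1)
        return out

    n3 = mean2(c, np.arange(n)) if n >= 3 else np.full(n, np.nan)
    n2 = np.full(n, np.nan)
    for lev in np.unique(levels):
        sel = np.nonzero(levels == lev)[0]
        if len(sel) >= 3:
            tree = cKDTree(c[sel])
            d, _ = tree.query(c[sel], k=3)
            n2[sel] = d[:, 1:3].mean(axis=1)
    return n3, n2


def _embryo_center(points: np.ndarray) -> np.ndarray:
    """Embryo centre by algebraic least-squares sphere fit.

    Nuclei of a (hemi)spherical embryo lie on concentric shells, so the
    common centre is recovered far more accurately by fitting
    ``|x - a|^2 = R^2`` (linear in ``2a`` and ``R^2 - |a|^2``) than by the
    raw centroid, which is biased whenever sampling over the shell is
    uneven.  Falls back to the centroid for degenerate configurations.
    """
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = (points**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4 or not np.all(np.isfinite(sol)):
        return points.mean(axis=0)
    return sol[:3]


def thickness_and_depth(
    centroids,
    nominal_diameter: float,
    n_regions: int = N_AZIMUTH_REGIONS,
) -> tuple[np.ndarray, np.ndarray]:
    """Depth level (outermost = 1) and thickness from the innermost layer.

    Nuclei are referred to the embryo centroid.  Depth level bins the radial
    distance within azimuthal columns by ``nominal_diameter`` from the
    outermost nucleus of each column inward.  Thickness is the perpendicular
    distance to a local least-squares plane fitted to the innermost-layer
    nuclei of each of ``n_regions`` azimuthal sub-regions (sub-regions with
    fewer than 3 nuclei borrow from their neighbours).
    """
    c = _as_centroids(centroids)
    n = len(c)
    if n < 10:
        raise ValueError("need at least 10 nuclei to identify embryo layers")
    if nominal_diameter <= 0:
        raise ValueError("nominal_diameter must be positive")
    center = _embryo_center(c)
    rel = c - center
    rho = np.linalg.norm(rel, axis=1)
    phi = np.arctan2(rel[:, 1], rel[:, 0])  # azimuth in the xy plane

    # radial columns: azimuthal bins (coarser than the thickness sub-regions
    # so each column holds a few nuclei)
    n_cols = max(4, min(36, n // 8))
    col = np.minimum(((phi + math.pi) / (2 * math.pi) * n_cols).astype(int), n_cols - 1)
    depth = np.zeros(n, dtype=int)
    for k in np.unique(col):
        sel = col == k
        rho_max = rho[sel].max()
        depth[sel] = 1 + np.floor((rho_max - rho[sel]) / nominal_diameter).astype(int)

    inner_level = depth.max()
    inner = depth == inner_level
    inner_pts = c[inner]
    inner_dirs = rel[inner] / np.maximum(rho[inner, None], 1e-12)
    dirs = rel / np.maximum(rho[:, None], 1e-12)

    # 360 sub-regions of the solid angle about the embryo centre: equal-area
    # polar bands (via cos theta) crossed with azimuthal sectors
    n_bands = max(1, int(round(math.sqrt(n_regions / 4))))
    n_phi = max(1, n_regions // n_bands)
    cos_t = np.clip(rel[:, 2] / np.maximum(rho, 1e-12), -1.0, 1.0)
    band = np.minimum(((cos_t + 1.0) / 2.0 * n_bands).astype(int), n_bands - 1)
    sector = np.minimum(((phi + math.pi) / (2 * math.pi) * n_phi).astype(int), n_phi - 1)
    region = band * n_phi + sector

    def fit_plane(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        q = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(q, full_matrices=False)
        return pts.mean(axis=0), vt[-1]

    thickness = np.zeros(n)
    for k in np.unique(region):
        sel_k = region == k
        pts = inner_pts[region[inner] == k]
        if len(pts) < 3:
            # borrow the innermost-layer nuclei closest in direction
            centre_dir = dirs[sel_k].mean(axis=0)
            centre_dir /= max(np.linalg.norm(centre_dir), 1e-12)
            order = np.argsort(-(inner_dirs @ centre_dir))
            pts = inner_pts[order[: max(5, 3)]]
        if len(pts) >= 3:
            point, normal = fit_plane(pts)
            thickness[sel_k] = np.abs((c[sel_k] - point) @ normal)
    return thickness, depth


def h_sorting(centroids, bin_size: int = H_SORTING_BIN) -> np.ndarray:
    """Height-sorting bin per nucleus: every ``bin_size`` nuclei from the top.

    "Top" is the maximum of the height axis (z).  Bin ``i`` holds the nuclei
    of height ranks ``[i*bin_size, (i+1)*bin_size)``.
    """
    c = _as_centroids(centroids)
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    order = np.argsort(-c[:, 2], kind="stable")
    bins = np.empty(len(c), dtype=int)
    bins[order] = np.arange(len(c)) // bin_size
    return bins


def evl_flags(depth_levels) -> tuple[np.ndarray, np.ndarray]:
    """Outer/inner enveloping-layer flags from depth levels.

    Outer EVL candidates have depth level 1; inner EVL candidates have the
    maximum observed level.  With a single layer every nucleus carries both
    flags (degenerate but consistent).
    """
    levels = np.asarray(depth_levels, dtype=int)
    if levels.size == 0:
        raise ValueError("no depth levels given")
    return levels == 1, levels == levels.max()


def _cross_section_metrics(mask: np.ndarray) -> tuple[float, float] | None:
    """(circularity, aspect) of a binary 2D cross-section, or None if empty."""
    if mask.sum() == 0:
        return None
    area = float(mask.sum())
    perimeter = float(measure.perimeter_crofton(mask, directions=4))
    circ = 4.0 * math.pi * area / perimeter**2 if perimeter > 0 else None
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    ra = rows.max() - rows.min() + 1
    rb = cols.max() - cols.min() + 1
    aspect = min(ra, rb) / max(ra, rb)
    if circ is None:
        return None
    return circ, aspect


def shape_metrics(nucleus) -> ShapeRecord:
    """Circularity and aspect of the three central cross-sections.

    ``nucleus`` needs ``voxels`` (set of (x, y, z)) and ``centroid``; the xy,
    xz and yz sections pass through the rounded centroid.  Degenerate
    (empty) sections yield ``None`` for that plane; the means are taken over
    the defined planes.
    """
    voxels = np.array(sorted(nucleus.voxels))
    if len(voxels) < 8:
        raise ValueError("nucleus too small for shape metrics (need >= 8 voxels)")
    cx, cy, cz = (int(round(v)) for v in nucleus.centroid)

    def plane(sel: np.ndarray, a_col: int, b_col: int):
        pts = voxels[sel]
        if len(pts) == 0:
            return None
        a = pts[:, a_col]
        b = pts[:, b_col]
        mask = np.zeros((b.max() - b.min() + 1, a.max() - a.min() + 1), dtype=bool)
        mask[b - b.min(), a - a.min()] = True
        return _cross_section_metrics(mask)

    xy = plane(voxels[:, 2] == cz, 0, 1)
    xz = plane(voxels[:, 1] == cy, 0, 2)
    yz = plane(voxels[:, 0] == cx, 1, 2)
    return ShapeRecord(
        sphericity_xy=xy[0] if xy else None,
        sphericity_yz=yz[0] if yz else None,
        sphericity_xz=xz[0] if xz else None,
        aspect_xy=xy[1] if xy else None,
        aspect_yz=yz[1] if yz else None,
        aspect_xz=xz[1] if xz else None,
    )


def classify_shape(
    record: ShapeRecord,
    nucleus_radius: float,
    embryo_mean_radius: float,
    paired: bool,
    sphericity_thresh: float = SPHERICITY_THRESH,
    aspect_thresh: float = ASPECT_THRESH,
) -> str:
    """Shape class from the mean sphericity / mean aspect decision tree.

    spherical  : mean sphericity > threshold (0.9)
    irregular  : sphericity <= 0.9 and mean aspect > 0.7
    elliptical : sphericity <= 0.9, aspect <= 0.7, not a dividing pair
    dividing   : as elliptical, but smaller than the embryo mean radius and
                 paired with another such nucleus
    """
    ms, ma = record.mean_sphericity, record.mean_aspect
    if ms is None or ma is None:
        raise ValueError("shape record has no defined cross-section")
    if ms > sphericity_thresh:
        return "spherical"
    if ma > aspect_thresh:
        return "irregular"
    if nucleus_radius < embryo_mean_radius and paired:
        return "dividing"
    return "elliptical"


def pair_detection(
    centroids,
    radii,
    embryo_mean_radius: float,
    nominal_radius: float,
) -> np.ndarray:
    """Mutual nearest-neighbour pairing of sub-mean-radius nuclei.

    Two nuclei are paired iff both are smaller than the embryo mean radius,
    each is the other's nearest small nucleus, and they lie within twice the
    nominal nucleus radius — the geometry of a nucleus in late division.
    Pairing is symmetric by construction.
    """
    c = _as_centroids(centroids)
    r = np.asarray(radii, dtype=float)
    if len(r) != len(c):
        raise ValueError("radii length mismatch")
    paired = np.zeros(len(c), dtype=bool)
    small = np.nonzero(r < embryo_mean_radius)[0]
    if len(small) < 2:
        return paired
    pts = c[small]
    tree = cKDTree(pts)
    d, nn = tree.query(pts, k=2)
    for a in range(len(small)):
        b = int(nn[a, 1])
        if int(nn[b, 1]) == a and d[a, 1] <= 2.0 * nominal_radius:
            paired[small[a]] = True
            paired[small[b]] = True
    return paired


def _equivalent_radius(volume_voxels: float) -> float:
    return (3.0 * volume_voxels / (4.0 * math.pi)) ** (1.0 / 3.0)


def feature_table(result, nominal_radius: float) -> pd.DataFrame:
    """All topology features of a segmentation result, one row per nucleus."""
    nuclei = result.nuclei
    if not nuclei:
        return pd.DataFrame(
            columns=["id", "size", "depth_level", "thickness", "density3d",
                     "density2d", "neighbor3d", "neighbor2d", "h_sorting",
                     "evl_inner", "evl_outer"]
        )
    cents = result.centroids
    thickness, depth = thickness_and_depth(cents, nominal_diameter=2 * nominal_radius)
    d3, d2 = density_features(cents, depth)
    n3, n2 = neighbor_features(cents, depth)
    hbins = h_sorting(cents)
    outer, inner = evl_flags(depth)
    return pd.DataFrame(
        {
            "id": [n.id for n in nuclei],
            "size": [n.volume for n in nuclei],
            "depth_level": depth,
            "thickness": thickness,
            "density3d": d3,
            "density2d": d2,
            "neighbor3d": n3,
            "neighbor2d": n2,
            "h_sorting": hbins,
            "evl_inner": inner,
            "evl_outer": outer,
        }
    )


def shape_table(result, nominal_radius: float) -> pd.DataFrame:
    """Shape metrics and classes of a segmentation result."""
    nuclei = result.nuclei
    radii = np.array([_equivalent_radius(n.volume) for n in nuclei])
    embryo_mean = float(radii.mean()) if len(radii) else 0.0
    paired = (
        pair_detection(result.centroids, radii, embryo_mean, nominal_radius)
        if len(nuclei) >= 2
        else np.zeros(len(nuclei), dtype=bool)
    )
    rows = []
    for i, n in enumerate(nuclei):
        rec = shape_metrics(n)
        rows.append(
            {
                "id": n.id,
                "sphericity_xy": rec.sphericity_xy,
                "sphericity_yz": rec.sphericity_yz,
                "sphericity_xz": rec.sphericity_xz,
                "mean_sphericity": rec.mean_sphericity,
                "aspect_xy": rec.aspect_xy,
                "aspect_yz": rec.aspect_yz,
                "aspect_xz": rec.aspect_xz,
                "mean_aspect": rec.mean_aspect,
                "paired": bool(paired[i]),
                "shape_class": classify_shape(rec, radii[i], embryo_mean, bool(paired[i])),
            }
        )
    return pd.DataFrame(rows)
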