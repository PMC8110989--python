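# Methods

## The segmentation model

`wavenuc` segments fluorescently labelled nuclei in 3D confocal z-stacks.
The core assumption is that a nucleus is a bright, roughly isotropic blob of
a known approximate radius *r* (in pixels), sitting on a background that may
carry heavy, unstructured noise. The method makes no use of absolute
intensity thresholds; its single required parameter is *r*.

Each z-slice *f(x, y)* is correlated with dilated copies of a 2D Mexican-hat
wavelet,

    K(s, a, b) = s^(-1/2) * Σ_{x,y} f(x, y) ψ((x − a)/s, (y − b)/s),
    ψ(x, y)    = (1/πσ₀²) (1 − (x² + y²)/(2σ₀²)) exp(−(x² + y²)/σ₀²),

over the scale set {r − 1, r, r + 1}. The sampled, truncated kernel is
shifted to exact zero sum, so any constant background (and, up to edge
effects, any slowly varying intensity gradient) is annihilated — this is
what makes the transform immune to attenuation ramps without preprocessing.

A nucleus appears as a positive response maximum co-located across all
scales, surrounded by a closed zero-level contour. Two facts carry the
whole design:

1. **Real objects are scale-stable.** The zero-level contour of a real blob
   is dominated by the object's own extent, so its area is nearly the same
   at every scale in the set.
2. **Noise structure is kernel-sized.** A response feature created by noise
   inherits the kernel footprint, so its contour area grows like s² — a
   23–27% step between adjacent scales, which always violates a 10% area
   agreement.

The pipeline is: per-slice multi-scale identification → 3D alignment of the
2D masks → lateral division → axial division → size filtering.

### Pipeline stages and their tunables

| parameter | default | meaning |
|---|---|---|
| `radius` | required | expected nucleus radius, pixels |
| scale set | {r−1, r, r+1} | dilations of the mother wavelet |
| `mother_sigma` σ₀ | 0.35 | kernel width at scale 1 (see below) |
| `similarity_tol` | 0.10 | cross-scale contour-area agreement |
| `colocation_tol` | 2 px | peak co-location across scales |
| `h_frac` | 0.02 | extremum prominence floor, fraction of the slice's coefficient range |
| `overlap_thresh` | 0.80 | adjacent-slice mask intersection / smaller area |
| `intensity_floor` | 0.20 | minimum mask intensity relative to the seed centre |
| `shift_frac` | 1/3 | centre-shift division threshold, fraction of r |
| `min_size_frac` | 0.20 | volume cutoff, fraction of (4/3)πr³ |

**Identification.** Coefficient extrema (prominence ≥ `h_frac` of the
slice's coefficient range, suppressing plateau duplicates) that co-locate
within 2 px across every scale become candidates. For each candidate the
4-connected positive region around the peak is extracted at every scale;
the candidate survives if at least two scales' areas agree within
`similarity_tol` (relative spread), and the agreeing regions are combined
by per-pixel majority vote. The resulting region boundary is regularized by
a 3×3 binary opening + closing — impulse noise frays the discrete
zero-level set, which would otherwise destabilize the slice-to-slice
overlap test. Touching nuclei surface as one merged region holding several
candidates; the region is partitioned among them by nearest centre, so
masks never overlap and the final label volume is a true partition.

**Alignment.** Masks chain across adjacent slices when their intersection
exceeds 80% of the smaller area and the (95th-percentile) intensity inside
the new mask is at least 20% of the chain's seed-centre intensity. Chains
grow from seeds in decreasing centre-intensity order (median over the 3×3
centre neighbourhood), which anchors the intensity floor at true nucleus
centres; sub-floor tails are set aside as single-slice objects for the size
filter. One or two degraded slices are bridged when the overlap rule holds
directly across the gap (at 75% of the threshold, since a sphere overlaps
itself less across a 2–3-plane separation); a missing slice is filled with
the geometric intersection of its neighbours. Robust statistics matter
here: under salt-and-pepper noise the literal "max intensity" of any region
is the impulse amplitude, which would void the floor entirely.

Greedy chaining can still split a nucleus's column in two when a merged
cross-section is consumed by the wrong object's chain, so a stitching pass
(after alignment, and again after the lateral division) re-joins objects
with disjoint z ranges whose facing masks are co-columnar (centre shift at
most `shift_frac · r`), overlap at 75% of the alignment threshold, where at
least one piece is already a plausible nucleus (above the size cutoff) and
both facing masks clear the intensity floor against the brighter seed.
The guards matter: without them, stitching would resurrect the dim tails
the alignment deliberately set aside.

**Division.** Within each object, slices holding more than one co-located
candidate are split along the perpendicular bisector between the centres,
and sub-masks re-chain across slices; a centre shift larger than
`shift_frac · r` between consecutive slices cuts the object. Axially, the
object's XZ and YZ mid-planes (averaged over a 3-px slab, resampled to
isotropic pixels if the voxel size is anisotropic) are run through the same
wavelet identification; only when **both** planes show two or more
qualifying extrema separated in z is the object cut at the mid-plane.
Requiring full identification (not just extrema) on the planes is what
keeps impulse noise from faking a second nucleus.

**Filtering.** Objects spanning fewer than max(2, ⌈r/4⌉) slices are plane
fragments, not nuclei (no sphere of admissible radius is that thin), and
objects smaller than `min_size_frac` of the expected sphere volume
(4/3)πr³, scaled by lateral/axial voxel anisotropy, are removed. Division
is skipped for objects already below the cutoff — their parts could never
survive it — as a pure optimization.

### Choice of the mother kernel width σ₀

The source formulation leaves the kernel width at scale 1 open. It trades
off two failure modes measured on the synthetic benchmark:

* large σ₀ (≈ 1): strong noise averaging, but the zero-level contour is
  kernel-dominated — areas across {8, 9, 10} spread by ~40%, so genuine
  nuclei fail the 10% similarity rule and nothing is detected;
* small σ₀ (≈ 0.2): contours are object-locked (6–7% spread), but the
  kernel barely averages noise, and impulse noise at density 0.10 destroys
  the per-slice contours.

σ₀ = 0.35 is the largest width at which a clean nucleus of the benchmark's
blob profile (Gaussian, σ_b = 0.4 r) still passes the similarity rule with
margin; it is fixed package-wide and exposed for sensitivity analysis.

### A note on sign conventions

Some descriptions of this method speak of nucleus centres as coefficient
*minima*. With the transform and kernel exactly as written above, a bright
blob produces a positive *maximum*; the geometry (one extremum per nucleus,
zero-level contour around it) is identical, and this implementation detects
maxima of the positive response throughout.

## Synthetic benchmark generator

The generator emulates the validation imagery the method is designed for:
nuclei are isotropic 3D Gaussian blobs (peak intensity *I*, s.d. 0.4 r),
placed uniformly at random with every pairwise and boundary distance at
least 1.5 r; realized radius and intensity are r ± U(0,1)·ρ_r·r and
I ± U(0,1)·ρ_I·I with equiprobable sign (a symmetric-uniform mixture, i.e.
uniform on [r(1−ρ), r(1+ρ)]). A forced-overlap mode places the first half
normally and accepts each remaining nucleus only *closer* than 1.5 r to an
existing one. White Gaussian noise of variance 0.01·I² is always added;
regimes on top: extra Gaussian noise of variance ND, salt-and-pepper
replacing a fraction ND of voxels with the volume maximum or zero, or a
lateral linear attenuation ramp (factor ND at x = 0 to 1 at the right
edge). Defaults: 128×128×40 voxels, 20 nuclei, r = 9 px, I = 1000,
ρ_r = ρ_I = 0.2.

What the generator does **not** emulate: optics (no PSF, no textured
chromatin — nuclei are soft blobs, easier than real nuclei for contour
stability), photon statistics (no Poisson noise), axial anisotropy (voxels
are isotropic unless requested), and imaging artefacts beyond the three
regimes. Passing the benchmark therefore demonstrates noise robustness and
overlap-division ability under controlled conditions, not performance on
real embryos.

The ground-truth label volume marks voxels within the realized radius of
each centre (nearest centre wins). These spheres are systematically larger
than the wavelet masks (the response zero-level sits near √2 × the combined
kernel/blob width ≈ 0.7–0.8 r), so the voxel-level Jaccard index of a
detection-perfect segmentation measures ≈ 0.64; detection metrics are
unaffected.

## Baselines

* **point-wise**: 9×9×3 mean smoothing, h-maxima suppression (depth 10% of
  the smoothed dynamic range), merging of maxima closer than 6 px, centre
  intensity over a 6×6×3 ellipsoid. A detector; it produces no masks.
* **multilevel Otsu**: per-slice Gaussian low-pass (σ=2), unsharp masking
  (radius 2, amount 1), 5×5 adaptive Wiener, then per-slice 3-class Otsu
  with the brightest class as foreground; 26-connected 3D components.
* **Derivatives-Sum**: per-slice Gaussian denoise, F = w₁·|∇f| + w₂·(−∇²f)
  + w₃·det H(f) with each map min–max normalized (weights default 1,1,1;
  the Laplacian is negated because blob interiors have ∇² < 0), per-slice
  Otsu binarization of F, masks chained across z at 50% overlap.

Otsu and DS apply the same minimum-size rule as the wavelet path when given
the expected radius; without it their precision collapses to speckle
counting and the comparison would be a strawman.

## Evaluation

Detections and ground-truth centres match when each is the other's nearest
neighbour **and** they lie within one nucleus radius (the cap is ours: an
uncapped mutual-NN rule would match a detection across the whole image to a
lone truth point). TP rate = TP/(TP+FN), Precision = TP/(TP+FP), FN rate =
FN/(TP+FN); undefined denominators yield explicit `None`, never 0. The
voxel-level accuracy is the Jaccard index of binary foregrounds.

## Morphometrics

Density (3D / in-layer 2D counts within 30 px), neighbour distance (mean of
the two nearest, 3D / in-layer), depth level (radial rank from the embryo
surface: azimuthal columns about the embryo centre, binned by the nominal
diameter, outermost = 1), thickness (distance to a local plane fitted to
the innermost layer within 360 solid-angle sub-regions — 9 equal-area polar
bands × 40 azimuthal sectors; sparse regions borrow the nearest inner-layer
nuclei by direction), height sorting (bins of 500 from the top of the
z-axis down), and enveloping-layer flags (depth level 1 = outer candidate,
maximum level = inner candidate). The embryo centre is an algebraic
least-squares sphere fit — the centroid of shell-distributed nuclei is
biased by uneven angular coverage.

Shape classification uses the three central cross-sections through the
centroid: circularity 4π·area/perimeter² (Crofton perimeter, 4 directions —
the estimator is calibrated so digital disks score ≈ 1) and the min/max
extent ratio, averaged over defined planes. Classes: mean circularity
> 0.9 → spherical; else mean aspect > 0.7 → irregular; else dividing if
the nucleus's equivalent radius is below the embryo mean *and* it forms a
mutual-nearest-neighbour pair with another such nucleus within 2 nominal
radii, otherwise elliptical. "Paired" is operationalized as that mutual-NN
rule; aspect is normalized to ≤ 1 so the 0.7 threshold measures elongation
regardless of orientation. Both choices are documented here because the
source material leaves them open.

Known limitations: depth level assumes a roughly shell-structured point
cloud (it is not meaningful for arbitrary clusters); the 30 px density
radius and 500-nucleus height bins are pixel-unit constants and do not
rescale with voxel size; the height axis is the volume's z axis unless a
config override supplies one (embryo reorientation is out of scope).

## Benchmark problem sizes

The shipped tests and the acceptance script use 20-volume batches for the
salt-and-pepper study (noise densities 0.02 / 0.05 / 0.10) and 8-volume
batches for the Gaussian / attenuation / forced-overlap ordering checks —
with 20 nuclei per volume, an 8-volume batch mean is an average over 160
objects, stable to a few hundredths. Batch means of detection rates are
asserted within a 10% band of their nominal values, and method orderings
with a 0.03 allowance for batch-mean estimation noise.

## Numerical choices

Reflect (symmetric) boundary padding for all correlations; FFT-based
correlation once the direct cost exceeds 2²¹ multiply-adds (both routes
agree with a brute-force evaluation to 1e−8 relative); deterministic
tie-breaks everywhere (nearest-neighbour ties and equidistant pixels in
median-line splits go to the lowest index); all randomness flows from a
single integer seed through `numpy.random.default_rng`. Degenerate inputs
(empty volumes, constant slices, single-slice objects, undefined rate
denominators) return explicit empty/`None`/unchanged results rather than
raising, except where the contract demands an error (non-positive σ,
infeasible packing, mismatched shapes).
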