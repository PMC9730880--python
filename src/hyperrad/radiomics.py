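"""IBSI-style per-lesion radiomic features: histogram, shape, GLCM, GLRLM.

The catalog is fixed and versioned: every lesion yields the same 46 features
per modality (17 histogram, 9 shape, 12 co-occurrence, 8 run-length),
namespaced ``{hist|shape|glcm|glrlm}_<name>`` with a modality prefix
(``ct_`` / ``pet_``) when both modalities are combined.

Conventions:

* Histogram statistics are computed on the resampled in-mask intensities;
  entropy and uniformity use the fixed-bin-width discretized indices
  (log base 2).
* Percentiles interpolate linearly between order statistics at 1-based
  position 1 + q*(n-1).
* ``hist_energy`` is intensity energy (sum of squared intensities), not
  histogram uniformity.
* Texture matrices use the 13 unique 3D direction classes at Chebyshev
  distance 1, merged into a single matrix before normalization.  Directions
  that cannot move inside the mask bounding box (a singleton axis) are
  dropped, so a 1-voxel-thick ROI is scanned only along its extent.
"""

from __future__ import annotations

import warnings
from itertools import product

import numpy as np
from scipy.ndimage import gaussian_filter as ndi_gaussian
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import marching_cubes, mesh_surface_area

from .imaging import (
    DiscretizedROI,
    LesionMask,
    LesionVolume,
    discretize,
    lesion_volume_filter,
    resample_isotropic,
    resample_mask,
)

__all__ = [
    "intensity_features",
    "shape_features",
    "glcm_features",
    "glrlm_features",
    "extract_all",
    "feature_catalog",
    "cooccurrence_matrix",
    "runlength_matrix",
    "DIRECTIONS_3D",
]

#: The 13 unique 3D displacement classes (one representative per +/- pair).
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)


# ---------------------------------------------------------------------------
# Histogram / intensity statistics


def intensity_features(volume: LesionVolume, mask: LesionMask,
                       roi: DiscretizedROI) -> dict[str, float]:
    """First-order statistics of the in-mask intensity distribution."""
    x = volume.intensities[mask.voxels]
    if x.size == 0:
        raise ValueError("empty ROI: no in-mask voxels")
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    sd = np.sqrt(var)
    centered = x - mean
    if sd > 0:
        skew = float((centered**3).mean() / sd**3)
        kurt = float((centered**4).mean() / sd**4 - 3.0)  # excess kurtosis
        cv = sd / abs(mean) if mean != 0 else 0.0
    else:
        skew = kurt = cv = 0.0
    p10, p25, med, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    bins = roi.in_mask_bins
    counts = np.bincount(bins)[1:]
    p = counts[counts > 0] / n
    entropy = float(max(0.0, -(p * np.log2(p)).sum()))
    uniformity = float((p**2).sum())

    return {
        "hist_mean": mean,
        "hist_variance": var,
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
        "hist_min": float(x.min()),
        "hist_max": float(x.max()),
        "hist_percentile10": float(p10),
        "hist_percentile90": float(p90),
        "hist_median": float(med),
        "hist_RMS": float(np.sqrt((x**2).mean())),
        "hist_energy": float((x**2).sum()),
        "hist_entropy": entropy,
        "hist_uniformity": uniformity,
        "hist_range": float(x.max() - x.min()),
        "hist_iqr": float(p75 - p25),
        "hist_mad": float(np.abs(centered).mean()),
        "hist_cv": float(cv),
    }


# ---------------------------------------------------------------------------
# Shape


def _max_diameter(centers_mm: np.ndarray) -> float:
    """Largest pairwise distance between voxel centers (convex hull trick)."""
    pts = centers_mm
    if len(pts) > 10:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) masks: brute force
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def shape_features(mask: LesionMask) -> dict[str, float]:
    """Morphological features of the binary lesion region.

    Surface area comes from the triangulated 0.5-level isosurface of the
    zero-padded mask; axis ratios from the principal components of the
    voxel-center cloud.
    """
    if not mask.voxels.any():
        raise ValueError("empty mask")
    n = int(mask.voxels.sum())
    volume = mask.volume_mm3

    # Light Gaussian pre-smoothing (sigma 0.5 voxel) of the 0/1 field tames
    # the staircase artifact of the isosurface; tiny masks that would vanish
    # fall back to the raw binary field.
    padded = np.pad(mask.voxels.astype(float), 2)
    smoothed = ndi_gaussian(padded, 0.5)
    field = smoothed if smoothed.max() > 0.5 else padded
    verts, faces, _, _ = marching_cubes(field, level=0.5,
                                        spacing=tuple(mask.spacing_mm))
    area = float(mesh_surface_area(verts, faces))

    sphericity = np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area
    compactness = 36 * np.pi * volume**2 / area**3

    centers = np.argwhere(mask.voxels) * mask.spacing_mm
    max_diam = _max_diameter(centers)

    if n > 1:
        cov = np.cov(centers, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
        eig = np.clip(eig, 0.0, None)
        major = 4.0 * np.sqrt(eig[0])
        elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
        flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0
    else:
        major, elongation, flatness = 0.0, 1.0, 1.0

    return {
        "shape_volume": volume,
        "shape_surface_area": area,
        "shape_sphericity": float(sphericity),
        "shape_compactness": float(compactness),
        "shape_surface_to_volume": float(area / volume),
        "shape_max_diameter_3d": max_diam,
        "shape_major_axis_length": float(major),
        "shape_elongation": elongation,
        "shape_flatness": flatness,
    }


# ---------------------------------------------------------------------------
# Texture: grey-level co-occurrence


def _bounding_box(mask: np.ndarray) -> tuple[slice, ...]:
    idx = np.argwhere(mask)
    lo, hi = idx.min(0), idx.max(0) + 1
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def _active_directions(shape: tuple[int, ...]) -> list[tuple[int, int, int]]:
    """Directions that can move inside the bounding box (skip singleton axes)."""
    return [d for d in DIRECTIONS_3D
            if all(shape[a] > 1 for a in range(3) if d[a] != 0)]


def cooccurrence_matrix(roi: DiscretizedROI) -> np.ndarray:
    """Symmetric merged GLCM over the active 3D directions at distance 1.

    Returns the normalized (Ng x Ng) probability matrix indexed by grey
    level - 1; Ng is the highest in-mask bin index.
    """
    box = _bounding_box(roi.mask)
    bins = np.where(roi.mask, roi.bin_indices, 0)[box]
    ng = int(bins.max())
    counts = np.zeros((ng, ng), dtype=float)
    for d in _active_directions(bins.shape):
        src = tuple(slice(max(k, 0), bins.shape[a] + min(k, 0))
                    for a, k in enumerate(d))
        dst = tuple(slice(max(-k, 0), bins.shape[a] + min(-k, 0))
                    for a, k in enumerate(d))
        a, b = bins[src], bins[dst]
        ok = (a > 0) & (b > 0)
        np.add.at(counts, (a[ok] - 1, b[ok] - 1), 1.0)
    counts = counts + counts.T  # symmetric: count each ordered pair both ways
    total = counts.sum()
    if total > 0:
        counts /= total
    return counts


def glcm_features(roi: DiscretizedROI) -> dict[str, float]:
    """Co-occurrence texture features from the merged symmetric GLCM."""
    names = ["glcm_joint_maximum", "glcm_joint_average", "glcm_joint_variance",
             "glcm_joint_entropy", "glcm_contrast", "glcm_dissimilarity",
             "glcm_inverse_difference", "glcm_inverse_difference_moment",
             "glcm_correlation", "glcm_cluster_tendency", "glcm_cluster_shade",
             "glcm_angular_second_moment"]
    p = cooccurrence_matrix(roi)
    if p.sum() == 0:
        warnings.warn("ROI has no voxel pairs; co-occurrence features set to 0")
        return {k: 0.0 for k in names}

    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = p.sum(axis=1)
    mu = float((i * pi).sum())  # symmetric: row and column means coincide
    var = float(((i - mu) ** 2 * pi).sum())
    nz = p > 0

    corr = (float((((ii - mu) * (jj - mu) * p)).sum()) / var) if var > 0 else 1.0
    return {
        "glcm_joint_maximum": float(p.max()),
        "glcm_joint_average": mu,
        "glcm_joint_variance": float((((ii - mu) ** 2) * p).sum()),
        "glcm_joint_entropy": float(max(0.0, -(p[nz] * np.log2(p[nz])).sum())),
        "glcm_contrast": float(((ii - jj) ** 2 * p).sum()),
        "glcm_dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "glcm_inverse_difference": float((p / (1 + np.abs(ii - jj))).sum()),
        "glcm_inverse_difference_moment": float((p / (1 + (ii - jj) ** 2)).sum()),
        "glcm_correlation": corr,
        "glcm_cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "glcm_cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "glcm_angular_second_moment": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# Texture: grey-level run length


def runlength_matrix(roi: DiscretizedROI) -> tuple[np.ndarray, int]:
    """Merged GLRLM over the active directions.

    Returns ``(R, n_directions)`` where ``R[g-1, l-1]`` counts runs of grey
    level g and length l, summed over directions.
    """
    box = _bounding_box(roi.mask)
    bins = np.where(roi.mask, roi.bin_indices, 0)[box]
    ng = int(bins.max())
    nmax = max(bins.shape)
    dirs = _active_directions(bins.shape)
    R = np.zeros((ng, nmax), dtype=float)
    shape = bins.shape
    if not dirs:  # 1x1x1 box: each voxel is its own run
        for g in bins[bins > 0]:
            R[g - 1, 0] += 1.0
        return R, 1
    for d in dirs:
        # run starts: in-mask voxels whose predecessor along d is absent/different
        for start in np.argwhere(bins > 0):
            prev = start - d
            if (0 <= prev[0] < shape[0] and 0 <= prev[1] < shape[1]
                    and 0 <= prev[2] < shape[2]
                    and bins[tuple(prev)] == bins[tuple(start)]):
                continue
            g = bins[tuple(start)]
            length = 1
            nxt = start + d
            while (0 <= nxt[0] < shape[0] and 0 <= nxt[1] < shape[1]
                   and 0 <= nxt[2] < shape[2] and bins[tuple(nxt)] == g):
                length += 1
                nxt = nxt + d
            R[g - 1, length - 1] += 1.0
    return R, max(len(dirs), 1)


def glrlm_features(roi: DiscretizedROI) -> dict[str, float]:
    """Run-length texture features from the merged GLRLM."""
    R, ndir = runlength_matrix(roi)
    nr = R.sum()
    nv = int(roi.mask.sum())
    if nr == 0:  # unreachable for a nonempty ROI, but keep features finite
        return {k: 0.0 for k in
                ["glrlm_sre", "glrlm_lre", "glrlm_lgre", "glrlm_hgre",
                 "glrlm_run_percentage", "glrlm_run_length_nonuniformity",
                 "glrlm_grey_level_nonuniformity", "glrlm_run_entropy"]}
    g = np.arange(1, R.shape[0] + 1, dtype=float)
    l = np.arange(1, R.shape[1] + 1, dtype=float)
    rg = R.sum(axis=1)  # per grey level
    rl = R.sum(axis=0)  # per run length
    p = R[R > 0] / nr
    return {
        "glrlm_sre": float((rl / l**2).sum() / nr),
        "glrlm_lre": float((rl * l**2).sum() / nr),
        "glrlm_lgre": float((rg / g**2).sum() / nr),
        "glrlm_hgre": float((rg * g**2).sum() / nr),
        "glrlm_run_percentage": float(nr / (nv * ndir)),
        "glrlm_run_length_nonuniformity": float((rl**2).sum() / nr),
        "glrlm_grey_level_nonuniformity": float((rg**2).sum() / nr),
        "glrlm_run_entropy": float(max(0.0, -(p * np.log2(p)).sum())),
    }


# ---------------------------------------------------------------------------
# Catalog and full extraction

_FAMILY_EXTRACTORS = {
    "hist": 17, "shape": 9, "glcm": 12, "glrlm": 8,
}


def feature_catalog() -> list[dict[str, str]]:
    """The fixed per-modality feature catalog (name + family), in order."""
    tiny = _tiny_roi_features()
    return [{"name": k, "family": k.split("_", 1)[0]} for k in tiny]


def _tiny_roi_features() -> dict[str, float]:
    vol = LesionVolume(np.arange(8, dtype=float).reshape(2, 2, 2),
                       (1, 1, 1), (0, 0, 0), "PET")
    msk = LesionMask(np.ones((2, 2, 2), bool), (1, 1, 1), (0, 0, 0))
    roi = discretize(vol, msk)
    out: dict[str, float] = {}
    out.update(intensity_features(vol, msk, roi))
    out.update(shape_features(msk))
    out.update(glcm_features(roi))
    out.update(glrlm_features(roi))
    return out


def _extract_modality(volume: LesionVolume, mask: LesionMask,
                      target_mm: float, bin_width: float | None,
                      anchor: float | None) -> dict[str, float]:
    v = resample_isotropic(volume, target_mm)
    m = resample_mask(mask, target_mm)
    if v.intensities.shape != m.voxels.shape:  # masks can round up differently
        shape = tuple(min(a, b) for a, b in zip(v.intensities.shape, m.voxels.shape))
        v = LesionVolume(v.intensities[tuple(slice(s) for s in shape)],
                         v.spacing_mm, v.origin_mm, v.modality)
        m = LesionMask(m.voxels[tuple(slice(s) for s in shape)],
                       m.spacing_mm, m.origin_mm, m.lesion_id)
    roi = discretize(v, m, bin_width, anchor)
    out: dict[str, float] = {}
    out.update(intensity_features(v, m, roi))
    out.update(shape_features(m))
    out.update(glcm_features(roi))
    out.update(glrlm_features(roi))
    return out


def extract_all(ct: LesionVolume, pet: LesionVolume,
                ct_mask: LesionMask, pet_mask: LesionMask,
                target_mm: float = 2.0,
                bin_width_ct: float | None = None,
                bin_width_pet: float | None = None,
                anchor_ct: float | None = None,
                anchor_pet: float | None = None,
                min_cc: float = 0.5) -> dict[str, float]:
    """Full two-modality extraction for one lesion.

    Applies the minimum-volume filter on the native grids, resamples to
    isotropic voxels, discretizes per modality and concatenates ``ct_``- and
    ``pet_``-prefixed features.  Shape features come from each modality's own
    mask (CT and PET segmentations differ).
    """
    lesion_id = ct_mask.lesion_id
    if not lesion_volume_filter(ct_mask, min_cc) or \
       not lesion_volume_filter(pet_mask, min_cc):
        raise ValueError(f"lesion {lesion_id!r} below {min_cc} cc volume filter")
    try:
        ct_feats = _extract_modality(ct, ct_mask, target_mm, bin_width_ct, anchor_ct)
        pet_feats = _extract_modality(pet, pet_mask, target_mm, bin_width_pet,
                                      anchor_pet)
    except Exception as exc:
        raise RuntimeError(f"feature extraction failed for lesion "
                           f"{lesion_id!r}: {exc}") from exc
    out = {f"ct_{k}": v for k, v in ct_feats.items()}
    out.update({f"pet_{k}": v for k, v in pet_feats.items()})
    return out
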