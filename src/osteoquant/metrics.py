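"""The four bespoke imaging indices.

* Bone-resorption index (BRI): mean pH-probe intensity inside the
  osteoclast mask (signal) over the mean outside (noise).  Higher values
  mean more localized acidification, i.e. more active resorption.
* Cell-deformation index (CDI): for one cell observed at the two endpoints
  of a time window, (A + C) / (A + B) where A and C are the footprint
  areas at the endpoints and B their overlap.  1 for a stationary cell;
  grows with translation and shape change, so it reads out motility.
* TRAP⁺ area: summed mature-osteoclast object area per image, reported
  relative to the reference-group mean.
* Adhesion ratio: the bone-contact read-out of precursors — sum of
  precursor object measure versus the colocalized (precursor AND bone)
  measure, reported both as the literal precursor/adhesion ratio (>= 1)
  and as the bounded adhesion fraction (adhesion/precursor in [0, 1]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .segmentation import RegionLabels

logger = logging.getLogger(__name__)

__all__ = [
    "BriResult",
    "CdiResult",
    "AdhesionResult",
    "bone_resorption_index",
    "cell_deformation_index",
    "deformation_indices",
    "trap_area",
    "adhesion_ratio",
]


@dataclass
class BriResult:
    image_id: str | None
    signal: float  # mean probe intensity inside the osteoclast mask
    noise: float  # mean outside
    bri: float  # signal / noise


@dataclass
class CdiResult:
    cell_id: int | None
    window: tuple[int, int]
    area_t0_um2: float  # A
    area_t1_um2: float  # C
    overlap_um2: float  # B
    cdi: float  # (A + C) / (A + B)


@dataclass
class AdhesionResult:
    image_id: str | None
    precursor_sum: float  # total precursor measure (µm² or µm³)
    adhesion_sum: float  # colocalized measure
    printed_ratio: float  # precursor / adhesion, NaN when adhesion is 0
    adhesion_fraction: float  # adhesion / precursor, in [0, 1]
    flagged: bool = False  # True when the printed ratio was undefined


def bone_resorption_index(
    phocas_image: np.ndarray,
    osteoclast_mask: np.ndarray,
    image_id: str | None = None,
    exclusion_ring_px: int = 0,
) -> BriResult:
    """Ratio of mean pH-probe intensity inside the osteoclast mask to the
    mean outside it.

    Inputs are expected post gamma correction and maximum-intensity
    projection.  ``exclusion_ring_px`` optionally drops a dilation ring
    around the mask from the noise region to avoid counting PSF bleed as
    noise.

    Raises on an empty or full mask, and on a zero noise mean (the index
    would be infinite, which no real acquisition produces).
    """
    phocas_image = np.asarray(phocas_image, dtype=float)
    mask = np.asarray(osteoclast_mask, dtype=bool)
    if phocas_image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("osteoclast mask is empty")
    if mask.all():
        raise ValueError("osteoclast mask covers the whole field")
    outside = ~mask
    if exclusion_ring_px > 0:
        from scipy import ndimage

        ring = ndimage.binary_dilation(mask, iterations=exclusion_ring_px) & ~mask
        outside = outside & ~ring
        if not outside.any():
            raise ValueError("exclusion ring left no noise region")
    signal = float(phocas_image[mask].mean())
    noise = float(phocas_image[outside].mean())
    if noise == 0:
        raise ValueError("zero noise mean: resorption index undefined")
    return BriResult(image_id=image_id, signal=signal, noise=noise, bri=signal / noise)


def cell_deformation_index(
    footprint_t0: np.ndarray,
    footprint_t1: np.ndarray,
    pixel_size_um: float = 1.0,
    cell_id: int | None = None,
    window: tuple[int, int] = (0, 1),
) -> CdiResult:
    """(A + C) / (A + B) for one cell across a time window.

    A and C are the footprint areas at the start and end of the window, B
    the area of their overlap.  Since B <= C the index is always >= 1,
    with equality exactly when the end footprint lies inside the start
    footprint (B = C).
    """
    fp0 = np.asarray(footprint_t0, dtype=bool)
    fp1 = np.asarray(footprint_t1, dtype=bool)
    if fp0.shape != fp1.shape:
        raise ValueError("footprints must share the frame geometry")
    if not fp0.any() or not fp1.any():
        raise ValueError("empty footprint: cell must be excluded from this window")
    unit = pixel_size_um**2
    a = float(fp0.sum()) * unit
    c = float(fp1.sum()) * unit
    b = float((fp0 & fp1).sum()) * unit
    return CdiResult(
        cell_id=cell_id,
        window=window,
        area_t0_um2=a,
        area_t1_um2=c,
        overlap_um2=b,
        cdi=(a + c) / (a + b),
    )


def deformation_indices(
    labels_t0: RegionLabels,
    labels_t1: RegionLabels,
    max_match_um: float = 20.0,
    window: tuple[int, int] = (0, 1),
) -> list[CdiResult]:
    """Per-cell deformation indices between two labeled frames.

    Cells are put in correspondence by centroid-nearest optimal matching
    within ``max_match_um`` (mature osteoclasts barely translocate, so a
    generous gate suffices); unmatched objects are skipped with a log
    message.
    """
    if labels_t0.n_objects == 0 or labels_t1.n_objects == 0:
        return []
    c0 = labels_t0.table[["centroid_y_um", "centroid_x_um"]].to_numpy()
    c1 = labels_t1.table[["centroid_y_um", "centroid_x_um"]].to_numpy()
    dist = np.linalg.norm(c0[:, None, :] - c1[None, :, :], axis=2)
    cost = np.where(dist <= max_match_um, dist, 1e6)
    rows, cols = linear_sum_assignment(cost)
    results = []
    for i, j in zip(rows, cols):
        if dist[i, j] > max_match_um:
            continue
        lab0 = int(labels_t0.table["label"].iloc[i])
        lab1 = int(labels_t1.table["label"].iloc[j])
        fp0 = labels_t0.label_image == lab0
        fp1 = labels_t1.label_image == lab1
        results.append(
            cell_deformation_index(
                fp0, fp1, labels_t0.pixel_size_um, cell_id=lab0, window=window
            )
        )
    skipped = labels_t0.n_objects - len(results)
    if skipped:
        logger.info("deformation_indices: %d objects had no match within gate", skipped)
    return results


def trap_area(labels: RegionLabels, reference_mean: float) -> float:
    """Summed TRAP⁺ (mature-osteoclast) object area of one image divided
    by the reference-group mean area, i.e. 'area relative to steady state'."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return labels.total_measure() / reference_mean


def adhesion_ratio(
    precursor_labels: RegionLabels,
    adhesion_mask: np.ndarray,
    image_id: str | None = None,
) -> AdhesionResult:
    """Precursor-to-adhesion measure ratio for one image.

    ``adhesion_mask`` must be the colocalization of the bone mask with the
    precursor objects, so the adhesion measure can never exceed the
    precursor measure: the printed ratio is >= 1 and the adhesion fraction
    (its inverse) lies in [0, 1].  When no voxel colocalizes the printed
    ratio is undefined; the record reports fraction 0 and is flagged.
    """
    adhesion_mask = np.asarray(adhesion_mask, dtype=bool)
    if adhesion_mask.shape != precursor_labels.label_image.shape:
        raise ValueError("adhesion mask and labels have different shapes")
    outside = adhesion_mask & ~precursor_labels.mask()
    if outside.any():
        raise ValueError(
            "adhesion mask extends outside the precursor objects; it must be "
            "their intersection with the bone mask"
        )
    unit = precursor_labels.pixel_size_um**2 * (
        precursor_labels.z_step_um if precursor_labels.is_3d else 1.0
    )
    precursor_sum = precursor_labels.total_measure()
    adhesion_sum = float(adhesion_mask.sum()) * unit
    if precursor_sum <= 0:
        raise ValueError("no precursor objects: adhesion ratio undefined")
    if adhesion_sum == 0:
        return AdhesionResult(
            image_id=image_id,
            precursor_sum=precursor_sum,
            adhesion_sum=0.0,
            printed_ratio=float("nan"),
            adhesion_fraction=0.0,
            flagged=True,
        )
    return AdhesionResult(
        image_id=image_id,
        precursor_sum=precursor_sum,
        adhesion_sum=adhesion_sum,
        printed_ratio=precursor_sum / adhesion_sum,
        adhesion_fraction=adhesion_sum / precursor_sum,
    )
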