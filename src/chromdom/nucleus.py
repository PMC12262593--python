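"""Nucleus segmentation from the DAPI channel.

Because the Z extent of a nucleus stack (tens of slides) is tiny compared
with its in-plane size, segmentation is 2D and slide-by-slide: threshold
the DAPI signal, keep the largest connected components, refine each
morphologically (fill holes, dilate, fill again), gate on size and shape,
extract a Sobel boundary, and finally stack the accepted per-slide regions
into 3D nuclei.

Default parameter values reflect 1500x1500-pixel acquisitions; the size
gate in particular scales with image area and should be reduced
proportionally for smaller fields of view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

logger = logging.getLogger(__name__)

#: printed pipeline defaults
DAPI_CUTOFF = 500.0
TOP_K_COMPONENTS = 15
REFINE_DILATIONS = 10
MIN_NUCLEUS_PX = 100_000
MIN_CIRCULARITY = 0.4

#: 8-connected structuring element used for all 2D morphology
SQUARE_3x3 = np.ones((3, 3), dtype=bool)


@dataclass
class NucleusRegion:
    """One 3D nucleus assembled from accepted per-slide 2D regions."""

    label: int
    mask: np.ndarray                    # 3D boolean (z, y, x)
    boundary: np.ndarray                # (n, 3) voxel coordinates
    per_slide_areas: dict[int, int] = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def threshold_dapi(slide: np.ndarray, cutoff: float = DAPI_CUTOFF) -> np.ndarray:
    """Binary mask of candidate nucleus pixels: intensity strictly above
    ``cutoff`` (a 499/500/501 slide turns on 501 only)."""
    slide = np.asarray(slide)
    if slide.size == 0:
        raise ValueError("empty slide")
    return slide > cutoff


def candidate_components(mask: np.ndarray, top_k: int = TOP_K_COMPONENTS) -> list[np.ndarray]:
    """The up-to-``top_k`` largest 8-connected components of a 2D mask,
    as boolean masks ordered by pixel count descending."""
    labels, n = ndimage.label(mask, structure=SQUARE_3x3)
    if n == 0:
        return []
    sizes = np.bincount(labels.ravel())[1:]
    order = np.argsort(sizes, kind="stable")[::-1][:top_k]
    return [labels == (i + 1) for i in order]


def refine_region(region: np.ndarray, iterations: int = REFINE_DILATIONS) -> np.ndarray:
    """Morphological refinement of one candidate region: hole filling,
    ``iterations`` dilation steps with the 3x3 square element, and a second
    hole filling. Output always contains the input."""
    filled = ndimage.binary_fill_holes(region)
    dilated = ndimage.binary_dilation(
        filled, structure=SQUARE_3x3, iterations=iterations
    )
    return ndimage.binary_fill_holes(dilated)


def circularity(region: np.ndarray) -> float:
    """2D shape score 4*pi*A / P**2 — 1 for a disk, smaller for elongated
    or ragged regions. The perimeter is the weighted count of boundary
    steps along the traced contour."""
    area = int(region.sum())
    perim = measure.perimeter(region, neighborhood=4)
    if perim == 0:
        return 0.0
    return float(4.0 * np.pi * area / perim**2)


def accept_nucleus(
    region: np.ndarray,
    min_px: int = MIN_NUCLEUS_PX,
    min_shape: float = MIN_CIRCULARITY,
) -> bool:
    """Size-and-shape gate for a refined region: accepted iff its area is
    at least ``min_px`` and its circularity strictly exceeds ``min_shape``."""
    area = int(region.sum())
    if area < min_px:
        return False
    score = circularity(region)
    if score == 0.0:
        logger.warning("degenerate zero-perimeter region of area %d rejected", area)
        return False
    return score > min_shape


def extract_boundary(region: np.ndarray, within_region_only: bool = False) -> np.ndarray:
    """Boundary pixels of a binary region via the Sobel operator.

    Sobel gradients are taken in X and Y on the 0/1 mask (zero padding
    outside the frame, so frame-touching regions still close), combined as
    the gradient magnitude and binarized at > 0. By default every pixel
    with a nonzero response is returned (a ring straddling the region
    edge); with ``within_region_only`` the set is restricted to region
    pixels, which for well-behaved regions equals the set of true pixels
    with at least one false 8-neighbour.
    """
    region = np.asarray(region)
    if not region.any():
        raise ValueError("empty region has no boundary")
    f = region.astype(np.float64)
    gx = ndimage.sobel(f, axis=1, mode="constant", cval=0.0)
    gy = ndimage.sobel(f, axis=0, mode="constant", cval=0.0)
    mag = np.hypot(gx, gy)
    edge = mag > 1e-9
    if within_region_only:
        edge &= region.astype(bool)
    return np.argwhere(edge)


@dataclass
class SlideRegion:
    """One accepted 2D region on one slide."""

    z: int
    mask: np.ndarray
    boundary: np.ndarray  # (n, 2) pixel coordinates


def stack_nuclei(per_slide: list[list[SlideRegion]]) -> list[NucleusRegion]:
    """Stack accepted per-slide regions into 3D nuclei.

    Regions overlapping (26-connectivity) in consecutive slides share one
    3D label; slides are taken in the given z order. Boundaries travel
    with their slide region.
    """
    nz = len(per_slide)
    if nz == 0 or all(len(s) == 0 for s in per_slide):
        return []
    shape2d = next(r.mask.shape for s in per_slide for r in s)
    vol = np.zeros((nz,) + shape2d, dtype=bool)
    for z, regions in enumerate(per_slide):
        for r in regions:
            vol[z] |= r.mask
    labels, n = ndimage.label(vol, structure=np.ones((3, 3, 3), dtype=bool))
    nuclei: dict[int, NucleusRegion] = {}
    boundaries: dict[int, list[np.ndarray]] = {}
    for lab in range(1, n + 1):
        nuclei[lab] = NucleusRegion(label=lab, mask=labels == lab, boundary=np.empty((0, 3), int))
        boundaries[lab] = []
    for z, regions in enumerate(per_slide):
        for r in regions:
            yy, xx = np.nonzero(r.mask)
            lab = int(labels[z, yy[0], xx[0]])
            nuclei[lab].per_slide_areas[z] = nuclei[lab].per_slide_areas.get(z, 0) + int(
                r.mask.sum()
            )
            if len(r.boundary):
                b3 = np.column_stack(
                    [np.full(len(r.boundary), z), r.boundary[:, 0], r.boundary[:, 1]]
                )
                boundaries[lab].append(b3)
    for lab, chunks in boundaries.items():
        if chunks:
            nuclei[lab].boundary = np.unique(np.vstack(chunks), axis=0)
    return [nuclei[lab] for lab in sorted(nuclei)]


def segment_nuclei(
    dapi: np.ndarray,
    cutoff: float = DAPI_CUTOFF,
    top_k: int = TOP_K_COMPONENTS,
    min_px: int = MIN_NUCLEUS_PX,
    min_shape: float = MIN_CIRCULARITY,
    dilations: int = REFINE_DILATIONS,
) -> list[NucleusRegion]:
    """Full slide-by-slide segmentation of a 3D DAPI channel into nuclei."""
    per_slide: list[list[SlideRegion]] = []
    for z in range(dapi.shape[0]):
        accepted: list[SlideRegion] = []
        mask = threshold_dapi(dapi[z], cutoff)
        n_on = int(mask.sum())
        comps = candidate_components(mask, top_k)
        for comp in comps:
            refined = refine_region(comp, dilations)
            if accept_nucleus(refined, min_px, min_shape):
                accepted.append(
                    SlideRegion(z=z, mask=refined, boundary=extract_boundary(refined))
                )
        logger.debug(
            "slide %d: %d ON px, %d components, %d accepted",
            z, n_on, len(comps), len(accepted),
        )
        per_slide.append(accepted)
    nuclei = stack_nuclei(per_slide)
    logger.info("segmented %d nuclei from %d slides", len(nuclei), dapi.shape[0])
    return nuclei
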