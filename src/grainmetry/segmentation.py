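"""Grain/background segmentation and region extraction.

Grains are photographed as dark objects on a lit white panel, so the
brightness (HSB "B") channel is thresholded and the *darker* side is
taken as foreground.  The default automatic threshold is the iterative
intermeans (IsoData) method: starting from the overall mean intensity,
the threshold is repeatedly replaced by the midpoint of the mean
intensities of the two classes it induces, until it stabilises.

Each maximal connected foreground component becomes one
:class:`GrainRegion` carrying its pixel set and its outer boundary,
traced clockwise through pixel centres with the Moore neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ParameterError
from .raster_io import RasterImage

__all__ = [
    "GrainRegion",
    "isodata_intermeans",
    "hsb_threshold",
    "fill_holes",
    "label_components",
    "trace_boundary",
    "segment_image",
]


@dataclass
class GrainRegion:
    """One segmented grain.

    ``pixel_coords`` is an ``(n, 2)`` integer array of (row, col) pixels;
    ``boundary`` is the ordered outer-boundary polygon through pixel
    centres (clockwise, first vertex = top-left boundary pixel), without
    a repeated closing vertex; ``bbox`` is (row_min, col_min, row_max,
    col_max), inclusive.
    """

    label: int
    pixel_coords: np.ndarray
    boundary: np.ndarray
    bbox: tuple[int, int, int, int]

    @property
    def area(self) -> int:
        return len(self.pixel_coords)

    def local_mask(self) -> np.ndarray:
        r0, c0, r1, c1 = self.bbox
        m = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
        m[self.pixel_coords[:, 0] - r0, self.pixel_coords[:, 1] - c0] = True
        return m


def isodata_intermeans(histogram: np.ndarray) -> float:
    """Iterative-intermeans (IsoData) threshold of a 256-bin histogram.

    Returns the converged threshold ``t``; foreground is the class of
    values ``<= t``.  For a histogram with a single occupied bin there is
    no darker class and ``min - 1`` is returned (empty foreground).
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.shape != (256,):
        raise ParameterError("histogram must have 256 bins")
    levels = np.arange(256, dtype=float)
    occupied = np.nonzero(hist)[0]
    if occupied.size == 0:
        return -1.0
    if occupied.size == 1:
        return float(occupied[0]) - 1.0
    t = float((hist * levels).sum() / hist.sum())
    for _ in range(256):
        low = levels <= t
        w_low = hist[low].sum()
        w_high = hist[~low].sum()
        if w_low == 0:
            t = float(occupied[0])
            continue
        if w_high == 0:
            t = float(occupied[-1]) - 1.0
            continue
        m_low = (hist[low] * levels[low]).sum() / w_low
        m_high = (hist[~low] * levels[~low]).sum() / w_high
        t_new = (m_low + m_high) / 2.0
        if t_new == t:
            break
        t = t_new
    return t


def hsb_threshold(
    image: RasterImage, method: str = "default-isodata", invert: bool = False
) -> np.ndarray:
    """Threshold the HSB brightness channel; return a boolean mask.

    ``method`` is one of ``"default-isodata"`` (iterative intermeans),
    ``"otsu"``, or ``"fixed:<0..255>"``.  Foreground is the side darker
    than the threshold (grains on a lit white panel); ``invert=True``
    selects the brighter side instead.
    """
    b = image.brightness()
    if method == "default-isodata":
        hist = np.bincount(b.ravel(), minlength=256).astype(float)
        t = isodata_intermeans(hist)
    elif method == "otsu":
        if b.min() == b.max():
            t = float(b.min()) - 1.0
        else:
            t = float(threshold_otsu(b))
    elif method.startswith("fixed:"):
        try:
            t = float(method.split(":", 1)[1])
        except ValueError as exc:
            raise ParameterError(f"bad fixed threshold in {method!r}") from exc
        if not 0 <= t <= 255:
            raise ParameterError(f"fixed threshold must be in [0, 255], got {t}")
    else:
        raise ParameterError(
            f"unknown threshold method {method!r}; "
            "expected 'default-isodata', 'otsu', or 'fixed:<0..255>'"
        )
    mask = b > t if invert else b <= t
    return mask


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill interior holes (e.g. specular highlights inside a grain)."""
    return ndimage.binary_fill_holes(mask)


_STRUCT = {4: ndimage.generate_binary_structure(2, 1), 8: np.ones((3, 3), bool)}


def label_components(mask: np.ndarray, connectivity: int = 8) -> list[GrainRegion]:
    """Split a mask into connected regions, labelled 1..N in raster order.

    Labels follow the raster-scan order of each component's first pixel.
    No size or circularity filtering is applied.  An empty mask yields an
    empty list.
    """
    if connectivity not in _STRUCT:
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    lab, n = ndimage.label(mask, structure=_STRUCT[connectivity])
    if n == 0:
        return []
    slices = ndimage.find_objects(lab)
    # raster-scan order of the first pixel of each component
    first_index = np.full(n + 1, np.iinfo(np.int64).max, dtype=np.int64)
    flat = lab.ravel()
    nz = np.nonzero(flat)[0]
    np.minimum.at(first_index, flat[nz], nz)
    order = np.argsort(first_index[1:], kind="stable")
    regions: list[GrainRegion] = []
    for new_label, old_idx in enumerate(order, start=1):
        sl = slices[old_idx]
        local = lab[sl] == old_idx + 1
        rr, cc = np.nonzero(local)
        r0, c0 = sl[0].start, sl[1].start
        coords = np.column_stack([rr + r0, cc + c0])
        contour = _moore_trace(local)
        contour = contour + np.array([r0, c0])
        bbox = (r0, c0, sl[0].stop - 1, sl[1].stop - 1)
        regions.append(GrainRegion(new_label, coords, contour, bbox))
    return regions


def trace_boundary(region: GrainRegion) -> np.ndarray:
    """Ordered outer-boundary polygon of a region through pixel centres.

    Moore boundary tracing, clockwise in image coordinates, starting at
    the top-left (first in raster scan) boundary pixel.  A single-pixel
    region gives the degenerate one-point polygon.
    """
    r0, c0 = region.bbox[0], region.bbox[1]
    return _moore_trace(region.local_mask()) + np.array([r0, c0])


# clockwise Moore neighbourhood (image coordinates, row increases down),
# starting from W: W, NW, N, NE, E, SE, S, SW
_CW = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))
_DIR_INDEX = {d: i for i, d in enumerate(_CW)}


def _moore_trace(mask: np.ndarray) -> np.ndarray:
    """Moore boundary trace of the first (raster-order) component in mask."""
    padded = np.pad(mask, 1).astype(np.uint8)
    flat = np.flatnonzero(padded.ravel())
    if flat.size == 0:
        raise ParameterError("cannot trace an empty mask")
    w = padded.shape[1]
    r, c = int(flat[0]) // w, int(flat[0]) % w
    start = (r, c)
    contour = [start]
    b_idx = 0  # backtrack direction index (W): raster-first pixel has bg to its W
    cur = start
    first_edge = None
    grid = padded
    while True:
        found = None
        for k in range(1, 9):
            j = (b_idx + k) % 8
            dr, dc = _CW[j]
            nr, nc = cur[0] + dr, cur[1] + dc
            if grid[nr, nc]:
                found = ((nr, nc), j, (b_idx + k - 1) % 8)
                break
        if found is None:  # isolated single pixel
            break
        nxt, j, prev_j = found
        edge = (cur, nxt)
        if first_edge is None:
            first_edge = edge
        elif edge == first_edge:
            contour.pop()  # drop the re-appended start vertex
            break
        contour.append(nxt)
        # new backtrack = last background neighbour scanned, relative to nxt
        bg = (cur[0] + _CW[prev_j][0], cur[1] + _CW[prev_j][1])
        b_idx = _DIR_INDEX[(bg[0] - nxt[0], bg[1] - nxt[1])]
        cur = nxt
        if len(contour) > 8 * mask.size:  # safety net; cannot trigger on valid input
            raise RuntimeError("boundary trace failed to close")
    return np.asarray(contour, dtype=np.int64) - 1  # un-pad


def exclude_edge_regions(
    regions: list[GrainRegion], shape: tuple[int, int]
) -> list[GrainRegion]:
    """Drop regions whose bounding box touches the image border."""
    h, w = shape
    kept = [
        reg
        for reg in regions
        if reg.bbox[0] > 0 and reg.bbox[1] > 0 and reg.bbox[2] < h - 1 and reg.bbox[3] < w - 1
    ]
    for i, reg in enumerate(kept, start=1):
        reg.label = i
    return kept


def segment_image(
    image: RasterImage,
    method: str = "default-isodata",
    invert: bool = False,
    holes_filled: bool = True,
    exclude_edges: bool = False,
    connectivity: int = 8,
) -> tuple[np.ndarray, list[GrainRegion]]:
    """Threshold, optionally fill holes, and label grain regions.

    Returns ``(mask, regions)``.  Hole filling is on by default: grains
    are solid objects and an interior specular highlight would corrupt
    area and solidity.
    """
    mask = hsb_threshold(image, method=method, invert=invert)
    if holes_filled:
        mask = fill_holes(mask)
    regions = label_components(mask, connectivity=connectivity)
    if exclude_edges:
        regions = exclude_edge_regions(regions, mask.shape)
    return mask, regions
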