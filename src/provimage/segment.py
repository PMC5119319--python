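"""Segmentations as first-class objects, plus the two segmentation algorithms
used by the cell-segmentation pipeline.

A :class:`SegmentedImage` is a 2D array of non-negative integer labels in
which 0 is background and every distinct positive integer is one segment.
Individual segments are accessed as :class:`Region` objects — boolean masks
with derived morphology (area, perimeter, border, inner, convex hull,
centroid) computed on the fly.

``connected_components`` and ``watershed_with_seeds`` are decorated
transformations: applying them appends to the image history and writes a
false-colour audit PNG like any other pipeline step.
"""

from __future__ import annotations

import io
from typing import List, Optional

import numpy as np
import scipy.ndimage as ndi
import skimage.measure
import skimage.segmentation
from PIL import Image as _PILImage

from .color import pretty_color_from_identifier
from .image import History, Image
from .transform import CROSS, transformation

__all__ = [
    "SegmentedImage",
    "Region",
    "connected_components",
    "watershed_with_seeds",
    "false_colour",
    "false_colour_png",
]


def _on_segment(points: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Which points lie on the segment spanned by a (near-)collinear set."""
    # order the member points along their principal direction
    direction = coords[np.argmax(np.abs(coords - coords[0]).sum(axis=1))] - coords[0]
    norm = np.linalg.norm(direction)
    if norm == 0:  # single distinct point
        return (np.abs(points - coords[0]).sum(axis=1) < 1e-9)
    direction = direction / norm
    proj = (coords - coords[0]) @ direction
    lo, hi = proj.min(), proj.max()
    p_proj = (points - coords[0]) @ direction
    perp = points - coords[0] - np.outer(p_proj, direction)
    return (
        (np.linalg.norm(perp, axis=1) < 1e-9)
        & (p_proj >= lo - 1e-9)
        & (p_proj <= hi + 1e-9)
    )


class Region(np.ndarray):
    """Boolean mask of one segment, with morphology derived on demand.

    All derived properties are pure functions of the mask.  The structuring
    element for ``inner``/``border``/``dilate`` is the same 3x3 cross used by
    the binary transforms, so chains such as ``region.inner.border.dilate()``
    are internally consistent.
    """

    def __new__(cls, mask):
        return np.asarray(mask, dtype=bool).view(cls)

    def __array_wrap__(self, out_arr, context=None, return_scalar=False):
        arr = np.asarray(out_arr)
        if return_scalar and arr.ndim == 0:
            return arr[()]
        return arr

    @property
    def area(self) -> int:
        """Number of member pixels."""
        return int(np.count_nonzero(self))

    @property
    def inner(self) -> "Region":
        """Erosion of the mask by the 3x3 cross."""
        return Region(ndi.binary_erosion(np.asarray(self), structure=CROSS,
                                         border_value=0))

    @property
    def border(self) -> "Region":
        """The 1-pixel-thick inner boundary: mask AND NOT inner."""
        return Region(np.asarray(self) & ~np.asarray(self.inner))

    @property
    def perimeter(self) -> int:
        """Number of border pixels."""
        return self.border.area

    @property
    def convex_hull(self) -> "Region":
        """Filled convex hull of the member pixel centres, rasterised.

        A pixel belongs to the hull when its centre lies inside (or on the
        boundary of) the convex hull of the member pixel centres, so the
        hull is always a superset of the mask and the operation is
        idempotent.  Degenerate masks (a single pixel, collinear pixels)
        fill the lattice points on the spanning segment.
        """
        mask = np.asarray(self)
        coords = np.argwhere(mask).astype(float)
        if coords.shape[0] == 0:
            return Region(np.zeros_like(mask))
        rows, cols = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        centres = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
        span = coords - coords[0]
        if coords.shape[0] < 3 or np.linalg.matrix_rank(span, tol=1e-9) < 2:
            inside = _on_segment(centres, coords)
        else:
            from scipy.spatial import ConvexHull, QhullError

            try:
                hull = ConvexHull(coords)
            except QhullError:  # numerically collinear point set
                inside = _on_segment(centres, coords)
            else:
                # half-plane test of every pixel centre against the facets
                a = hull.equations[:, :2]
                b = hull.equations[:, 2]
                inside = np.all(centres @ a.T + b <= 1e-9, axis=1)
        return Region(inside.reshape(mask.shape))

    @property
    def centroid(self) -> tuple:
        """Mean (row, column) of member pixel coordinates."""
        coords = np.argwhere(np.asarray(self))
        if coords.shape[0] == 0:
            raise ValueError("centroid of an empty region is undefined")
        mean = coords.mean(axis=0)
        return (float(mean[0]), float(mean[1]))

    def dilate(self) -> "Region":
        """Dilation of the mask by the 3x3 cross, clipped at the image edge."""
        return Region(ndi.binary_dilation(np.asarray(self), structure=CROSS))


class SegmentedImage(Image):
    """2D label array; 0 is background, each positive integer one segment."""

    @classmethod
    def from_array(cls, labels, creation_note: str = "segmentation"):
        arr = np.asarray(labels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("labels must be a nonempty 2D array")
        if arr.dtype.kind not in "iub" or (arr.dtype.kind == "i" and arr.min() < 0):
            raise TypeError("labels must be non-negative integers")
        obj = arr.view(cls)
        obj.history = History(creation_note)
        return obj

    @property
    def identifiers(self) -> List[int]:
        """Sorted distinct positive label values present."""
        values = np.unique(np.asarray(self))
        return [int(v) for v in values if v > 0]

    def region_by_identifier(self, identifier: int) -> Region:
        identifier = int(identifier)
        if identifier not in self.identifiers:
            raise KeyError(
                "no segment with identifier {}; present: {}".format(
                    identifier, self.identifiers
                )
            )
        return Region(np.asarray(self) == identifier)

    def remove_region(self, identifier: int) -> None:
        """Set every pixel of the segment to background, in place."""
        identifier = int(identifier)
        if identifier not in self.identifiers:
            raise KeyError(
                "no segment with identifier {}; present: {}".format(
                    identifier, self.identifiers
                )
            )
        np.asarray(self)[np.asarray(self) == identifier] = 0

    def false_colour(self) -> np.ndarray:
        return false_colour(self)

    def png(self) -> bytes:
        """False-colour PNG: background black, each segment its pretty colour."""
        return false_colour_png(self)


def false_colour(seg) -> np.ndarray:
    """RGB uint8 array: background (0,0,0), segment i its deterministic colour."""
    labels = np.asarray(seg)
    rgb = np.zeros(labels.shape + (3,), dtype=np.uint8)
    for i in np.unique(labels):
        if i <= 0:
            continue
        rgb[labels == i] = pretty_color_from_identifier(int(i))
    return rgb


def false_colour_png(seg) -> bytes:
    buf = io.BytesIO()
    _PILImage.fromarray(false_colour(seg), mode="RGB").save(buf, format="PNG")
    return buf.getvalue()


@transformation
def connected_components(image, background=0):
    """Label maximal 8-connected groups of equal-valued pixels.

    Pixels equal to ``background`` map to 0; each remaining component
    receives a distinct consecutive positive label 1..K, assigned in raster
    order of the component's first pixel.
    """
    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
        background = int(bool(background))
    labels = skimage.measure.label(arr, background=background, connectivity=2)
    return SegmentedImage.from_array(labels)


@transformation
def watershed_with_seeds(landscape, seeds, mask=None):
    """Priority-flood watershed growing basins from seed labels.

    Basins grow from the seeds in order of ascending landscape value, ties
    broken by flooding (insertion) order, so the output is deterministic.
    Every pixel receives exactly one seed's label — there are no watershed
    lines — except where ``mask`` is False, which stays background.
    """
    land = np.asarray(landscape)
    seed_arr = np.asarray(seeds)
    if land.shape != seed_arr.shape:
        raise ValueError(
            "landscape shape {} and seeds shape {} differ".format(
                land.shape, seed_arr.shape
            )
        )
    if not (seed_arr > 0).any():
        raise ValueError("seeds must contain at least one segment")
    mask_arr: Optional[np.ndarray] = None
    if mask is not None:
        mask_arr = np.asarray(mask)
        if mask_arr.shape != land.shape:
            raise ValueError(
                "mask shape {} and landscape shape {} differ".format(
                    mask_arr.shape, land.shape
                )
            )
        mask_arr = mask_arr.astype(bool)
    labels = skimage.segmentation.watershed(
        land, markers=seed_arr.astype(np.int64), mask=mask_arr, connectivity=1
    )
    return SegmentedImage.from_array(labels)
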