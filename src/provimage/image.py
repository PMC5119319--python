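"""Provenance-carrying 2D images and 3D stacks.

The central object is :class:`Image`, a thin :class:`numpy.ndarray` subclass
that carries a :class:`History`: a creation record naming where the pixels
came from plus an ordered list of :class:`Event` entries, one per decorated
transformation applied to the lineage (see :mod:`provimage.transform`).

Provenance flows *only* through decorated transformations.  Raw numpy
operations on an ``Image`` (negation, comparison, slicing arithmetic)
deliberately return plain ``ndarray`` objects, so an expression such as
``image > cutoff`` inside a transformation body is an ordinary array and the
decorator alone decides whose history the result inherits.
"""

from __future__ import annotations

import io
import os
from typing import Iterable, Iterator, List, Sequence

import numpy as np
import tifffile
from PIL import Image as _PILImage

__all__ = [
    "Event",
    "History",
    "Image",
    "Stack3D",
    "image_from_array",
    "image_from_file",
    "encode_png",
    "stack_from_slices",
]

#: dtype kinds an Image may hold: boolean, unsigned 8/16-bit, floating point.
_SUPPORTED_DTYPES = (
    np.dtype(bool),
    np.dtype(np.uint8),
    np.dtype(np.uint16),
    np.dtype(np.float16),
    np.dtype(np.float32),
    np.dtype(np.float64),
)


class Event:
    """One transformation applied to an image lineage.

    Stringifies in call style, image-valued arguments rendered as the
    literal token ``image``, e.g. ``threshold_abs(image, 50)``.
    """

    def __init__(self, function_name: str, argument_rendering: str) -> None:
        self.function_name = function_name
        self.argument_rendering = argument_rendering

    def __str__(self) -> str:
        return "{}({})".format(self.function_name, self.argument_rendering)

    def __repr__(self) -> str:
        return "<History.Event({})>".format(self)

    def __eq__(self, other: object) -> bool:
        return str(self) == str(other)

    def __hash__(self) -> int:
        return hash(str(self))


class History:
    """Creation record plus ordered, append-only list of events."""

    def __init__(self, creation: str | None = None) -> None:
        self.creation = creation
        self.events: List[Event] = []

    def add_event(self, event: Event) -> Event:
        self.events.append(event)
        return event

    def copy(self) -> "History":
        new = History(self.creation)
        new.events = list(self.events)
        return new

    def as_strings(self) -> List[str]:
        """History serialised as a plain list of strings."""
        strings = []
        if self.creation is not None:
            strings.append(self.creation)
        strings.extend(str(e) for e in self.events)
        return strings

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, History):
            return NotImplemented
        return self.as_strings() == other.as_strings()

    def __repr__(self) -> str:
        return "<History(creation={!r}, events={})>".format(
            self.creation, [str(e) for e in self.events]
        )


def _validate_pixels(values: np.ndarray) -> None:
    if values.ndim != 2:
        raise ValueError(
            "expected a 2D pixel array, got {} dimension(s)".format(values.ndim)
        )
    if values.size == 0:
        raise ValueError("pixel array must have positive extents")


def _validate_dtype(values: np.ndarray) -> None:
    if values.dtype not in _SUPPORTED_DTYPES:
        raise TypeError(
            "unsupported pixel dtype {}; expected one of bool, uint8, uint16 "
            "or floating point".format(values.dtype)
        )


class Image(np.ndarray):
    """2D pixel array with an attached provenance :class:`History`."""

    def __new__(cls, shape, dtype=np.uint8):
        obj = np.zeros(shape, dtype=dtype).view(cls)
        obj.history = History()
        return obj

    def __array_finalize__(self, obj) -> None:
        if not hasattr(self, "history"):
            self.history = History()

    def __array_wrap__(self, out_arr, context=None, return_scalar=False):
        # Provenance only flows through decorated transformations; ufunc
        # results (image > cutoff, -image, ...) are plain arrays.
        arr = np.asarray(out_arr)
        if return_scalar and arr.ndim == 0:
            return arr[()]
        return arr

    @classmethod
    def from_array(cls, values, creation_note: str) -> "Image":
        """Wrap a 2D array as an Image with a fresh creation record.

        The array is shared, not copied, and the dtype is preserved.
        """
        arr = np.asarray(values)
        _validate_pixels(arr)
        _validate_dtype(arr)
        obj = arr.view(cls)
        obj.history = History(creation_note)
        return obj

    @classmethod
    def from_file(cls, path) -> "Image":
        """Read a single grayscale TIFF or PNG slice from disk."""
        path = os.fspath(path)
        if not os.path.isfile(path):
            raise FileNotFoundError("no such image file: {}".format(path))
        ext = os.path.splitext(path)[1].lower()
        if ext in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            with _PILImage.open(path) as im:
                if im.mode not in ("L", "I;16", "I", "1"):
                    raise ValueError(
                        "unsupported image content in {}: mode {} is not "
                        "single-channel grayscale".format(path, im.mode)
                    )
                arr = np.asarray(im)
        if arr.ndim != 2:
            raise ValueError(
                "unsupported image content in {}: expected a single 2D "
                "grayscale page, got shape {}".format(path, arr.shape)
            )
        return cls.from_array(
            arr, "Created Image from {}".format(os.path.abspath(path))
        )

    def png(self) -> bytes:
        """PNG byte string of the image (8-bit grayscale)."""
        return encode_png(self)

    def _repr_png_(self) -> bytes:
        return self.png()


class Stack3D(np.ndarray):
    """3D voxel array ordered (z, row, column), with a History."""

    def __new__(cls, shape, dtype=np.uint8):
        obj = np.zeros(shape, dtype=dtype).view(cls)
        obj.history = History()
        return obj

    def __array_finalize__(self, obj) -> None:
        if not hasattr(self, "history"):
            self.history = History()

    def __array_wrap__(self, out_arr, context=None, return_scalar=False):
        arr = np.asarray(out_arr)
        if return_scalar and arr.ndim == 0:
            return arr[()]
        return arr


def _to_uint8(pixels: np.ndarray) -> np.ndarray:
    """Map pixels to the 8-bit display range.

    Booleans map False->0, True->255; uint8 passes through unchanged; other
    dtypes are min-max rescaled so min->0 and max->255 (a constant image maps
    to all zeros).  Mid-range values round half-to-even (0.5 of a unit-range
    float image becomes 128).
    """
    if pixels.dtype == bool:
        return np.where(pixels, np.uint8(255), np.uint8(0))
    if pixels.dtype == np.uint8:
        return np.asarray(pixels)
    lo = float(pixels.min())
    hi = float(pixels.max())
    if hi == lo:
        return np.zeros(pixels.shape, dtype=np.uint8)
    scaled = (pixels.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.round(scaled).astype(np.uint8)


def encode_png(image) -> bytes:
    """Encode a 2D image as an 8-bit grayscale PNG byte string."""
    arr = np.asarray(image)
    _validate_pixels(arr)
    buf = io.BytesIO()
    _PILImage.fromarray(_to_uint8(arr), mode="L").save(buf, format="PNG")
    return buf.getvalue()


def image_from_array(values, creation_note: str) -> Image:
    """Functional alias for :meth:`Image.from_array`."""
    return Image.from_array(values, creation_note)


def image_from_file(path) -> Image:
    """Functional alias for :meth:`Image.from_file`."""
    return Image.from_file(path)


def stack_from_slices(slices: Sequence[Image]) -> Stack3D:
    """Assemble ordered 2D slices into a (z, row, column) stack.

    All slices must share shape and dtype; the stack's creation record lists
    the source slices in order.
    """
    slices = list(slices)
    if not slices:
        raise ValueError("cannot build a stack from an empty slice list")
    first = np.asarray(slices[0])
    for k, sl in enumerate(slices):
        arr = np.asarray(sl)
        if arr.shape != first.shape or arr.dtype != first.dtype:
            raise ValueError(
                "slice {} has shape {} dtype {}, expected shape {} dtype {}"
                .format(k, arr.shape, arr.dtype, first.shape, first.dtype)
            )
    voxels = np.stack([np.asarray(s) for s in slices], axis=0)
    stack = voxels.view(Stack3D)
    sources = []
    for k, sl in enumerate(slices):
        creation = getattr(getattr(sl, "history", None), "creation", None)
        sources.append(creation if creation is not None else "slice {}".format(k))
    stack.history = History(
        "Created Stack3D from {} slices: {}".format(len(slices), "; ".join(sources))
    )
    return stack
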