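"""The transformation decorator and the built-in binary-image transforms.

``@transformation`` turns any image -> image function into an audited step:
the returned array is coerced to an :class:`~provimage.image.Image`, the
history of the first Image-typed argument is copied and extended with an
:class:`~provimage.image.Event` rendering the call, and (while auditing is
enabled) the result is written to ``{counter}_{function_name}.png`` in the
audit directory.  One module-global :data:`AUDIT` configuration is shared by
every decorated function so that a pipeline produces one continuous
numbering of audit images.
"""

from __future__ import annotations

import functools
import itertools
import logging
import os
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
import skimage.morphology

from .image import Event, History, Image

__all__ = [
    "AuditConfig",
    "AUDIT",
    "transformation",
    "threshold_abs",
    "invert",
    "dilate_binary",
    "erode_binary",
    "remove_small_objects",
    "negate",
    "CROSS",
]

logger = logging.getLogger(__name__)

#: 3x3 cross (4-connected) structuring element shared by all morphology here
#: and by Region.inner/border/dilate, so chains like inner.border.dilate()
#: are internally consistent.
CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class AuditConfig:
    """Where (and whether) decorated transforms write their audit PNGs."""

    def __init__(self, enabled: bool = True, directory=None) -> None:
        self.enabled = enabled
        self.directory = Path(directory) if directory is not None else Path(".")
        self.counter = 1

    def reset(self, directory=None, enabled: bool | None = None) -> None:
        """Reset the counter to 1, optionally retargeting the directory."""
        self.counter = 1
        if directory is not None:
            self.directory = Path(directory)
        if enabled is not None:
            self.enabled = enabled


#: Global audit configuration shared by all decorated functions.
AUDIT = AuditConfig()


def _render_value(value) -> str:
    if isinstance(value, np.ndarray):
        return "image"
    return repr(value)


def _render_call(args, kwargs) -> str:
    parts = [_render_value(a) for a in args]
    parts.extend("{}={}".format(k, _render_value(v)) for k, v in kwargs.items())
    return ", ".join(parts)


def transformation(func):
    """Decorate an image -> image function with history and audit output.

    The first Image-typed argument (positional first, then keyword, in call
    order) donates its history; called with only bare arrays, the result
    starts a fresh history created by the function itself.
    """

    @functools.wraps(func)
    def wrapper(*args, **kwargs):
        donor = next(
            (
                a
                for a in itertools.chain(args, kwargs.values())
                if isinstance(a, Image)
            ),
            None,
        )
        result = func(*args, **kwargs)
        arr = np.asarray(result)
        if arr.ndim != 2:
            raise ValueError(
                "transformation {} returned a {}-dimensional result; "
                "transformations must return a 2D image".format(
                    func.__name__, arr.ndim
                )
            )
        if not isinstance(result, Image):
            result = arr.view(Image)
        if donor is not None:
            history = donor.history.copy()
        else:
            history = History("created by {}".format(func.__name__))
        event = Event(func.__name__, _render_call(args, kwargs))
        history.add_event(event)
        result.history = history
        logger.info("%s", event)
        if AUDIT.enabled:
            fname = Path(AUDIT.directory) / "{}_{}.png".format(
                AUDIT.counter, func.__name__
            )
            os.makedirs(fname.parent, exist_ok=True)
            with open(fname, "wb") as fh:
                fh.write(result.png())
            AUDIT.counter += 1
        return result

    return wrapper


def _require_binary(image, name: str) -> np.ndarray:
    arr = np.asarray(image)
    if arr.dtype != bool:
        raise TypeError(
            "{} expects a boolean image, got dtype {}".format(name, arr.dtype)
        )
    return arr


@transformation
def threshold_abs(image, cutoff):
    """Binary image: True exactly where the pixel value is strictly > cutoff."""
    return np.asarray(image) > cutoff


@transformation
def invert(image):
    """Elementwise logical negation of a binary image."""
    return np.logical_not(_require_binary(image, "invert"))


@transformation
def dilate_binary(image):
    """Morphological dilation by a 3x3 cross; the border is padded False."""
    return ndi.binary_dilation(_require_binary(image, "dilate_binary"), structure=CROSS)


@transformation
def erode_binary(image):
    """Morphological erosion by a 3x3 cross; the border is padded False."""
    return ndi.binary_erosion(
        _require_binary(image, "erode_binary"), structure=CROSS, border_value=0
    )


@transformation
def remove_small_objects(image, min_size):
    """Drop 8-connected True components with area < min_size.

    Components of area >= min_size are retained unchanged.
    """
    arr = _require_binary(image, "remove_small_objects")
    if min_size < 1:
        raise ValueError("min_size must be >= 1, got {}".format(min_size))
    return skimage.morphology.remove_small_objects(
        arr, max_size=min_size - 1, connectivity=2
    )


def negate(image) -> np.ndarray:
    """Negated copy of an intensity landscape, safe for unsigned dtypes.

    Unsigned integer pixels are promoted to a signed type first, so
    ``negate(cellwall)`` is the well-defined analogue of ``-cellwall``
    without modular-arithmetic underflow.  Returns a plain array: negation
    is landscape preparation, not an audited transformation.
    """
    arr = np.asarray(image)
    if arr.dtype.kind == "u":
        arr = arr.astype(np.promote_types(arr.dtype, np.int8))
    return -arr
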