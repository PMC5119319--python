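"""RGB annotation canvases over grayscale backgrounds.

An :class:`AnnotatedImage` is an 8-bit RGB canvas the same spatial shape as
its source image.  Drawing operations (region masking, crosses, bitmap-font
text) set exactly the pixels their contract names and clip silently at the
canvas edge, so annotating near a border never raises.  All rendering is
deterministic: the palette comes from
:func:`~provimage.color.pretty_color_from_identifier` and text uses the
embedded 5x7 bitmap font.
"""

from __future__ import annotations

import io
import logging
import math

import numpy as np
from PIL import Image as _PILImage

from . import _font
from .color import Color, pretty_color_from_identifier

__all__ = [
    "AnnotatedImage",
    "Color",
    "pretty_color_from_identifier",
    "from_grayscale",
    "mask_region",
    "draw_cross",
    "text_at",
    "annotation_png",
]

logger = logging.getLogger(__name__)


def _rescale_to_uint8(pixels: np.ndarray) -> np.ndarray:
    lo = float(pixels.min())
    hi = float(pixels.max())
    if hi == lo:
        return np.zeros(pixels.shape, dtype=np.uint8)
    scaled = (pixels.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.round(scaled).astype(np.uint8)


class AnnotatedImage(np.ndarray):
    """(rows, cols, 3) uint8 canvas with drawing convenience methods."""

    def __new__(cls, canvas):
        arr = np.ascontiguousarray(canvas, dtype=np.uint8)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(
                "canvas must have shape (rows, cols, 3), got {}".format(arr.shape)
            )
        return arr.view(cls)

    @classmethod
    def from_grayscale(cls, image) -> "AnnotatedImage":
        """Canvas with r=g=b = input min-max rescaled to [0, 255]."""
        arr = np.asarray(image)
        if arr.ndim != 2:
            raise ValueError("expected a 2D grayscale image")
        gray = _rescale_to_uint8(arr)
        return cls(np.repeat(gray[:, :, None], 3, axis=2))

    def mask_region(self, region, color) -> None:
        """Set every pixel where the region mask is True to ``color``."""
        mask = np.asarray(region, dtype=bool)
        if mask.shape != self.shape[:2]:
            raise ValueError(
                "region shape {} does not match canvas shape {}".format(
                    mask.shape, self.shape[:2]
                )
            )
        np.asarray(self)[mask] = tuple(color)

    def draw_cross(self, position, color, radius: int = 2) -> None:
        """Draw a plus-shaped cross centred at (row, col), clipped at edges."""
        row = int(math.floor(position[0]))
        col = int(math.floor(position[1]))
        rows, cols = self.shape[:2]
        base = np.asarray(self)
        for d in range(-radius, radius + 1):
            if 0 <= row + d < rows and 0 <= col < cols:
                base[row + d, col] = tuple(color)
            if 0 <= row < rows and 0 <= col + d < cols:
                base[row, col + d] = tuple(color)

    def text_at(self, text, position, color=(255, 255, 255), center: bool = False) -> None:
        """Draw text with the embedded 5x7 font; glyph pixels get ``color``.

        With ``center=True`` the text's bounding box is centred on
        ``position`` (offsets rounded toward negative infinity); otherwise
        the bounding box's top-left corner is anchored there.  Unsupported
        characters render as a hollow box with a logged warning.
        """
        mask, unsupported = _font.text_mask(str(text))
        if unsupported:
            logger.warning(
                "unsupported characters %r rendered as boxes", "".join(unsupported)
            )
        if mask.shape[1] == 0:
            return
        height, width = mask.shape
        if center:
            top = math.floor(position[0] - (height - 1) / 2)
            left = math.floor(position[1] - (width - 1) / 2)
        else:
            top = math.floor(position[0])
            left = math.floor(position[1])
        rows, cols = self.shape[:2]
        r0, r1 = max(top, 0), min(top + height, rows)
        c0, c1 = max(left, 0), min(left + width, cols)
        if r0 >= r1 or c0 >= c1:
            return
        sub = mask[r0 - top : r1 - top, c0 - left : c1 - left]
        np.asarray(self)[r0:r1, c0:c1][sub] = tuple(color)

    def png(self) -> bytes:
        """8-bit RGB PNG byte string of the canvas."""
        buf = io.BytesIO()
        _PILImage.fromarray(np.asarray(self), mode="RGB").save(buf, format="PNG")
        return buf.getvalue()

    def _repr_png_(self) -> bytes:
        return self.png()


def from_grayscale(image) -> AnnotatedImage:
    return AnnotatedImage.from_grayscale(image)


def mask_region(canvas: AnnotatedImage, region, color) -> None:
    canvas.mask_region(region, color)


def draw_cross(canvas: AnnotatedImage, position, color, radius: int = 2) -> None:
    canvas.draw_cross(position, color, radius)


def text_at(canvas: AnnotatedImage, text, position, color=(255, 255, 255),
            center: bool = False) -> None:
    canvas.text_at(text, position, color, center)


def annotation_png(canvas: AnnotatedImage) -> bytes:
    return canvas.png()
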