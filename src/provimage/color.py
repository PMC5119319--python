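"""Deterministic "pretty" colours for segment identifiers.

A fixed linear congruential generator keeps the palette identical across
platforms, processes and library versions — false-colour images of the same
segmentation are byte-identical everywhere.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = ["Color", "pretty_color_from_identifier"]

_LCG_MULTIPLIER = 1664525
_LCG_INCREMENT = 1013904223
_LCG_MODULUS = 2**32


class Color(NamedTuple):
    """8-bit RGB colour."""

    r: int
    g: int
    b: int


def pretty_color_from_identifier(identifier: int) -> Color:
    """Deterministic colour for a positive segment identifier.

    The identifier seeds an LCG (modulus 2^32, multiplier 1664525, increment
    1013904223); three draws are mapped into [63, 255] via ``v % 193 + 63``
    so every segment stays visible against a black background.  The same
    identifier yields the same colour on every platform.
    """
    identifier = int(identifier)
    if identifier < 1:
        raise ValueError(
            "segment identifiers are positive integers, got {}".format(identifier)
        )
    state = identifier % _LCG_MODULUS
    channels = []
    for _ in range(3):
        state = (_LCG_MULTIPLIER * state + _LCG_INCREMENT) % _LCG_MODULUS
        channels.append(state % 193 + 63)
    return Color(*channels)
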