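"""Embedded 5x7 bitmap font for deterministic text annotation.

System font rendering differs between platforms and library builds, which
would break byte-for-byte reproducibility of annotated images; a tiny fixed
glyph table does not.  Glyphs cover digits, A-Z (lower case is rendered as
upper case) and space; any other character renders as a hollow box.
"""

from __future__ import annotations

import numpy as np

GLYPH_WIDTH = 5
GLYPH_HEIGHT = 7
GLYPH_GAP = 1

# Each glyph is 7 rows of 5 characters; "#" marks a set pixel.
_RAW = {
    "0": (" ### ", "#   #", "#  ##", "# # #", "##  #", "#   #", " ### "),
    "1": ("  #  ", " ##  ", "  #  ", "  #  ", "  #  ", "  #  ", " ### "),
    "2": (" ### ", "#   #", "    #", "   # ", "  #  ", " #   ", "#####"),
    "3": ("#####", "    #", "   # ", "  ## ", "    #", "#   #", " ### "),
    "4": ("   # ", "  ## ", " # # ", "#  # ", "#####", "   # ", "   # "),
    "5": ("#####", "#    ", "#### ", "    #", "    #", "#   #", " ### "),
    "6": ("  ## ", " #   ", "#    ", "#### ", "#   #", "#   #", " ### "),
    "7": ("#####", "    #", "   # ", "  #  ", " #   ", " #   ", " #   "),
    "8": (" ### ", "#   #", "#   #", " ### ", "#   #", "#   #", " ### "),
    "9": (" ### ", "#   #", "#   #", " ####", "    #", "   # ", " ##  "),
    "A": (" ### ", "#   #", "#   #", "#####", "#   #", "#   #", "#   #"),
    "B": ("#### ", "#   #", "#   #", "#### ", "#   #", "#   #", "#### "),
    "C": (" ### ", "#   #", "#    ", "#    ", "#    ", "#   #", " ### "),
    "D": ("###  ", "#  # ", "#   #", "#   #", "#   #", "#  # ", "###  "),
    "E": ("#####", "#    ", "#    ", "#### ", "#    ", "#    ", "#####"),
    "F": ("#####", "#    ", "#    ", "#### ", "#    ", "#    ", "#    "),
    "G": (" ### ", "#   #", "#    ", "# ###", "#   #", "#   #", " ####"),
    "H": ("#   #", "#   #", "#   #", "#####", "#   #", "#   #", "#   #"),
    "I": (" ### ", "  #  ", "  #  ", "  #  ", "  #  ", "  #  ", " ### "),
    "J": ("  ###", "   # ", "   # ", "   # ", "   # ", "#  # ", " ##  "),
    "K": ("#   #", "#  # ", "# #  ", "##   ", "# #  ", "#  # ", "#   #"),
    "L": ("#    ", "#    ", "#    ", "#    ", "#    ", "#    ", "#####"),
    "M": ("#   #", "## ##", "# # #", "# # #", "#   #", "#   #", "#   #"),
    "N": ("#   #", "##  #", "# # #", "#  ##", "#   #", "#   #", "#   #"),
    "O": (" ### ", "#   #", "#   #", "#   #", "#   #", "#   #", " ### "),
    "P": ("#### ", "#   #", "#   #", "#### ", "#    ", "#    ", "#    "),
    "Q": (" ### ", "#   #", "#   #", "#   #", "# # #", "#  # ", " ## #"),
    "R": ("#### ", "#   #", "#   #", "#### ", "# #  ", "#  # ", "#   #"),
    "S": (" ####", "#    ", "#    ", " ### ", "    #", "    #", "#### "),
    "T": ("#####", "  #  ", "  #  ", "  #  ", "  #  ", "  #  ", "  #  "),
    "U": ("#   #", "#   #", "#   #", "#   #", "#   #", "#   #", " ### "),
    "V": ("#   #", "#   #", "#   #", "#   #", "#   #", " # # ", "  #  "),
    "W": ("#   #", "#   #", "#   #", "# # #", "# # #", "## ##", "#   #"),
    "X": ("#   #", "#   #", " # # ", "  #  ", " # # ", "#   #", "#   #"),
    "Y": ("#   #", "#   #", " # # ", "  #  ", "  #  ", "  #  ", "  #  "),
    "Z": ("#####", "    #", "   # ", "  #  ", " #   ", "#    ", "#####"),
    "-": ("     ", "     ", "     ", "#####", "     ", "     ", "     "),
    ".": ("     ", "     ", "     ", "     ", "     ", " ##  ", " ##  "),
    " ": ("     ", "     ", "     ", "     ", "     ", "     ", "     "),
}

#: Hollow box drawn for unsupported characters.
BOX = ("#####", "#   #", "#   #", "#   #", "#   #", "#   #", "#####")


def _to_mask(rows) -> np.ndarray:
    return np.array([[ch == "#" for ch in row] for row in rows], dtype=bool)


GLYPHS = {char: _to_mask(rows) for char, rows in _RAW.items()}
BOX_GLYPH = _to_mask(BOX)


def glyph(char: str) -> np.ndarray:
    """Boolean 7x5 mask for one character; None when unsupported."""
    return GLYPHS.get(char.upper())


def text_mask(text: str):
    """Render a line of text as a boolean mask.

    Returns ``(mask, unsupported)`` where ``mask`` has shape
    ``(7, 6*len(text) - 1)`` (empty text gives a (7, 0) mask) and
    ``unsupported`` lists characters replaced by the hollow box glyph.
    """
    if not text:
        return np.zeros((GLYPH_HEIGHT, 0), dtype=bool), []
    width = len(text) * (GLYPH_WIDTH + GLYPH_GAP) - GLYPH_GAP
    mask = np.zeros((GLYPH_HEIGHT, width), dtype=bool)
    unsupported = []
    for k, char in enumerate(text):
        g = glyph(char)
        if g is None:
            g = BOX_GLYPH
            unsupported.append(char)
        left = k * (GLYPH_WIDTH + GLYPH_GAP)
        mask[:, left : left + GLYPH_WIDTH] = g
    return mask, unsupported
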