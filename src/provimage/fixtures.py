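"""Synthetic microscopy collections with known ground truth.

The generator emulates a confocal image of plant tissue in which cell walls
carry a bright membrane marker: a regular R x C grid of dark cell interiors
separated (and framed) by bright wall lines, lightly blurred and optionally
degraded with Gaussian noise.  A second channel holds one nuclear-marker
blob per cell at the cell's centroid.  Slices are written as 8-bit
grayscale TIFFs in the backend naming scheme ``S{s}_C{c}_Z{z}_T{t}.tif``,
so every other module — the data manager, the transforms, the segmentation
pipeline — can be exercised end to end without Bio-Formats or downloads.

The ground truth labels the R x C interiors 1..R*C in raster order, walls 0;
the generator is fully seeded, so a given spec yields a byte-identical
fixture every time.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import scipy.ndimage as ndi
import tifffile

from .datamanager import SliceCoordinate, format_slice_filename
from .image import Image
from .segment import SegmentedImage

__all__ = ["FixtureSpec", "generate_cell_grid", "generate_collection"]

#: nuclear channel is 0, cell-wall channel is 1, as in confocal two-channel
#: acquisitions with a nuclear and a membrane marker.
NUCLEI_CHANNEL = 0
CELL_WALL_CHANNEL = 1


@dataclasses.dataclass
class FixtureSpec:
    """Geometry, intensities and dimensions of a synthetic cell-grid fixture.

    Defaults describe a 4 x 5 grid of 32 px cells separated by 2 px walls
    (wall marker intensity 200 over interior 20, noise-free), imaged as two
    channels and three z-slices of a single series and timepoint.
    """

    rows: int = 4
    cols: int = 5
    cell_size: int = 32
    wall_width: int = 2
    wall_intensity: int = 200
    interior_intensity: int = 20
    noise_sd: float = 0.0
    zslices: int = 3
    channels: int = 2
    series: int = 1
    timepoints: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.wall_width < 1:
            raise ValueError("wall width must be at least 1 pixel")
        if self.cell_size < 2 * self.wall_width:
            raise ValueError(
                "cell size {} too small for wall width {}: interiors would "
                "blur away".format(self.cell_size, self.wall_width)
            )
        if not (0 <= self.interior_intensity < self.wall_intensity <= 255):
            raise ValueError("need 0 <= interior < wall intensity <= 255")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        for name in ("zslices", "channels", "series", "timepoints"):
            if getattr(self, name) < 1:
                raise ValueError("{} must be positive".format(name))

    @property
    def shape(self) -> Tuple[int, int]:
        pitch_r = self.cell_size + self.wall_width
        pitch_c = self.cell_size + self.wall_width
        return (
            self.rows * pitch_r + self.wall_width,
            self.cols * pitch_c + self.wall_width,
        )

    @property
    def interior_area(self) -> int:
        return self.cell_size**2

    @property
    def midpoint_intensity(self) -> float:
        return (self.wall_intensity + self.interior_intensity) / 2.0


def _wall_mask(spec: FixtureSpec) -> np.ndarray:
    shape = spec.shape
    mask = np.zeros(shape, dtype=bool)
    pitch = spec.cell_size + spec.wall_width
    for i in range(spec.rows + 1):
        mask[i * pitch : i * pitch + spec.wall_width, :] = True
    for j in range(spec.cols + 1):
        mask[:, j * pitch : j * pitch + spec.wall_width] = True
    return mask


def _truth_labels(spec: FixtureSpec) -> np.ndarray:
    labels = np.zeros(spec.shape, dtype=np.uint16)
    pitch = spec.cell_size + spec.wall_width
    for i in range(spec.rows):
        for j in range(spec.cols):
            r0 = i * pitch + spec.wall_width
            c0 = j * pitch + spec.wall_width
            labels[r0 : r0 + spec.cell_size, c0 : c0 + spec.cell_size] = (
                i * spec.cols + j + 1
            )
    return labels


def _render(base: np.ndarray, spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    # blur sigma is a quarter of the wall width (full +/- sigma width = wall/2)
    blurred = ndi.gaussian_filter(base.astype(np.float64), sigma=spec.wall_width / 4.0)
    if spec.noise_sd > 0:
        blurred = blurred + rng.normal(0.0, spec.noise_sd, size=blurred.shape)
    return np.clip(np.round(blurred), 0, 255).astype(np.uint8)


def generate_cell_grid(spec: FixtureSpec) -> Tuple[Image, SegmentedImage]:
    """Cell-wall channel image plus its ground-truth segmentation.

    Bright wall lines (wall intensity) over dark interiors, Gaussian blur of
    sigma wall_width/4, additive Gaussian noise from a generator seeded with
    ``spec.seed``, clipped to [0, 255].  The truth labels the interiors
    1..R*C in raster order and the walls 0.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = np.full(spec.shape, float(spec.interior_intensity))
    base[_wall_mask(spec)] = float(spec.wall_intensity)
    pixels = _render(base, spec, rng)
    image = Image.from_array(
        pixels,
        "synthetic cell grid ({}x{} cells, cell {} px, wall {} px, seed {})".format(
            spec.rows, spec.cols, spec.cell_size, spec.wall_width, spec.seed
        ),
    )
    truth = SegmentedImage.from_array(
        _truth_labels(spec), "synthetic cell grid ground truth"
    )
    return image, truth


def _nuclei_channel(spec: FixtureSpec, truth: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    base = np.full(spec.shape, 10.0)
    rows, cols = np.mgrid[0 : spec.shape[0], 0 : spec.shape[1]]
    sigma = max(spec.cell_size / 6.0, 1.0)
    for i in np.unique(truth):
        if i == 0:
            continue
        coords = np.argwhere(truth == i)
        cr, cc = coords.mean(axis=0)
        base += 180.0 * np.exp(
            -((rows - cr) ** 2 + (cols - cc) ** 2) / (2.0 * sigma**2)
        )
    if spec.noise_sd > 0:
        base = base + rng.normal(0.0, spec.noise_sd, size=base.shape)
    return np.clip(np.round(base), 0, 255).astype(np.uint8)


def generate_collection(spec: FixtureSpec, outdir) -> Dict:
    """Write a full synthetic collection of TIFF slices plus a JSON manifest.

    Channel 1 carries the cell-wall grid with a small z-dependent contrast
    modulation (signal falls off away from the middle focal plane); channel
    0 carries one Gaussian nuclear blob per ground-truth cell.  Returns the
    manifest (spec fields plus per-cell truth centroids and areas), which is
    also written to ``manifest.json`` in the output directory.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    truth = _truth_labels(spec)
    wall_base = np.full(spec.shape, float(spec.interior_intensity))
    wall_base[_wall_mask(spec)] = float(spec.wall_intensity)
    mid_z = (spec.zslices - 1) / 2.0

    slices = []
    for s in range(spec.series):
        for t in range(spec.timepoints):
            for c in range(spec.channels):
                for z in range(spec.zslices):
                    if c == CELL_WALL_CHANNEL or spec.channels == 1:
                        # contrast falls off 10% per normalised focal distance
                        falloff = 1.0 - 0.1 * (
                            abs(z - mid_z) / mid_z if mid_z > 0 else 0.0
                        )
                        base = spec.interior_intensity + falloff * (
                            wall_base - spec.interior_intensity
                        )
                        pixels = _render(base, spec, rng)
                    else:
                        pixels = _nuclei_channel(spec, truth, rng)
                    coord = SliceCoordinate(s, c, z, t)
                    name = format_slice_filename(coord)
                    tifffile.imwrite(outdir / name, pixels)
                    slices.append(name)

    centroids = {}
    areas = {}
    for i in np.unique(truth):
        if i == 0:
            continue
        coords = np.argwhere(truth == i)
        centroids[int(i)] = [float(v) for v in coords.mean(axis=0)]
        areas[int(i)] = int(coords.shape[0])
    manifest = {
        "spec": dataclasses.asdict(spec),
        "slices": slices,
        "cell_count": int(spec.rows * spec.cols),
        "truth_centroids": centroids,
        "truth_areas": areas,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
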