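"""Unpack multi-dimensional bioimage files into a content-addressed cache of
2D TIFF slices, and expose them as a :class:`MicroscopyCollection`.

A converter turns one input (a proprietary microscopy file, or — with the
built-in ``tifdir`` converter — a directory or zip archive of already-named
slices) into a set of grayscale TIFFs named ``S{s}_C{c}_Z{z}_T{t}.tif``
inside ``<backend root>/<md5 of the input bytes>/``.  Because the cache is
content-addressed, conversion happens exactly once per distinct input, no
matter how often or under what name it is loaded.

The native path wraps the external Bio-Formats ``bfconvert`` tool; every
test and the whole synthetic workflow run without it via ``tifdir``.
"""

from __future__ import annotations

import hashlib
import logging
import os
import re
import shutil
import subprocess
import zipfile
from pathlib import Path
from typing import Dict, NamedTuple

from .image import Image, Stack3D, image_from_file, stack_from_slices

__all__ = [
    "SliceCoordinate",
    "MicroscopyCollection",
    "BackendCache",
    "DataManager",
    "ConversionError",
    "EmptyCollectionError",
    "TifDirConverter",
    "BfconvertConverter",
    "cache_key",
    "load",
    "parse_slice_filename",
    "format_slice_filename",
    "DEFAULT_BACKEND_ROOT",
]

logger = logging.getLogger(__name__)

DEFAULT_BACKEND_ROOT = "provimage_backend"

_SLICE_RE = re.compile(r"^S(\d+)_C(\d+)_Z(\d+)_T(\d+)\.tif$")


class ConversionError(RuntimeError):
    """A converter failed or produced no usable slices."""


class EmptyCollectionError(ConversionError):
    """Conversion yielded no parseable slice files."""


class SliceCoordinate(NamedTuple):
    """(series, channel, z-slice, timepoint) address of one 2D image."""

    s: int
    c: int
    z: int
    t: int


def format_slice_filename(coord: SliceCoordinate) -> str:
    return "S{}_C{}_Z{}_T{}.tif".format(*coord)


def parse_slice_filename(name: str) -> SliceCoordinate:
    """Inverse of the naming scheme: "S0_C1_Z31_T0.tif" -> (0, 1, 31, 0)."""
    match = _SLICE_RE.match(name)
    if match is None:
        raise ValueError(
            "filename {!r} does not follow the S{{s}}_C{{c}}_Z{{z}}_T{{t}}.tif "
            "naming scheme".format(name)
        )
    return SliceCoordinate(*(int(g) for g in match.groups()))


def _hash_file(md5: "hashlib._Hash", path: Path) -> None:
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            md5.update(chunk)


def cache_key(path) -> str:
    """32-character lowercase hex MD5 of the input's content.

    For a regular file this is the digest of its bytes, so identical content
    yields an identical key regardless of filename.  For a directory the
    digest covers the sorted relative file names and their bytes.
    """
    path = Path(path)
    md5 = hashlib.md5()
    if path.is_dir():
        for sub in sorted(p for p in path.rglob("*") if p.is_file()):
            md5.update(str(sub.relative_to(path)).encode())
            _hash_file(md5, sub)
    elif path.is_file():
        _hash_file(md5, path)
    else:
        raise FileNotFoundError("cannot hash unreadable input: {}".format(path))
    return md5.hexdigest()


class TifDirConverter:
    """Built-in converter for pre-converted inputs.

    Treats an input directory (or zip archive) of TIFF slices already named
    ``S{s}_C{c}_Z{z}_T{t}.tif`` as the conversion result and copies them
    byte-identically into the cache.  Files not following the scheme are
    skipped with a warning.
    """

    name = "tifdir"

    def convert(self, input_path, output_dir) -> None:
        input_path = Path(input_path)
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        copied = 0
        if input_path.is_dir():
            for src in sorted(input_path.iterdir()):
                if not src.is_file():
                    continue
                try:
                    parse_slice_filename(src.name)
                except ValueError:
                    logger.warning("skipping non-slice file %s", src)
                    continue
                shutil.copyfile(src, output_dir / src.name)
                copied += 1
        elif zipfile.is_zipfile(input_path):
            with zipfile.ZipFile(input_path) as zf:
                for info in sorted(zf.infolist(), key=lambda i: i.filename):
                    name = os.path.basename(info.filename)
                    if not name:
                        continue
                    try:
                        parse_slice_filename(name)
                    except ValueError:
                        logger.warning("skipping non-slice member %s", info.filename)
                        continue
                    with zf.open(info) as src, open(output_dir / name, "wb") as dst:
                        shutil.copyfileobj(src, dst)
                    copied += 1
        else:
            raise ConversionError(
                "tifdir converter expects a directory or zip archive of "
                "S{{s}}_C{{c}}_Z{{z}}_T{{t}}.tif slices, got {}".format(input_path)
            )
        if copied == 0:
            raise EmptyCollectionError(
                "no files following the slice naming scheme found in "
                "{}".format(input_path)
            )


class BfconvertConverter:
    """Wrapper around the external Bio-Formats ``bfconvert`` tool.

    Optional: requires the ``bfconvert`` executable on PATH.  The output
    pattern maps Bio-Formats' series/channel/z/time counters onto the
    ``S{s}_C{c}_Z{z}_T{t}.tif`` naming scheme.
    """

    name = "bfconvert"

    def __init__(self, executable: str = "bfconvert") -> None:
        self.executable = executable

    def convert(self, input_path, output_dir) -> None:
        exe = shutil.which(self.executable)
        if exe is None:
            raise ConversionError(
                "bfconvert not found on PATH; install the Bio-Formats command "
                "line tools, or use the self-contained 'tifdir' converter with "
                "a directory of S{s}_C{c}_Z{z}_T{t}.tif slices"
            )
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        pattern = str(output_dir / "S%s_C%c_Z%z_T%t.tif")
        result = subprocess.run(
            [exe, str(input_path), pattern],
            capture_output=True,
            text=True,
        )
        if result.returncode != 0:
            raise ConversionError(
                "bfconvert failed with exit status {}:\n{}".format(
                    result.returncode, result.stderr
                )
            )


CONVERTERS = {
    TifDirConverter.name: TifDirConverter,
    BfconvertConverter.name: BfconvertConverter,
}


class BackendCache:
    """Content-addressed cache directory plus the converter that fills it."""

    def __init__(self, root=DEFAULT_BACKEND_ROOT, converter=None) -> None:
        self.root = Path(root)
        self.converter = converter if converter is not None else TifDirConverter()

    def directory_for(self, input_path) -> Path:
        return self.root / cache_key(input_path)

    def ensure(self, input_path) -> Path:
        """Return the populated cache subdirectory, converting only on a miss."""
        target = self.directory_for(input_path)
        if target.is_dir() and any(target.iterdir()):
            return target
        self.converter.convert(input_path, target)
        return target


class MicroscopyCollection:
    """Index from (series, channel, z, time) coordinates to cached slices."""

    def __init__(self, entries: Dict[SliceCoordinate, Path], source) -> None:
        self.entries = dict(entries)
        self.source = Path(source)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def coordinates(self):
        return sorted(self.entries)

    def available(self) -> Dict[str, list]:
        """Observed coordinate values per axis (sparse sets, not ranges)."""
        coords = self.coordinates
        return {
            "series": sorted({c.s for c in coords}),
            "channels": sorted({c.c for c in coords}),
            "zslices": sorted({c.z for c in coords}),
            "timepoints": sorted({c.t for c in coords}),
        }

    def _lookup(self, coord: SliceCoordinate) -> Path:
        try:
            return self.entries[coord]
        except KeyError:
            raise KeyError(
                "no slice at {}; available: {}".format(coord, self.available())
            ) from None

    def image(self, s: int = 0, c: int = 0, z: int = 0, t: int = 0) -> Image:
        """Load the 2D slice at (s, c, z, t); omitted coordinates default to 0."""
        return image_from_file(self._lookup(SliceCoordinate(s, c, z, t)))

    def zstack(self, s: int = 0, c: int = 0, t: int = 0) -> Stack3D:
        """Assemble all z-slices for (s, c, t), ordered by ascending z.

        The z coordinates must be contiguous from their minimum; a gap is a
        consistency error.
        """
        zs = sorted(co.z for co in self.entries if (co.s, co.c, co.t) == (s, c, t))
        if not zs:
            raise KeyError(
                "no slices for s={}, c={}, t={}; available: {}".format(
                    s, c, t, self.available()
                )
            )
        expected = list(range(zs[0], zs[0] + len(zs)))
        if zs != expected:
            raise ValueError(
                "z-slices for s={}, c={}, t={} are not contiguous: {}".format(
                    s, c, t, zs
                )
            )
        slices = [self.image(s=s, c=c, z=z, t=t) for z in zs]
        return stack_from_slices(slices)


def _index_cache_dir(directory: Path) -> Dict[SliceCoordinate, Path]:
    entries: Dict[SliceCoordinate, Path] = {}
    for path in sorted(Path(directory).iterdir()):
        if not path.is_file():
            continue
        try:
            coord = parse_slice_filename(path.name)
        except ValueError:
            logger.warning("skipping non-slice file in cache: %s", path)
            continue
        entries[coord] = path
    return entries


def load(path, cache: BackendCache | None = None) -> MicroscopyCollection:
    """Load a bioimage input as a collection of addressable 2D slices.

    If the cache already holds slices for this input's content hash no
    conversion runs; otherwise the cache's converter populates it first.
    """
    if cache is None:
        cache = BackendCache()
    directory = cache.ensure(path)
    entries = _index_cache_dir(directory)
    if not entries:
        raise EmptyCollectionError(
            "cache directory {} contains no parseable slices".format(directory)
        )
    return MicroscopyCollection(entries, source=path)


class DataManager:
    """Convenience front end: ``DataManager().load("hypocotyl.czi")``."""

    def __init__(self, backend_root=DEFAULT_BACKEND_ROOT, converter=None) -> None:
        if isinstance(converter, str):
            converter = CONVERTERS[converter]()
        self.cache = BackendCache(backend_root, converter)

    def load(self, path) -> MicroscopyCollection:
        return load(path, self.cache)
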