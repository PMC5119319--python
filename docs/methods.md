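# Methods

## Provenance model

An `Image` is a `numpy.ndarray` subclass with a `History`: a creation
record set exactly once at construction (the absolute source path for
`image_from_file`, a generator description otherwise) and an append-only
list of `Event`s. An event stores the function name and a call-style
rendering of the arguments in which any array-valued argument appears as
the literal token `image` and keyword arguments as `name=value`
(`remove_small_objects(image, min_size=500)`). Histories compare and
serialise by their string form, so a history is exportable as a plain list
of strings.

Provenance flows **only** through functions decorated with
`@transformation`. Raw numpy operations on an `Image` (`image > cutoff`,
`-image`, slicing arithmetic) return plain `ndarray`s by design
(`__array_wrap__` downcasts): an untracked operation must not silently
masquerade as tracked. The decorator picks the first `Image`-typed argument
(positionals first, then keywords, in call order) as the history donor,
copies its history, and appends one event. A consequence worth knowing: in
`watershed_with_seeds(negate(cellwall), seeds=seeds)` the negated landscape
is a bare array, so the segmentation inherits the *seeds* lineage — the
five preceding pipeline steps — plus its own event, which is exactly the
chain of operations that produced the result. Called with only bare
arrays, a transformation starts a fresh history (`created by <name>`), a
convenience chosen over raising.

One module-global `AuditConfig` is shared by all decorated functions so a
pipeline yields one continuous numbering (`{counter}_{name}.png`, counter
starting at 1, no zero padding). Audit output can be disabled or
redirected; the counter is resettable. Histories are not persisted to disk
automatically and are not embedded in image metadata.

## Pixel conventions and PNG encoding

Coordinates are (row, column), 0-based, throughout. Supported `Image`
dtypes are bool, uint8, uint16 and floating point; dtype is preserved by
construction. PNG encoding maps bool to {0, 255} and passes uint8 through
unchanged; uint16 and float images are min-max rescaled so min→0 and
max→255 (constant image → all zeros) — an audit image should always be
viewable regardless of the source bit depth. The rounding rule for
rescaled mid-range values is numpy's round-half-to-even, pinned by test
(0.5 on a unit-range float image encodes to 128). `SegmentedImage`
overrides `png()` with a false-colour rendering (background black, segment
*i* coloured by `pretty_color_from_identifier(i)`).

## Slice cache and collections

Inputs are unpacked into `<backend root>/<key>/S{s}_C{c}_Z{z}_T{t}.tif`
where the key is the 32-hex-character MD5 of the input bytes (for a
directory input, of the sorted relative names and contents). Content
addressing makes conversion idempotent: a second load of the same bytes,
under any filename, finds a populated cache directory and runs no
converter. MD5's collision weakness is irrelevant for a local cache.
Non-conforming files in a cache directory are skipped with a logged
warning, not fatal. Coordinate availability is reported as the observed
sparse sets per axis, not inferred dense ranges; `zstack` requires
contiguous z for the requested (s, c, t) and errors on gaps. The
`bfconvert` converter shells out to Bio-Formats with an output pattern
matching the naming scheme and is entirely optional; `tifdir` (directory
or zip of pre-named slices) covers every self-contained use.

## Morphology and segmentation

The structuring element everywhere is the 3×3 cross (4-connected), with
borders treated as padded False; connected components and small-object
removal use 8-connectivity. These choices are not forced by any principle
— they are fixed and tested because every downstream number depends on
them. `remove_small_objects` retains components of area ≥ `min_size`
(strict removal below). Component labels are consecutive 1..K in raster
order of each component's first pixel.

`watershed_with_seeds` is a priority-flood: basins grow from the seeds in
ascending landscape order, ties broken by insertion (flooding) order, so
results are bit-reproducible; with no mask every pixel ends in some seed's
basin (no watershed-line pixels). Both labelling and flooding are
delegated to scikit-image (`measure.label`,
`segmentation.watershed`) — the tests verify the raster-order and
nearest-seed contracts against independent brute-force oracles rather than
trusting the library. On a flat landscape with two point seeds the result
equals Manhattan-nearest assignment with equidistant pixels going to the
first-flooded seed; with more seeds the tie pattern follows flooding order
and is asserted only to be distance-minimal and deterministic. Landscape
negation is the caller's step; `negate()` promotes unsigned dtypes to
signed first, because `-x` on uint8 wraps modulo 256.

`Region.perimeter` is defined as the border pixel count (border = mask AND
NOT its cross-erosion). Alternatives — crack length, weighted contour
estimators — give systematically different values; the simple count was
chosen because it composes exactly with `area(inner) + area(border) =
area(mask)` and is trivially auditable. `Region.convex_hull` is the
rasterised hull of member pixel centres: a pixel is included when its
centre lies in the convex hull (boundary included, tolerance 1e-9) of the
member centres, computed by half-plane tests against the Qhull facets;
degenerate (single-pixel or collinear) masks fill the lattice points on
their spanning segment. This rule makes the hull a superset of the mask
and idempotent. `remove_region` zeroes a label without renumbering the
survivors.

## Annotation determinism

`AnnotatedImage` drawing ops touch only the pixels their contract names
and clip silently at the canvas edge. Text uses an embedded 5×7 bitmap
font (digits, A–Z, lower case rendered as upper case, space, `-`, `.`;
anything else is a hollow box plus a logged warning) with a 1-pixel glyph
gap; centred text rounds its top-left offset toward negative infinity.
The label palette is a fixed LCG (modulus 2^32, multiplier 1664525,
increment 1013904223) seeded by the identifier, each of three draws mapped
to [63, 255] via `v mod 193 + 63` — no platform RNG, no font stack, so
annotated output is byte-identical across machines. The floor of 63 keeps
every segment visible against the black background.

## Synthetic fixtures

`FixtureSpec` defaults describe the study conditions used throughout the
tests and the acceptance script: a 4×5 grid of 32 px cell interiors
(intensity 20) separated and framed by 2 px walls (intensity 200), blurred
with a Gaussian of σ = wall_width/4 (the blur's ±σ width is half the wall
width), optional additive Gaussian noise (default sd 0 — the reference
condition is noise-free), 2 channels × 3 z-slices of one series and
timepoint. With this σ, thresholding the noise-free image at the midpoint
intensity recovers the wall mask exactly, including at wall junctions,
which pins the generator's geometry by construction. Channel 1 is the
wall marker with a 10 % contrast fall-off per normalised distance from the
middle focal plane; channel 0 holds one Gaussian nuclear blob per cell at
its centroid. Ground truth labels the interiors 1..R·C in raster order;
walls are background, and the image's outer wall frame plays the role
that non-cell border tissue plays in real data — it is absorbed by edge
cells and bounded by the area filter. All randomness comes from one
`numpy` generator seeded by `spec.seed`, and TIFF writing embeds no
timestamps, so a spec is byte-reproducible.

What the generator does **not** emulate: point-spread anisotropy, shot
noise statistics, intensity gradients, touching or irregularly shaped
cells, and out-of-focus light. Passing tests therefore demonstrate the
pipeline's correctness and reproducibility machinery, not segmentation
accuracy on real tissue, where threshold and size parameters must be
re-tuned.

## Demo pipeline and problem sizes

The demo chain is: absolute threshold (strictly greater) → binary
dilation → inversion → small-object removal → connected components →
seeded watershed on the negated landscape, then removal of regions whose
area exceeds a maximum (regions too large to be cells, e.g. tissue
borders). CLI defaults are cutoff 50, min_size 500, max area 40 000,
channel 1, z-slice 31 when present (else the middle slice). On the default
fixture the tests and acceptance script use the fixture-appropriate
values: cutoff = midpoint intensity 110, min_size 400 (below the 1024 px
interior), max area 1.5× the interior area. Under the noise-free default
the pipeline recovers all 20 cells with centroids within 0.5 px of ground
truth (interior cells are exact; edge cells shift by absorbing the outer
wall frame). The property suites run on small arrays — 100 random 16×16
binaries against a flood-fill oracle, 100 random 18×18 watershed
landscapes, 138×172 px demo images — sizes chosen so the full suite
completes in seconds while still exercising every contract.

## Known limitations

- 2D only: z-stacks are materialised arrays handled slice-wise by callers;
  there is no 3D segmentation and no out-of-core/virtual-stack support.
- No metadata extraction from bioimage files (physical pixel sizes,
  channels names); coordinates are purely positional.
- Histories live on objects and audit PNGs; nothing re-attaches a history
  when an image is re-read from disk.
- The label palette guarantees determinism and visibility, not perceptual
  distinctness for adjacent labels.
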