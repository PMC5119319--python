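import numpy as np
import pytest

from provimage import transform
from provimage.fixtures import FixtureSpec, generate_collection


@pytest.fixture(autouse=True)
def quiet_audit(tmp_path):
    """Disable audit output by default and point it at a scratch directory.

    Tests that exercise audit behaviour re-enable it explicitly; everything
    else must not litter the working directory.
    """
    saved = (transform.AUDIT.enabled, transform.AUDIT.directory, transform.AUDIT.counter)
    transform.AUDIT.reset(directory=tmp_path, enabled=False)
    yield transform.AUDIT
    transform.AUDIT.enabled, transform.AUDIT.directory, transform.AUDIT.counter = saved


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec()


@pytest.fixture(scope="session")
def fixture_collection(tmp_path_factory, default_spec):
    """One shared synthetic collection (4x5 grid, noise-free, 2 channels, 3 z)."""
    outdir = tmp_path_factory.mktemp("fixture") / "collection"
    manifest = generate_collection(default_spec, outdir)
    return outdir, manifest


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; never reuse the implementation).
# ---------------------------------------------------------------------------

def flood_fill_label(arr, background=0):
    """Brute-force 8-connected labelling by BFS in raster order."""
    arr = np.asarray(arr)
    labels = np.zeros(arr.shape, dtype=int)
    next_label = 1
    for r0 in range(arr.shape[0]):
        for c0 in range(arr.shape[1]):
            if arr[r0, c0] == background or labels[r0, c0]:
                continue
            value = arr[r0, c0]
            queue = [(r0, c0)]
            labels[r0, c0] = next_label
            while queue:
                r, c = queue.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < arr.shape[0]
                            and 0 <= cc < arr.shape[1]
                            and labels[rr, cc] == 0
                            and arr[rr, cc] == value
                        ):
                            labels[rr, cc] = next_label
                            queue.append((rr, cc))
            next_label += 1
    return labels


def nearest_seed_labels(shape, seed_points):
    """Flat-terrain watershed oracle: each pixel goes to the seed with the
    smallest Manhattan distance; ties go to the earlier seed in the list."""
    labels = np.zeros(shape, dtype=int)
    for r in range(shape[0]):
        for c in range(shape[1]):
            best = None
            for order, (sr, sc, label) in enumerate(seed_points):
                d = abs(r - sr) + abs(c - sc)
                if best is None or (d, order) < best[:2]:
                    best = (d, order, label)
            labels[r, c] = best[2]
    return labels


def same_partition(a, b):
    """True when two label images induce the same partition of the plane."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return False
    mapping = {}
    reverse = {}
    for x, y in zip(a.ravel(), b.ravel()):
        if mapping.setdefault(x, y) != y or reverse.setdefault(y, x) != x:
            return False
    return True
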