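import numpy as np
import pytest
from scipy import ndimage

from hemvol.slice_geometry import SliceMask

FULL = np.ones((3, 3), dtype=bool)


def random_blob(rng, size=20, density=0.5):
    """A single 8-connected, hole-free random blob, or None if empty."""
    a = rng.random((size, size)) > (1 - density)
    a = ndimage.binary_closing(a)
    a = ndimage.binary_fill_holes(a)
    labels, n = ndimage.label(a, structure=FULL)
    if n == 0:
        return None
    sizes = ndimage.sum_labels(a, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


@pytest.fixture
def blobs():
    """60 seeded random blobs with anisotropic spacings."""
    rng = np.random.default_rng(1234)
    out = []
    while len(out) < 60:
        blob = random_blob(rng, size=int(rng.integers(8, 26)))
        if blob is None or blob.sum() < 2:
            continue
        sr, sc = rng.uniform(0.4, 1.6, size=2)
        out.append(SliceMask(blob, float(sr), float(sc)))
    return out


def voxel_ellipse(a_mm, b_mm, spacing, angle_deg=0.0):
    """Voxelized ellipse mask (semi-axes in mm) by centre inclusion."""
    ext = max(a_mm, b_mm) + 2 * spacing
    n = int(np.ceil(2 * ext / spacing))
    idx = (np.arange(n) - (n - 1) / 2) * spacing
    yy, xx = np.meshgrid(idx, idx, indexing="ij")
    if angle_deg:
        t = np.deg2rad(angle_deg)
        xx, yy = xx * np.cos(t) + yy * np.sin(t), -xx * np.sin(t) + yy * np.cos(t)
    return (xx / a_mm) ** 2 + (yy / b_mm) ** 2 <= 1.0


def voxel_disk(radius_px, size=None):
    size = size or (2 * radius_px + 5)
    c = (size - 1) / 2
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2
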