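"""Geometric measurement of a lesion on a single binary mask slice.

The per-slice quantities driving the volume estimators are the segmented
area, the maximum in-plane length (the longest distance between any two
contour pixels, i.e. the maximum Feret diameter) and the maximum width
perpendicular to that length (the longest chord of the contour polygon
orthogonal to the length axis).  All distances are taken between pixel
centres in physical millimetres, honouring anisotropic in-plane spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "SliceMask",
    "SliceMeasurement",
    "extract_contour",
    "max_length",
    "max_perpendicular_width",
    "measure_slice",
]

_FULL_CONNECTIVITY = np.ones((3, 3), dtype=bool)

# Moore neighbourhood in clockwise order starting from "up".
_MOORE = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)],
    dtype=int,
)


@dataclass(frozen=True)
class SliceMask:
    """One axial slice of a binary segmentation.

    Parameters
    ----------
    pixels
        2-D boolean (or 0/1) array, ``True`` where the lesion is present.
    spacing_row, spacing_col
        Physical size of one pixel along the row/column axis, in mm.
    slice_index
        Ordinal position of the slice within its axial stack.
    """

    pixels: np.ndarray
    spacing_row: float
    spacing_col: float
    slice_index: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"slice mask must be 2-D, got shape {arr.shape}")
        if self.spacing_row <= 0 or self.spacing_col <= 0:
            raise ValueError("pixel spacing must be strictly positive")
        object.__setattr__(self, "pixels", arr.astype(bool))


@dataclass(frozen=True)
class SliceMeasurement:
    """Area, maximum length and maximum perpendicular width of one slice."""

    area_mm2: float
    max_length_mm: float
    max_width_mm: float
    length_endpoints: Optional[tuple[tuple[int, int], tuple[int, int]]] = None
    width_anchor: Optional[tuple[int, int]] = None
    slice_index: int = 0

    @property
    def has_lesion(self) -> bool:
        return self.area_mm2 > 0.0

    def __post_init__(self) -> None:
        if self.area_mm2 < 0:
            raise ValueError("area cannot be negative")
        if self.max_width_mm > self.max_length_mm + 1e-9:
            raise ValueError("max width cannot exceed max length")


def _largest_component(pixels: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(pixels, structure=_FULL_CONNECTIVITY)
    if n == 0:
        raise ValueError("mask has no foreground pixels")
    if n > 1:
        sizes = ndimage.sum_labels(pixels, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1  # first occurrence wins ties
        warnings.warn(
            f"slice contains {n} foreground components; "
            "measuring the largest only",
            stacklevel=3,
        )
        return labels == keep
    return pixels.astype(bool)


_MOORE_INDEX = {tuple(d): i for i, d in enumerate(map(tuple, _MOORE))}


def _trace_boundary(comp: np.ndarray) -> np.ndarray:
    """Moore-neighbour boundary tracing of a single 8-connected component.

    Returns the closed boundary path in order; thin structures may
    legitimately revisit pixels (the path goes around them).
    """
    rows, cols = np.nonzero(comp)
    start = (int(rows[0]), int(cols[0]))  # uppermost-leftmost pixel
    h, w = comp.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and bool(comp[r, c])

    path: list[tuple[int, int]] = []
    current = start
    back_dir = 6  # index of (0, -1): left of the start is background
    seen: set[tuple[tuple[int, int], int]] = set()
    while (current, back_dir) not in seen:
        seen.add((current, back_dir))
        path.append(current)
        found = -1
        prev_k = 0
        for k in range(1, 9):
            d = (back_dir + k) % 8
            if fg(current[0] + int(_MOORE[d][0]), current[1] + int(_MOORE[d][1])):
                found = d
                prev_k = k - 1
                break
        if found < 0:  # isolated single pixel
            break
        prev_dir = (back_dir + prev_k) % 8  # last background cell examined
        prev_cell = (
            current[0] + int(_MOORE[prev_dir][0]),
            current[1] + int(_MOORE[prev_dir][1]),
        )
        nxt = (current[0] + int(_MOORE[found][0]), current[1] + int(_MOORE[found][1]))
        back_dir = _MOORE_INDEX[(prev_cell[0] - nxt[0], prev_cell[1] - nxt[1])]
        current = nxt
    return np.array(path, dtype=int)


def _insert_corner_pixels(path: np.ndarray, boundary_set: np.ndarray) -> np.ndarray:
    """Re-insert boundary pixels skipped by diagonal moves of the trace.

    A pixel whose only background neighbour is diagonal sits just inside a
    staircase corner; the Moore trace cuts that corner.  Each diagonal step
    p -> q of the path is expanded with any boundary pixel at the two shared
    4-neighbour corners, keeping the path ordered along the boundary.
    """
    if len(path) < 2:
        return path
    traced = set(map(tuple, path))
    closed = np.vstack([path, path[:1]])
    out: list[tuple[int, int]] = []
    for p, q in zip(closed[:-1], closed[1:]):
        out.append((int(p[0]), int(p[1])))
        if abs(int(q[0]) - int(p[0])) == 1 and abs(int(q[1]) - int(p[1])) == 1:
            for corner in ((int(p[0]), int(q[1])), (int(q[0]), int(p[1]))):
                if boundary_set[corner] and corner not in traced:
                    out.append(corner)
                    traced.add(corner)
    return np.array(out, dtype=int)


def extract_contour(mask: SliceMask) -> np.ndarray:
    """Ordered boundary pixels of the (largest) foreground component.

    The contour is the set of foreground pixels with at least one background
    8-neighbour (grid edges count as background), ordered along the outer
    boundary by Moore-neighbour tracing.

    Raises
    ------
    ValueError
        If the mask contains no foreground pixel.
    """
    comp = _largest_component(mask.pixels)
    path = _trace_boundary(comp)
    interior = ndimage.binary_erosion(comp, structure=_FULL_CONNECTIVITY, border_value=0)
    boundary_set = comp & ~interior
    path = _insert_corner_pixels(path, boundary_set)
    traced = set(map(tuple, path))
    expected = set(zip(*np.nonzero(boundary_set)))
    missing = expected - traced
    if missing:
        # inner boundaries (holes) are not part of the outer trace
        warnings.warn(
            f"{len(missing)} boundary pixels not on the outer contour "
            "(component has holes); they are ignored",
            stacklevel=2,
        )
    return path


def _to_physical(points: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    return points.astype(float) * np.asarray(spacing, dtype=float)


def max_length(
    contour: np.ndarray,
    spacing: tuple[float, float],
    method: str = "bruteforce",
) -> tuple[float, tuple[tuple[int, int], tuple[int, int]]]:
    """Longest distance (mm) between any two contour pixels.

    Parameters
    ----------
    contour
        (n, 2) integer pixel coordinates.
    spacing
        (spacing_row, spacing_col) in mm per pixel.
    method
        ``"bruteforce"`` evaluates all pixel pairs; ``"hull"`` restricts the
        search to convex-hull vertices (same result, faster for large
        contours).

    Returns
    -------
    (length_mm, (endpoint_a, endpoint_b))
        Endpoints are pixel coordinates; on exact ties the lexicographically
        smallest endpoint pair is returned.
    """
    pts = np.unique(np.asarray(contour, dtype=int), axis=0)  # lexicographic sort
    if len(pts) == 0:
        raise ValueError("contour is empty")
    if len(pts) == 1:
        p = tuple(int(v) for v in pts[0])
        return 0.0, (p, p)

    phys_all = _to_physical(pts, spacing)
    cand = pts
    phys = phys_all
    if method == "hull" and len(pts) >= 3:
        try:
            hull = ConvexHull(phys_all)
            order = np.sort(hull.vertices)
            cand = pts[order]
            phys = phys_all[order]
        except QhullError:  # collinear contour
            pass
    elif method not in ("bruteforce", "hull"):
        raise ValueError(f"unknown method {method!r}")

    diff = phys[:, None, :] - phys[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    dmax = d2.max()
    ii, jj = np.nonzero(d2 == dmax)
    upper = ii < jj
    i, j = int(ii[upper][0]), int(jj[upper][0])  # rows lexicographically sorted
    a = tuple(int(v) for v in cand[i])
    b = tuple(int(v) for v in cand[j])
    return float(np.sqrt(dmax)), (a, b)


def max_perpendicular_width(
    contour: np.ndarray,
    length_endpoints: tuple[tuple[int, int], tuple[int, int]],
    spacing: tuple[float, float],
) -> tuple[float, Optional[tuple[int, int]]]:
    """Longest chord of the contour polygon perpendicular to the length axis.

    For every contour pixel the full line through it, perpendicular (in
    physical coordinates) to the maximum-length direction, is intersected
    with the closed polygon through the ordered contour pixel centres; the
    farthest intersection from the pixel is that pixel's width, and the
    maximum over all pixels is returned.
    """
    path = np.asarray(contour, dtype=int)
    if len(path) == 0:
        raise ValueError("contour is empty")
    a, b = (np.asarray(p, dtype=float) for p in length_endpoints)
    sp = np.asarray(spacing, dtype=float)
    axis = (b - a) * sp
    norm = np.linalg.norm(axis)
    if norm == 0 or len(path) < 2:
        return 0.0, None
    u = axis / norm  # length direction
    w = np.array([-u[1], u[0]])  # perpendicular direction

    verts = path.astype(float) * sp
    closed = np.vstack([verts, verts[:1]])
    s_all = closed @ u
    t_all = closed @ w

    best = 0.0
    best_anchor: Optional[tuple[int, int]] = None
    for idx in range(len(verts)):
        s0 = s_all[idx]
        ds = s_all - s0  # signed coordinate along the length axis
        d0, d1 = ds[:-1], ds[1:]
        dists = [0.0]
        on_line = np.abs(d0) < 1e-12
        if on_line.any():
            dists.append(np.max(np.abs(t_all[:-1][on_line] - t_all[idx])))
        crossing = (d0 * d1) < 0
        if crossing.any():
            frac = d0[crossing] / (d0[crossing] - d1[crossing])
            t_int = t_all[:-1][crossing] + frac * (t_all[1:][crossing] - t_all[:-1][crossing])
            dists.append(np.max(np.abs(t_int - t_all[idx])))
        d = max(dists)
        if d > best:
            best = d
            best_anchor = tuple(int(v) for v in path[idx])
    return float(best), best_anchor


def measure_slice(mask: SliceMask) -> SliceMeasurement:
    """Area, maximum length and maximum perpendicular width of one slice.

    An empty slice yields an all-zero, lesion-free measurement; a
    single-pixel lesion has positive area but zero lengths.
    """
    n_fg = int(np.count_nonzero(mask.pixels))
    area = n_fg * mask.spacing_row * mask.spacing_col
    if n_fg == 0:
        return SliceMeasurement(0.0, 0.0, 0.0, None, None, mask.slice_index)
    spacing = (mask.spacing_row, mask.spacing_col)
    contour = extract_contour(mask)
    length, endpoints = max_length(contour, spacing)
    width, anchor = max_perpendicular_width(contour, endpoints, spacing)
    return SliceMeasurement(
        area_mm2=area,
        max_length_mm=length,
        max_width_mm=width,
        length_endpoints=endpoints,
        width_anchor=anchor,
        slice_index=mask.slice_index,
    )
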