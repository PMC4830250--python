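"""Lesion depth along the slice axis: bearing slices, C0 and C1.

The unadjusted depth C0 is slice thickness times the number of
lesion-bearing slices.  The adjusted depth C1 weights each bearing slice by
its area ratio to the reference (largest-area) slice: ratio > 75% counts as
a full slice, 25-75% as half a slice, < 25% not at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .slice_geometry import SliceMeasurement

__all__ = [
    "SeriesMeasurement",
    "DepthResult",
    "RepresentativeSlices",
    "find_bearing_slices",
    "weight_for_ratio",
    "compute_depths",
    "select_representative_slices",
]

MAX_RECOMMENDED_THICKNESS_MM = 5.0


@dataclass(frozen=True)
class SeriesMeasurement:
    """Ordered per-slice measurements of one axial series."""

    slices: tuple[SliceMeasurement, ...]
    slice_thickness_mm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "slices", tuple(self.slices))
        if not self.slices:
            raise ValueError("series has no slices")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice thickness must be strictly positive")
        if self.slice_thickness_mm > MAX_RECOMMENDED_THICKNESS_MM:
            warnings.warn(
                f"slice thickness {self.slice_thickness_mm} mm exceeds the "
                f"recommended maximum of {MAX_RECOMMENDED_THICKNESS_MM} mm",
                stacklevel=3,
            )

    @property
    def areas_mm2(self) -> np.ndarray:
        return np.array([s.area_mm2 for s in self.slices], dtype=float)


@dataclass(frozen=True)
class DepthResult:
    bearing_indices: tuple[int, ...]
    weights: tuple[float, ...]       # one per bearing slice, in {0, 0.5, 1}
    area_ratios: tuple[float, ...]   # one per bearing slice, vs the reference
    C0_mm: float
    C1_mm: float


@dataclass(frozen=True)
class RepresentativeSlices:
    largest_index: int   # source of A1, B1
    central_index: int   # source of A2, B2
    rng_seed: int


def find_bearing_slices(series: SeriesMeasurement) -> list[int]:
    """Indices of slices with nonzero lesion area, in axial order."""
    areas = series.areas_mm2
    idx = [i for i, a in enumerate(areas) if a > 0]
    if not idx:
        raise ValueError("no lesion-bearing slice in the series")
    if len(idx) != idx[-1] - idx[0] + 1:
        warnings.warn(
            "lesion-bearing slices are not contiguous; lesion-free gaps do "
            "not count toward the depth",
            stacklevel=2,
        )
    return idx


def weight_for_ratio(
    ratio: float, lower: float = 0.25, upper: float = 0.75
) -> float:
    """Slice-count weight for one area ratio.

    ``ratio > upper`` counts as a full bearing slice (1), ``lower <= ratio
    <= upper`` as half (0.5) and ``ratio < lower`` as none (0).  Both
    boundaries map to 0.5 by default.
    """
    if ratio < 0:
        raise ValueError("area ratio cannot be negative")
    if ratio > upper:
        return 1.0
    if ratio >= lower:
        return 0.5
    return 0.0


def compute_depths(series: SeriesMeasurement, reference_index: int) -> DepthResult:
    """Unadjusted (C0) and adjusted (C1) maximum depth in mm.

    Area ratios are taken against ``reference_index`` (normally the
    largest-area slice, so every ratio is <= 1).
    """
    areas = series.areas_mm2
    ref_area = areas[reference_index]
    if ref_area <= 0:
        raise ValueError("reference slice has no lesion")
    bearing = find_bearing_slices(series)
    ratios = tuple(float(areas[i] / ref_area) for i in bearing)
    weights = tuple(weight_for_ratio(r) for r in ratios)
    t = series.slice_thickness_mm
    c0 = t * len(bearing)
    c1 = t * float(sum(weights))
    return DepthResult(
        bearing_indices=tuple(bearing),
        weights=weights,
        area_ratios=ratios,
        C0_mm=c0,
        C1_mm=c1,
    )


def select_representative_slices(
    series: SeriesMeasurement, seed: int = 0
) -> RepresentativeSlices:
    """Pick the largest-area slice and the central bearing slice.

    For an odd number of bearing slices the central one is the middle of the
    ordered bearing list.  For an even number, the larger-area slice of the
    two middle ones is chosen; an exact area tie is broken by a seeded
    random draw.
    """
    bearing = find_bearing_slices(series)
    areas = series.areas_mm2
    largest = bearing[int(np.argmax(areas[bearing]))]
    n = len(bearing)
    if n % 2 == 1:
        central = bearing[n // 2]
    else:
        lo, hi = bearing[n // 2 - 1], bearing[n // 2]
        if areas[lo] > areas[hi]:
            central = lo
        elif areas[hi] > areas[lo]:
            central = hi
        else:
            rng = np.random.default_rng(seed)
            central = int(rng.choice([lo, hi]))
    return RepresentativeSlices(
        largest_index=int(largest), central_index=int(central), rng_seed=int(seed)
    )
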