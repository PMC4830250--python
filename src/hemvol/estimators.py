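"""Volume estimators: planimetry reference and the ABC/2 variations.

A variation is defined by a coefficient ``a``, an intercept ``b`` (mL), the
representative slice supplying the in-plane lengths (largest-area vs
central bearing slice) and the depth used (unadjusted C0 vs adjusted C1):

    estimate_mL = a * (A_mm * B_mm * C_mm / 1000) + b

The eight built-in variations are the four traditional halves of the
product (a = 0.5, b = 0) and the four regression-calibrated forms
(0.37*A1B1C0 - 0.75, 0.65*A1B1C1 - 1.04, 0.39*A2B2C0 - 0.04,
0.65*A2B2C1 - 0.17).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .depth_model import (
    SeriesMeasurement,
    compute_depths,
    find_bearing_slices,
    select_representative_slices,
)
from .slice_geometry import SliceMask, measure_slice

__all__ = [
    "VariationSpec",
    "CaseRecord",
    "PRODUCT_KEYS",
    "builtin_variations",
    "simplified_variations",
    "planimetry_volume",
    "abc_estimate",
    "measure_case",
]

PRODUCT_KEYS = ("A1B1C0", "A1B1C1", "A2B2C0", "A2B2C1")


@dataclass(frozen=True)
class VariationSpec:
    """One ABC/2 variation: estimate = coefficient * product + intercept."""

    name: str
    coefficient: float
    intercept_mL: float
    length_source: str  # "largest" -> A1, B1 ; "central" -> A2, B2
    depth_source: str   # "C0" | "C1"

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("coefficient must be positive")
        if self.length_source not in ("largest", "central"):
            raise ValueError(f"unknown length source {self.length_source!r}")
        if self.depth_source not in ("C0", "C1"):
            raise ValueError(f"unknown depth source {self.depth_source!r}")

    @property
    def product_key(self) -> str:
        idx = "1" if self.length_source == "largest" else "2"
        return f"A{idx}B{idx}{self.depth_source}"

    @property
    def formula(self) -> str:
        sign = "-" if self.intercept_mL < 0 else "+"
        tail = "" if self.intercept_mL == 0 else f" {sign} {abs(self.intercept_mL):g}"
        return f"{self.coefficient:g} x {self.product_key}{tail}"


def builtin_variations() -> dict[str, VariationSpec]:
    """The eight standard variations, in their canonical order."""
    specs = [
        VariationSpec("1", 0.5, 0.0, "largest", "C0"),
        VariationSpec("2", 0.5, 0.0, "largest", "C1"),
        VariationSpec("3", 0.5, 0.0, "central", "C0"),
        VariationSpec("4", 0.5, 0.0, "central", "C1"),
        VariationSpec("1p", 0.37, -0.75, "largest", "C0"),
        VariationSpec("2p", 0.65, -1.04, "largest", "C1"),
        VariationSpec("3p", 0.39, -0.04, "central", "C0"),
        VariationSpec("4p", 0.65, -0.17, "central", "C1"),
    ]
    return {s.name: s for s in specs}


def simplified_variations() -> dict[str, VariationSpec]:
    """Zero-intercept approximations of the two best calibrated forms.

    Convenience forms for bedside use; they are approximations, not fitted
    variations.
    """
    specs = [
        VariationSpec("2s", 0.65, 0.0, "largest", "C1"),
        VariationSpec("4s", 0.65, 0.0, "central", "C1"),
    ]
    return {s.name: s for s in specs}


@dataclass
class CaseRecord:
    """Everything measured for one case (one row of the per-case table)."""

    case_id: str
    planimetry_mL: float
    products_mL: dict[str, float]
    estimates_mL: dict[str, float]
    A1_mm: Optional[float] = None
    B1_mm: Optional[float] = None
    A2_mm: Optional[float] = None
    B2_mm: Optional[float] = None
    C0_mm: Optional[float] = None
    C1_mm: Optional[float] = None
    sex: Optional[str] = None
    age: Optional[int] = None

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "case_id": self.case_id,
            "sex": self.sex,
            "age": self.age,
            "planimetry_mL": self.planimetry_mL,
        }
        for k in ("A1_mm", "B1_mm", "A2_mm", "B2_mm", "C0_mm", "C1_mm"):
            row[k] = getattr(self, k)
        for k in PRODUCT_KEYS:
            row[f"product_{k}"] = self.products_mL.get(k)
        for name, value in self.estimates_mL.items():
            row[f"variation_{name}"] = value
        return row


def planimetry_volume(series: SeriesMeasurement) -> float:
    """Reference volume in mL: sum of slice areas times thickness."""
    find_bearing_slices(series)  # raises if the series carries no lesion
    return float(series.areas_mm2.sum() * series.slice_thickness_mm / 1000.0)


def abc_estimate(A: float, B: float, C: float, spec: VariationSpec) -> float:
    """Apply one variation to lengths A, B (mm) and depth C (mm) -> mL."""
    if A < 0 or B < 0 or C < 0:
        raise ValueError("A, B and C must be non-negative")
    return spec.coefficient * (A * B * C / 1000.0) + spec.intercept_mL


def measure_case(
    mask_volume: np.ndarray,
    spacing: tuple[float, float],
    thickness_mm: float,
    variations: Optional[Iterable[VariationSpec]] = None,
    seed: int = 0,
    case_id: str = "case",
) -> CaseRecord:
    """Measure a 3-D binary mask end to end.

    ``mask_volume`` stacks axial slices along the third array axis; rows and
    columns are in-plane with ``spacing = (mm/row-step, mm/col-step)``.
    """
    vol = np.asarray(mask_volume)
    if vol.ndim != 3:
        raise ValueError(f"mask volume must be 3-D, got shape {vol.shape}")
    if variations is None:
        variations = builtin_variations().values()
    variations = list(variations)

    slices = [
        measure_slice(SliceMask(vol[:, :, k], spacing[0], spacing[1], slice_index=k))
        for k in range(vol.shape[2])
    ]
    series = SeriesMeasurement(tuple(slices), thickness_mm)
    reps = select_representative_slices(series, seed=seed)
    depth = compute_depths(series, reference_index=reps.largest_index)

    largest = series.slices[reps.largest_index]
    central = series.slices[reps.central_index]
    A1, B1 = largest.max_length_mm, largest.max_width_mm
    A2, B2 = central.max_length_mm, central.max_width_mm
    C0, C1 = depth.C0_mm, depth.C1_mm

    lengths = {"largest": (A1, B1), "central": (A2, B2)}
    depths = {"C0": C0, "C1": C1}
    products = {
        key: lengths["largest" if key[1] == "1" else "central"][0]
        * lengths["largest" if key[1] == "1" else "central"][1]
        * depths[key[4:]]
        / 1000.0
        for key in PRODUCT_KEYS
    }
    estimates = {
        spec.name: abc_estimate(*lengths[spec.length_source], depths[spec.depth_source], spec)
        for spec in variations
    }
    return CaseRecord(
        case_id=case_id,
        planimetry_mL=planimetry_volume(series),
        products_mL=products,
        estimates_mL=estimates,
        A1_mm=A1,
        B1_mm=B1,
        A2_mm=A2,
        B2_mm=B2,
        C0_mm=C0,
        C1_mm=C1,
    )
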