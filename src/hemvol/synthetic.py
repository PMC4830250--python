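"""Synthetic phantoms with known volumes, and the packaged study table.

Phantoms emulate axial CT mask stacks: a 3-D boolean array with slices
stacked on the third axis, in-plane spacing in mm and a slice thickness of
at most 5 mm.  Shapes are ellipsoids, biconvex lenses (two-sphere
intersections, the typical epidural-hematoma shape) and smoothly perturbed
"irregular" ellipsoids.  Ellipsoid and lens truths are closed-form; the
irregular truth comes from a fine-grid oracle.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import CaseRecord, PRODUCT_KEYS, builtin_variations

__all__ = [
    "PhantomSpec",
    "Phantom",
    "make_ellipsoid_phantom",
    "make_lens_phantom",
    "make_irregular_phantom",
    "make_phantom",
    "simulate_cohort",
    "load_study_fixture",
    "fixture_dataframe",
]

FIXTURE_SHA256 = "a6507cc418fce027499c7d5f79c93a56376392edc459d4ff166427df654ab995"
FIXTURE_COLUMNS = [
    "case_id", "sex", "age", "planimetry_mL",
    "v1", "v2", "v3", "v4", "v1p", "v2p", "v3p", "v4p",
]
_VARIATION_NAMES = ("1", "2", "3", "4", "1p", "2p", "3p", "4p")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic lesion.

    Ellipsoid/irregular shapes use semi-axes ``(a, b, c)`` mm (c along the
    slice axis); the lens uses sphere radius ``R`` and centre separation
    ``d`` (d < 2R), separated in-plane.
    """

    shape: str = "ellipsoid"  # ellipsoid | lens | irregular
    semi_axes_mm: tuple[float, float, float] = (20.0, 15.0, 10.0)
    radius_mm: float = 30.0
    separation_mm: float = 30.0
    spacing_mm: float = 1.0
    thickness_mm: float = 4.0
    orientation_deg: Optional[tuple[float, float, float]] = None
    perturbation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("ellipsoid", "lens", "irregular"):
            raise ValueError(f"unknown phantom shape {self.shape!r}")
        if self.spacing_mm <= 0 or self.thickness_mm <= 0:
            raise ValueError("spacing and thickness must be positive")
        if self.shape in ("ellipsoid", "irregular") and min(self.semi_axes_mm) <= 0:
            raise ValueError("semi-axes must be positive")
        if self.shape == "lens":
            if self.radius_mm <= 0 or self.separation_mm < 0:
                raise ValueError("lens parameters must be positive")
            if self.separation_mm >= 2 * self.radius_mm:
                raise ValueError("lens separation must satisfy d < 2R")
        if self.shape == "irregular" and not 0 <= self.perturbation < 1:
            raise ValueError("perturbation amplitude must lie in [0, 1)")
        if self.thickness_mm > 5:
            warnings.warn("slice thickness exceeds 5 mm", stacklevel=3)


@dataclass(frozen=True)
class Phantom:
    mask: np.ndarray = field(repr=False)  # (rows, cols, slices) boolean
    spacing_row: float
    spacing_col: float
    thickness_mm: float
    true_volume_mL: float
    spec: PhantomSpec

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError("phantom mask is empty at the given resolution")
        if self.true_volume_mL <= 0:
            raise ValueError("true volume must be positive")


def _grid(extent_mm: Sequence[float], spacing: float, thickness: float):
    """Voxel-centre coordinate axes covering +-extent with one-voxel margin."""
    steps = (spacing, spacing, thickness)
    axes = []
    for ext, st in zip(extent_mm, steps):
        n = int(math.ceil(2.0 * (ext + st) / st))
        axes.append((np.arange(n) - (n - 1) / 2.0) * st)
    return np.meshgrid(*axes, indexing="ij")


def _rotated_coords(xx, yy, zz, orientation_deg):
    if orientation_deg is None:
        return xx, yy, zz
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_euler("zyx", orientation_deg, degrees=True)
    pts = np.stack([xx, yy, zz], axis=-1)
    body = pts @ rot.as_matrix()  # world -> body frame
    return body[..., 0], body[..., 1], body[..., 2]


def _ellipsoid_mask(spec: PhantomSpec, spacing: float, thickness: float) -> np.ndarray:
    a, b, c = spec.semi_axes_mm
    r = max(a, b, c) if spec.orientation_deg is not None else None
    extent = (r, r, r) if r is not None else (a, b, c)
    xx, yy, zz = _grid(extent, spacing, thickness)
    xb, yb, zb = _rotated_coords(xx, yy, zz, spec.orientation_deg)
    if spec.shape == "irregular" and spec.perturbation > 0:
        f = _angular_field(spec.seed)
        v = np.stack([xb / a, yb / b, zb / c], axis=-1)
        rho = np.sqrt((v**2).sum(axis=-1))
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(rho[..., None] > 0, v / rho[..., None], 0.0)
        return rho <= 1.0 + spec.perturbation * f(unit)
    return (xb / a) ** 2 + (yb / b) ** 2 + (zb / c) ** 2 <= 1.0


def _angular_field(seed: int, n_lobes: int = 6, kappa: float = 4.0):
    """Smooth seeded scalar field on the unit sphere, normalised to |f|<=1."""
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_lobes, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    weights = rng.uniform(-1.0, 1.0, size=n_lobes)

    def raw(unit: np.ndarray) -> np.ndarray:
        dots = unit @ dirs.T
        return np.exp(kappa * (dots - 1.0)) @ weights

    # normalise against a dense deterministic sample of directions
    k = np.arange(2048)
    phi = np.arccos(1 - 2 * (k + 0.5) / 2048)
    theta = np.pi * (1 + 5**0.5) * k
    sample = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )
    scale = np.abs(raw(sample)).max()

    def f(unit: np.ndarray) -> np.ndarray:
        return raw(unit) / scale

    return f


def _check_resolved(spec: PhantomSpec) -> None:
    a, b, c = spec.semi_axes_mm
    if min(a, b) < spec.spacing_mm or c < spec.thickness_mm:
        raise ValueError(
            "phantom is unresolved: semi-axes smaller than the voxel step"
        )


def make_ellipsoid_phantom(spec: PhantomSpec) -> Phantom:
    """Voxelize an ellipsoid; truth is the 4/3*pi*a*b*c closed form."""
    if spec.shape != "ellipsoid":
        raise ValueError("spec.shape must be 'ellipsoid'")
    a, b, c = spec.semi_axes_mm
    _check_resolved(spec)
    mask = _ellipsoid_mask(spec, spec.spacing_mm, spec.thickness_mm)
    true_mL = 4.0 / 3.0 * math.pi * a * b * c / 1000.0
    return Phantom(mask, spec.spacing_mm, spec.spacing_mm, spec.thickness_mm, true_mL, spec)


def lens_volume_mL(radius_mm: float, separation_mm: float) -> float:
    """Closed-form volume of the intersection of two equal spheres."""
    R, d = radius_mm, separation_mm
    return math.pi * (4 * R + d) * (2 * R - d) ** 2 / 12.0 / 1000.0


def make_lens_phantom(spec: PhantomSpec) -> Phantom:
    """Biconvex lens: intersection of two equal spheres d apart (in-plane)."""
    if spec.shape != "lens":
        raise ValueError("spec.shape must be 'lens'")
    R, d = spec.radius_mm, spec.separation_mm
    half_thickness = R - d / 2.0      # lens half-extent along the centre axis
    extent = (half_thickness, R, R)
    xx, yy, zz = _grid(extent, spec.spacing_mm, spec.thickness_mm)
    xb, yb, zb = _rotated_coords(xx, yy, zz, spec.orientation_deg)
    r2 = yb**2 + zb**2
    mask = ((xb - d / 2) ** 2 + r2 <= R**2) & ((xb + d / 2) ** 2 + r2 <= R**2)
    return Phantom(
        mask, spec.spacing_mm, spec.spacing_mm, spec.thickness_mm,
        lens_volume_mL(R, d), spec,
    )


def make_irregular_phantom(spec: PhantomSpec, oracle_refinement: int = 4) -> Phantom:
    """Radially perturbed ellipsoid; truth from a refined-grid voxel count."""
    if spec.shape != "irregular":
        raise ValueError("spec.shape must be 'irregular'")
    _check_resolved(spec)
    mask = _ellipsoid_mask(spec, spec.spacing_mm, spec.thickness_mm)
    fine_spacing = spec.spacing_mm / oracle_refinement
    fine_thickness = spec.thickness_mm / oracle_refinement
    fine = _ellipsoid_mask(spec, fine_spacing, fine_thickness)
    true_mL = float(fine.sum()) * fine_spacing**2 * fine_thickness / 1000.0
    return Phantom(mask, spec.spacing_mm, spec.spacing_mm, spec.thickness_mm, true_mL, spec)


def make_phantom(spec: PhantomSpec) -> Phantom:
    maker = {
        "ellipsoid": make_ellipsoid_phantom,
        "lens": make_lens_phantom,
        "irregular": make_irregular_phantom,
    }[spec.shape]
    return maker(spec)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def simulate_cohort(
    n: int,
    seed: int,
    mean_volume_mL: float = 31.72,
    sd_volume_mL: float = 39.24,
    volume_range_mL: tuple[float, float] = (3.0, 240.0),
    shape_mix: Optional[Mapping[str, float]] = None,
    spacing_range_mm: tuple[float, float] = (0.8, 1.2),
    thickness_range_mm: tuple[float, float] = (2.0, 5.0),
) -> list[Phantom]:
    """Seeded cohort of phantoms with log-normal target volumes.

    The default distribution is moment-matched to the study cohort (mean
    31.72 mL, SD 39.24 mL) and truncated to its printed volume range.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    if mean_volume_mL <= 0 or sd_volume_mL <= 0:
        raise ValueError("volume distribution parameters must be positive")
    if shape_mix is None:
        shape_mix = {"ellipsoid": 0.4, "lens": 0.4, "irregular": 0.2}
    names = list(shape_mix)
    probs = np.array([shape_mix[k] for k in names], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("invalid shape mix")
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    mu, sigma = _lognormal_params(mean_volume_mL, sd_volume_mL)
    phantoms: list[Phantom] = []
    while len(phantoms) < n:
        vol = float(rng.lognormal(mu, sigma))
        if not volume_range_mL[0] <= vol <= volume_range_mL[1]:
            continue
        shape = names[int(rng.choice(len(names), p=probs))]
        spacing = float(rng.uniform(*spacing_range_mm))
        thickness = float(rng.uniform(*thickness_range_mm))
        if shape == "lens":
            t = float(rng.uniform(0.8, 1.6))  # d / R
            R = (12.0 * vol * 1000.0 / (math.pi * (4 + t) * (2 - t) ** 2)) ** (1 / 3)
            spec = PhantomSpec(
                shape="lens", radius_mm=R, separation_mm=t * R,
                spacing_mm=spacing, thickness_mm=thickness,
                seed=int(rng.integers(2**31)),
            )
        else:
            q1 = float(rng.uniform(0.55, 0.9))   # b/a
            q2 = float(rng.uniform(0.4, 0.75))   # c/a
            a = (3.0 * vol * 1000.0 / (4.0 * math.pi * q1 * q2)) ** (1 / 3)
            spec = PhantomSpec(
                shape=shape, semi_axes_mm=(a, q1 * a, q2 * a),
                spacing_mm=spacing, thickness_mm=thickness,
                perturbation=float(rng.uniform(0.05, 0.2)) if shape == "irregular" else 0.0,
                seed=int(rng.integers(2**31)),
            )
        phantoms.append(make_phantom(spec))
    return phantoms


def _fixture_bytes() -> bytes:
    ref = resources.files("hemvol.data").joinpath("study_cases.csv")
    return ref.read_bytes()


def fixture_dataframe() -> pd.DataFrame:
    """The packaged 53-case study table, checksum-verified."""
    raw = _fixture_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != FIXTURE_SHA256:
        raise ValueError("study fixture is corrupted (checksum mismatch)")
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw))
    if list(df.columns) != FIXTURE_COLUMNS or len(df) != 53:
        raise ValueError("study fixture is corrupted (unexpected layout)")
    return df


def load_study_fixture() -> list[CaseRecord]:
    """The 53 study cases as case records.

    Products are reconstructed from the traditional columns by inverting the
    half-product definition (product = 2 x variation value); individual
    lengths are not recoverable from the published table and stay ``None``.
    """
    df = fixture_dataframe()
    records: list[CaseRecord] = []
    for row in df.itertuples(index=False):
        products = {
            "A1B1C0": 2.0 * row.v1,
            "A1B1C1": 2.0 * row.v2,
            "A2B2C0": 2.0 * row.v3,
            "A2B2C1": 2.0 * row.v4,
        }
        estimates = {
            name: float(getattr(row, f"v{name}"))
            for name in _VARIATION_NAMES
        }
        records.append(
            CaseRecord(
                case_id=str(row.case_id),
                planimetry_mL=float(row.planimetry_mL),
                products_mL=products,
                estimates_mL=estimates,
                sex=row.sex,
                age=int(row.age),
            )
        )
    return records
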