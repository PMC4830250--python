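"""Mask volume I/O and report writing.

NIfTI is the primary mask carrier: in-plane spacing comes from the first
two header zooms and the slice thickness from the third, each overridable.
Reports are a per-case CSV (one row per case, study-table layout plus the
four products) and a summary table in CSV or JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .estimators import CaseRecord
from .evaluation import EvaluationSummary
from .synthetic import Phantom

logger = logging.getLogger("hemvol")

__all__ = [
    "read_mask_volume",
    "write_phantom",
    "write_case_report",
    "write_summary",
    "bland_altman_plot",
]


def read_mask_volume(
    path: str | Path,
    label: Optional[int] = None,
    spacing_override: Optional[tuple[float, float]] = None,
    thickness_override: Optional[float] = None,
) -> tuple[np.ndarray, tuple[float, float], float]:
    """Load a 3-D binary mask with its geometry.

    Returns ``(mask, (spacing_row, spacing_col), thickness_mm)`` with axial
    slices along the third array axis.  Any nonzero voxel is lesion unless a
    specific ``label`` is requested.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"mask volume must be 3-D, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel spacing in header: {zooms}")
    spacing = (float(zooms[0]), float(zooms[1]))
    thickness = float(zooms[2])
    if spacing_override is not None:
        logger.info("overriding in-plane spacing %s -> %s", spacing, spacing_override)
        spacing = (float(spacing_override[0]), float(spacing_override[1]))
    if thickness_override is not None:
        logger.info("overriding slice thickness %s -> %s", thickness, thickness_override)
        thickness = float(thickness_override)
    if thickness > 5.0:
        logger.warning(
            "slice thickness %.2f mm exceeds 5 mm; such scans were excluded "
            "from the validation study", thickness,
        )
    mask = (data == label) if label is not None else (data != 0)
    return mask, spacing, thickness


def write_phantom(phantom: Phantom, path: str | Path) -> Path:
    """Write a phantom mask to NIfTI with a JSON sidecar holding the truth."""
    path = Path(path)
    affine = np.diag([phantom.spacing_row, phantom.spacing_col, phantom.thickness_mm, 1.0])
    img = nib.Nifti1Image(phantom.mask.astype(np.uint8), affine)
    img.header.set_zooms((phantom.spacing_row, phantom.spacing_col, phantom.thickness_mm))
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    spec = phantom.spec
    payload = {
        "true_volume_mL": phantom.true_volume_mL,
        "shape": spec.shape,
        "semi_axes_mm": list(spec.semi_axes_mm),
        "radius_mm": spec.radius_mm,
        "separation_mm": spec.separation_mm,
        "spacing_mm": spec.spacing_mm,
        "thickness_mm": spec.thickness_mm,
        "perturbation": spec.perturbation,
        "seed": spec.seed,
    }
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def records_dataframe(records: Sequence[CaseRecord]) -> pd.DataFrame:
    if not records:
        raise ValueError("no case records to write")
    return pd.DataFrame([rec.to_row() for rec in records])


def write_case_report(
    records: Sequence[CaseRecord],
    out_path: str | Path,
) -> Path:
    """Per-case CSV (study-table layout plus products); byte-stable."""
    df = records_dataframe(records)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_path, index=False, float_format="%.6g")
    return out_path


def write_summary(
    summary: EvaluationSummary,
    out_path: str | Path,
    fmt: str = "csv",
) -> Path:
    """Summary table (one row per variation) as CSV or JSON."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    rows = summary.to_rows()
    if fmt == "csv":
        pd.DataFrame(rows).to_csv(out_path, index=False, float_format="%.6g")
    elif fmt == "json":
        payload = {
            "n_cases": summary.n_cases,
            "reference_mean_mL": summary.reference_mean_mL,
            "reference_sd_mL": summary.reference_sd_mL,
            "tie_policy": summary.tie_policy,
            "variations": rows,
        }
        out_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown summary format {fmt!r}")
    return out_path


def bland_altman_plot(summary: EvaluationSummary, name: str, out_path: str | Path) -> Path:
    """Render one variation's Bland-Altman payload to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    row = summary.rows[name]
    ag = row.agreement
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ag.pair_means_mL, ag.differences_mL, s=18, alpha=0.8)
    for y, style in ((ag.mean_difference_mL, "-"), (ag.loa_low_mL, "--"), (ag.loa_high_mL, "--")):
        ax.axhline(y, linestyle=style, color="grey", linewidth=1)
    ax.set_xlabel("Mean of estimate and planimetry (mL)")
    ax.set_ylabel("Estimate - planimetry (mL)")
    ax.set_title(f"Variation {name}")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path
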