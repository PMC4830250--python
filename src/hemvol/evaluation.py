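"""Accuracy scoring of volume estimators against planimetry.

Implements the cohort summary: per-variation mean/SD/range of estimates,
Levene-gated independent t-test against the reference, closest-value
counts (intra-group and overall), absolute percentage deviations with
<10% / 10-20% / >20% binning, and Bland-Altman limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .estimators import CaseRecord, VariationSpec, builtin_variations

__all__ = [
    "DeviationStats",
    "ClosestValueCounts",
    "AgreementStats",
    "VariationSummary",
    "EvaluationSummary",
    "percentage_deviation",
    "closest_value_counts",
    "deviation_bins",
    "compare_means",
    "bland_altman",
    "summarize_cohort",
]

#: differences closer than this are treated as exact ties when ranking
#: variations per case (absorbs float subtraction noise on rounded inputs)
TIE_TOLERANCE_ML = 1e-9

DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "traditional": ("1", "2", "3", "4"),
    "new": ("1p", "2p", "3p", "4p"),
}


def percentage_deviation(estimate: float, reference: float) -> float:
    """Absolute deviation from the reference, as a percentage of it."""
    if reference <= 0:
        raise ValueError("reference volume must be positive")
    return abs(estimate - reference) / reference * 100.0


@dataclass(frozen=True)
class DeviationStats:
    per_case_deviation_pct: tuple[float, ...]
    mean_pct: float
    sd_pct: float
    min_pct: float
    max_pct: float
    bin_counts: tuple[int, int, int]  # <10%, 10-20%, >20%

    @classmethod
    def from_columns(cls, estimates: Sequence[float], references: Sequence[float]):
        dev = tuple(
            percentage_deviation(e, r) for e, r in zip(estimates, references, strict=True)
        )
        arr = np.array(dev)
        return cls(
            per_case_deviation_pct=dev,
            mean_pct=float(arr.mean()),
            sd_pct=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            min_pct=float(arr.min()),
            max_pct=float(arr.max()),
            bin_counts=deviation_bins(dev),
        )


def deviation_bins(deviations: Sequence[float]) -> tuple[int, int, int]:
    """Counts in the <10%, 10-20% (inclusive) and >20% deviation bins."""
    arr = np.asarray(deviations, dtype=float)
    if arr.size == 0:
        raise ValueError("no deviations to bin")
    if (arr < 0).any():
        raise ValueError("deviations cannot be negative")
    low = int((arr < 10).sum())
    mid = int(((arr >= 10) & (arr <= 20)).sum())
    high = int((arr > 20).sum())
    return (low, mid, high)


@dataclass(frozen=True)
class ClosestValueCounts:
    per_variation_count: dict[str, int]
    scope: str
    tie_policy: str

    def __post_init__(self) -> None:
        if self.tie_policy not in ("earlier", "later"):
            raise ValueError(f"unknown tie policy {self.tie_policy!r}")


def closest_value_counts(
    estimates: Mapping[str, Sequence[float]],
    references: Sequence[float],
    tie_policy: str = "earlier",
    scope: str = "overall",
    tie_tolerance: float = TIE_TOLERANCE_ML,
) -> ClosestValueCounts:
    """Per-case wins: which variation lands closest to the reference.

    Exact ties (absolute differences within ``tie_tolerance``) go to the
    earlier-listed variation by default, or the later-listed one under
    ``tie_policy="later"``.
    """
    names = list(estimates)
    if not names:
        raise ValueError("no estimate columns given")
    ref = np.asarray(references, dtype=float)
    cols = np.column_stack([np.asarray(estimates[n], dtype=float) for n in names])
    if cols.shape[0] != ref.shape[0]:
        raise ValueError("estimate columns and references differ in length")
    if ref.size == 0:
        raise ValueError("empty input")
    counts = dict.fromkeys(names, 0)
    diffs = np.abs(cols - ref[:, None])
    for row in diffs:
        tied = np.flatnonzero(row <= row.min() + tie_tolerance)
        winner = tied[0] if tie_policy == "earlier" else tied[-1]
        counts[names[int(winner)]] += 1
    return ClosestValueCounts(counts, scope=scope, tie_policy=tie_policy)


def compare_means(
    estimates: Sequence[float],
    references: Sequence[float],
    alpha: float = 0.05,
) -> tuple[float, float, str]:
    """Levene-gated two-sided independent t-test.

    Levene's test (mean-centred) decides between the pooled-variance t-test
    (homogeneous variances, p > alpha) and Welch's t-test.  Returns
    ``(levene_p, t_p, variant)`` with variant in {"student", "welch"}.
    """
    a = np.asarray(estimates, dtype=float)
    b = np.asarray(references, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("both samples are constant; tests are undefined")
    levene_p = float(stats.levene(a, b, center="mean").pvalue)
    equal_var = levene_p > alpha
    t_p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return levene_p, t_p, "student" if equal_var else "welch"


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman agreement between estimates and the reference."""

    mean_difference_mL: float
    sd_difference_mL: float
    loa_low_mL: float
    loa_high_mL: float
    proportion_within_loa: float
    pair_means_mL: tuple[float, ...] = field(repr=False, default=())
    differences_mL: tuple[float, ...] = field(repr=False, default=())


def bland_altman(
    estimates: Sequence[float], references: Sequence[float]
) -> AgreementStats:
    """Mean difference, SD and 1.96-SD limits of agreement."""
    e = np.asarray(estimates, dtype=float)
    r = np.asarray(references, dtype=float)
    if e.shape != r.shape:
        raise ValueError("estimates and references differ in length")
    if len(e) < 2:
        raise ValueError("need at least 2 paired values")
    d = e - r
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(((d >= lo) & (d <= hi)).mean())
    return AgreementStats(
        mean_difference_mL=mean,
        sd_difference_mL=sd,
        loa_low_mL=lo,
        loa_high_mL=hi,
        proportion_within_loa=within,
        pair_means_mL=tuple((e + r) / 2.0),
        differences_mL=tuple(d),
    )


@dataclass(frozen=True)
class VariationSummary:
    """One row of the cohort summary table."""

    name: str
    formula: str
    mean_mL: float
    sd_mL: float
    min_mL: float
    max_mL: float
    levene_p: float
    t_p: float
    t_variant: str
    closest_intra: int
    closest_overall: int
    deviations: DeviationStats
    agreement: AgreementStats

    def to_row(self) -> dict[str, object]:
        b = self.deviations.bin_counts
        n = len(self.deviations.per_case_deviation_pct)
        return {
            "variation": self.name,
            "formula": self.formula,
            "estimated_mean_mL": self.mean_mL,
            "estimated_sd_mL": self.sd_mL,
            "estimated_min_mL": self.min_mL,
            "estimated_max_mL": self.max_mL,
            "p_value": self.t_p,
            "levene_p": self.levene_p,
            "closest_intra_group": self.closest_intra,
            "closest_overall": self.closest_overall,
            "dev_lt10_n": b[0],
            "dev_10_20_n": b[1],
            "dev_gt20_n": b[2],
            "dev_lt10_pct": b[0] / n * 100.0,
            "dev_10_20_pct": b[1] / n * 100.0,
            "dev_gt20_pct": b[2] / n * 100.0,
            "dev_mean_pct": self.deviations.mean_pct,
            "dev_sd_pct": self.deviations.sd_pct,
            "dev_min_pct": self.deviations.min_pct,
            "dev_max_pct": self.deviations.max_pct,
            "ba_mean_diff_mL": self.agreement.mean_difference_mL,
            "ba_loa_low_mL": self.agreement.loa_low_mL,
            "ba_loa_high_mL": self.agreement.loa_high_mL,
        }


@dataclass(frozen=True)
class EvaluationSummary:
    rows: dict[str, VariationSummary]
    n_cases: int
    reference_mean_mL: float
    reference_sd_mL: float
    tie_policy: str

    def to_rows(self) -> list[dict[str, object]]:
        return [r.to_row() for r in self.rows.values()]


def summarize_cohort(
    records: Sequence[CaseRecord],
    registry: Optional[Mapping[str, VariationSpec]] = None,
    groups: Optional[Mapping[str, Sequence[str]]] = None,
    tie_policy: str = "earlier",
    alpha: float = 0.05,
) -> EvaluationSummary:
    """Full accuracy summary over a cohort of measured cases."""
    if len(records) < 3:
        raise ValueError("need at least 3 cases to summarize")
    if registry is None:
        registry = builtin_variations()
    if groups is None:
        groups = {k: v for k, v in DEFAULT_GROUPS.items() if set(v) <= set(registry)}

    ref = np.array([rec.planimetry_mL for rec in records], dtype=float)
    columns: dict[str, np.ndarray] = {}
    for name in registry:
        col = [rec.estimates_mL[name] for rec in records]
        columns[name] = np.asarray(col, dtype=float)

    overall = closest_value_counts(columns, ref, tie_policy, scope="overall")
    intra: dict[str, int] = {}
    for member_names in groups.values():
        sub = {n: columns[n] for n in member_names}
        got = closest_value_counts(sub, ref, tie_policy, scope="intra-group")
        intra.update(got.per_variation_count)

    rows: dict[str, VariationSummary] = {}
    for name, spec in registry.items():
        col = columns[name]
        levene_p, t_p, variant = compare_means(col, ref, alpha=alpha)
        rows[name] = VariationSummary(
            name=name,
            formula=spec.formula,
            mean_mL=float(col.mean()),
            sd_mL=float(col.std(ddof=1)),
            min_mL=float(col.min()),
            max_mL=float(col.max()),
            levene_p=levene_p,
            t_p=t_p,
            t_variant=variant,
            closest_intra=intra.get(name, 0),
            closest_overall=overall.per_variation_count[name],
            deviations=DeviationStats.from_columns(col, ref),
            agreement=bland_altman(col, ref),
        )
    return EvaluationSummary(
        rows=rows,
        n_cases=len(records),
        reference_mean_mL=float(ref.mean()),
        reference_sd_mL=float(ref.std(ddof=1)),
        tie_policy=tie_policy,
    )
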