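"""Inter-method reliability statistics for paired co-registrations.

Two co-registration methods applied to the same subjects yield, per
subject, an error (mm) and six decomposed transform parameters.  Their
agreement is quantified with the intra-class correlation ICC(3,1): the
two-way mixed-effects, consistency, single-measure ICC of Shrout & Fleiss,

    ICC(3,1) = (MS_B - MS_E) / (MS_B + (k - 1) MS_E),

where MS_B is the between-subjects mean square and MS_E the residual mean
square of the subjects x methods two-way ANOVA.  Being a consistency ICC
it ignores systematic per-method offsets.  Qualitative interpretation
follows Cicchetti's bands (poor < 0.40 <= fair < 0.60 <= good < 0.75 <=
excellent).  The error comparison additionally reports the Pearson
correlation between methods, its Cohen's d conversion
d = 2r / sqrt(1 - r^2), and an ICC recomputed after excluding subjects
whose second-method error exceeds the 2 mm quality heuristic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coregister import CoregResult
from .transforms import decompose

__all__ = [
    "icc_3_1",
    "icc_2_1",
    "pearson_r",
    "cohens_d_from_r",
    "classify_icc",
    "compare_methods",
    "MeasureComparison",
    "ComparisonReport",
]

MEASURES = ("error", "tx", "ty", "tz", "pitch", "roll", "yaw")


def _anova_mean_squares(table: np.ndarray):
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("ratings table must be (n >= 3) x (k >= 2)")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings table has missing/non-finite cells")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand, atol=1e-300, rtol=0.0) or np.ptp(x) == 0:
        raise ZeroDivisionError("zero total variance: ICC undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_b = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return n, k, ms_b, ms_c, ms_e


def icc_3_1(table: np.ndarray) -> float:
    """ICC(3,1): two-way mixed, consistency, single measures.

    ``table`` is an (n subjects, k methods) matrix of one measure.  Raises
    ``ZeroDivisionError`` when all cells are identical (undefined value).
    """
    n, k, ms_b, _, ms_e = _anova_mean_squares(table)
    denom = ms_b + (k - 1) * ms_e
    if denom == 0:
        raise ZeroDivisionError("zero total variance: ICC undefined")
    return float((ms_b - ms_e) / denom)


def icc_2_1(table: np.ndarray) -> float:
    """ICC(2,1): two-way random, absolute agreement, single measures.

    Non-default sensitivity variant; unlike ICC(3,1) it penalizes
    systematic per-method offsets.
    """
    n, k, ms_b, ms_c, ms_e = _anova_mean_squares(table)
    denom = ms_b + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom == 0:
        raise ZeroDivisionError("zero total variance: ICC undefined")
    return float((ms_b - ms_e) / denom)


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-d vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroDivisionError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def cohens_d_from_r(r: float) -> float:
    """Convert a correlation to Cohen's d: ``d = 2 r / sqrt(1 - r^2)``."""
    if not np.isfinite(r) or abs(r) >= 1.0:
        raise ValueError(f"|r| must be < 1, got {r}")
    return float(2.0 * r / np.sqrt(1.0 - r * r))


def classify_icc(value: float) -> str:
    """Cicchetti qualitative band for an ICC value in [-1, 1].

    Bands: < 0.40 poor; [0.40, 0.60) fair; [0.60, 0.75) good;
    >= 0.75 excellent (boundaries belong to the higher band).
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"ICC must lie in [-1, 1], got {value}")
    if value < 0.40:
        return "poor"
    if value < 0.60:
        return "fair"
    if value < 0.75:
        return "good"
    return "excellent"


# ---------------------------------------------------------------------------
# full method comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasureComparison:
    """Paired summary of one measure across two methods (a, b)."""

    measure: str
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    mean_diff: float  #: mean of per-subject (b - a)
    sd_diff: float
    icc: float
    icc_band: str

    def to_dict(self) -> dict:
        d = {
            "measure": self.measure,
            "median_a": self.median_a, "iqr_a": list(self.iqr_a),
            "median_b": self.median_b, "iqr_b": list(self.iqr_b),
            "mean_diff": self.mean_diff, "sd_diff": self.sd_diff,
            "icc": self.icc, "icc_band": self.icc_band,
        }
        return d


@dataclass(frozen=True)
class ComparisonReport:
    """Inter-method comparison over a cohort.

    ``measures`` maps 'error', 'tx' ... 'yaw' to per-measure summaries.
    Error-specific extras: Pearson r between methods' errors (with its
    Cohen's d), the ICC after excluding subjects whose method-b error
    exceeds the quality threshold, and per-method correlations between
    error and headshape-point count (None when counts are unavailable).
    """

    n_subjects: int
    measures: dict
    error_pearson_r: float
    error_pearson_p: float
    error_cohens_d: float
    quality_threshold: float
    n_excluded: int
    icc_after_exclusion: float | None
    headshape_count_correlation_a: tuple[float, float] | None
    headshape_count_correlation_b: tuple[float, float] | None

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "n_subjects": self.n_subjects,
            "measures": {k: v.to_dict() for k, v in self.measures.items()},
            "error_pearson_r": self.error_pearson_r,
            "error_pearson_p": self.error_pearson_p,
            "error_cohens_d": self.error_cohens_d,
            "quality_threshold": self.quality_threshold,
            "n_excluded": self.n_excluded,
            "icc_after_exclusion": self.icc_after_exclusion,
            "headshape_count_correlation_a": self.headshape_count_correlation_a,
            "headshape_count_correlation_b": self.headshape_count_correlation_b,
        }

    def to_json(self, path: str | Path) -> None:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj
        with open(path, "w") as fh:
            json.dump(_clean(self.to_dict()), fh, indent=1)

    def to_frame(self) -> pd.DataFrame:
        """One row per measure, mirroring a translation/rotation summary table."""
        rows = []
        for name in MEASURES:
            m = self.measures[name]
            rows.append({
                "measure": name,
                "median_a": m.median_a,
                "iqr_a_low": m.iqr_a[0], "iqr_a_high": m.iqr_a[1],
                "median_b": m.median_b,
                "iqr_b_low": m.iqr_b[0], "iqr_b_high": m.iqr_b[1],
                "mean_diff": m.mean_diff, "sd_diff": m.sd_diff,
                "icc": m.icc, "icc_band": m.icc_band,
            })
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _iqr(v: np.ndarray) -> tuple[float, float]:
    return float(np.percentile(v, 25)), float(np.percentile(v, 75))


def _measure_table(results_a, results_b) -> dict[str, np.ndarray]:
    cols: dict[str, list] = {m: [] for m in MEASURES}
    for res_a, res_b in zip(results_a, results_b):
        pa = decompose(res_a.transform)
        pb = decompose(res_b.transform)
        cols["error"].append((res_a.median_error, res_b.median_error))
        for name in MEASURES[1:]:
            cols[name].append((getattr(pa, name), getattr(pb, name)))
    return {m: np.array(v) for m, v in cols.items()}


def compare_methods(results_a: Sequence[CoregResult],
                    results_b: Sequence[CoregResult],
                    headshape_counts: Sequence[int] | None = None,
                    quality_threshold: float = 2.0) -> ComparisonReport:
    """Build the full two-method comparison report.

    ``results_a`` and ``results_b`` are per-subject results from the two
    methods, same subjects in the same order (conventionally a = manual,
    b = automated, so the exclusion rule drops subjects with automated
    error above the quality threshold and ``mean_diff`` is automated
    minus manual).
    """
    if len(results_a) != len(results_b):
        raise ValueError("mismatched subject lists between methods")
    n = len(results_a)
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if headshape_counts is not None and len(headshape_counts) != n:
        raise ValueError("headshape_counts length does not match subjects")

    tables = _measure_table(results_a, results_b)
    measures = {}
    for name, tab in tables.items():
        a, b = tab[:, 0], tab[:, 1]
        try:
            icc = icc_3_1(tab)
            band = classify_icc(icc)
        except ZeroDivisionError:  # degenerate (constant) measure
            icc, band = float("nan"), "undefined"
        measures[name] = MeasureComparison(
            measure=name,
            median_a=float(np.median(a)), iqr_a=_iqr(a),
            median_b=float(np.median(b)), iqr_b=_iqr(b),
            mean_diff=float(np.mean(b - a)),
            sd_diff=float(np.std(b - a, ddof=1)),
            icc=icc, icc_band=band,
        )

    err = tables["error"]
    r, p = pearson_r(err[:, 0], err[:, 1])
    # r can hit +/-1 exactly (e.g. identical methods); the d conversion
    # then diverges, which we report as a signed infinity
    d = (float(np.sign(r) * np.inf) if abs(r) >= 1.0
         else cohens_d_from_r(r))

    keep = err[:, 1] <= quality_threshold  # exclusion on method-b error
    n_excluded = int(np.sum(~keep))
    icc_excl = None
    if keep.sum() >= 3:
        try:
            icc_excl = icc_3_1(err[keep])
        except ZeroDivisionError:
            icc_excl = None

    corr_a = corr_b = None
    if headshape_counts is not None:
        counts = np.asarray(headshape_counts, dtype=float)
        corr_a = pearson_r(err[:, 0], counts)
        corr_b = pearson_r(err[:, 1], counts)

    return ComparisonReport(
        n_subjects=n, measures=measures,
        error_pearson_r=r, error_pearson_p=p, error_cohens_d=d,
        quality_threshold=quality_threshold, n_excluded=n_excluded,
        icc_after_exclusion=icc_excl,
        headshape_count_correlation_a=corr_a,
        headshape_count_correlation_b=corr_b,
    )
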