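"""Concordance statistics between reduced-dose and reference failure loads.

Per dose condition, the paired per-subject failure loads (reference =
full-dose full-view) are compared with:

* ordinary least squares of reduced on reference, with R^2 the squared
  Pearson correlation;
* RMSCV — the root mean square of per-subject two-point coefficients of
  variation, ``CV_i = (|ref_i - red_i| / sqrt(2)) / mean_i``, in percent
  (the convention of densitometric precision studies);
* Bland-Altman bias and 1.96-SD limits of agreement on differences
  ``d_i = reference_i - reduced_i`` (so dose-induced overestimation shows
  up as a negative bias);
* a two-sided paired t-test.

The identity ``bias == mean(reference) - mean(reduced)`` is exact and is
what links per-condition mean failure loads to the reported biases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcordanceResult",
    "linreg_r2",
    "rmscv",
    "bland_altman",
    "paired_test",
    "condition_summary",
]


@dataclass(frozen=True)
class ConcordanceResult:
    """Agreement of one reduced-dose condition with the reference."""

    condition: str
    n: int
    r2: float
    slope: float
    intercept: float
    rmscv_pct: float
    bias_n: float
    loa_low_n: float
    loa_high_n: float
    p_paired: float


def _pairs(reference, reduced) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(reference, dtype=np.float64)
    red = np.asarray(reduced, dtype=np.float64)
    if ref.shape != red.shape or ref.ndim != 1:
        raise ValueError("reference and reduced must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(red))):
        raise ValueError("failure loads must be finite")
    return ref, red


def linreg_r2(reference, reduced) -> tuple[float, float, float]:
    """OLS of reduced on reference: returns (R^2, slope, intercept)."""
    ref, red = _pairs(reference, reduced)
    if ref.size < 3:
        raise ValueError("need at least 3 pairs for a regression")
    if np.ptp(ref) == 0:
        raise ValueError("reference values have zero variance")
    res = stats.linregress(ref, red)
    return float(res.rvalue**2), float(res.slope), float(res.intercept)


def rmscv(reference, reduced) -> float:
    """Root-mean-square two-point coefficient of variation, in percent."""
    ref, red = _pairs(reference, reduced)
    if ref.size < 1:
        raise ValueError("need at least one pair")
    means = 0.5 * (ref + red)
    if np.any(means <= 0):
        raise ValueError("pair means must be positive for a CV")
    cv = (np.abs(ref - red) / np.sqrt(2.0)) / means
    return float(100.0 * np.sqrt(np.mean(cv**2)))


def bland_altman(reference, reduced) -> tuple[float, float, float]:
    """Bias and limits of agreement of d = reference - reduced.

    Returns (bias, loa_low, loa_high) with LoA = bias -/+ 1.96 * sd(d)
    (sample sd, n-1).  The sign convention makes overestimation at reduced
    dose a negative bias; magnitudes are what get reported.
    """
    ref, red = _pairs(reference, reduced)
    if ref.size < 2:
        raise ValueError("need at least 2 pairs")
    d = ref - red
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def paired_test(reference, reduced) -> float:
    """Two-sided paired t-test p-value; zero-variance differences give p = 1."""
    ref, red = _pairs(reference, reduced)
    if ref.size < 3:
        raise ValueError("need at least 3 pairs")
    d = ref - red
    if np.ptp(d) == 0:
        if not np.allclose(d, 0):
            warnings.warn("constant nonzero differences: p = 1 by convention", stacklevel=2)
        return 1.0
    return float(stats.ttest_rel(ref, red).pvalue)


def condition_summary(
    results: pd.DataFrame,
    reference_condition: str = "D100P100",
) -> pd.DataFrame:
    """Per-condition concordance table versus the reference condition.

    ``results`` needs columns ``subject``, ``condition``,
    ``failure_load_n`` (and optionally ``bmd_mgcc``).  Every condition must
    cover exactly the reference's subject set (pairing contract).
    """
    required = {"subject", "condition", "failure_load_n"}
    if not required.issubset(results.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    conditions = list(dict.fromkeys(results["condition"]))
    if reference_condition not in conditions:
        raise ValueError(f"reference condition {reference_condition!r} missing from results")
    ref_df = results[results["condition"] == reference_condition].set_index("subject")
    if ref_df.index.duplicated().any():
        raise ValueError("duplicate subjects within the reference condition")
    rows = []
    for cond in conditions:
        sub = results[results["condition"] == cond].set_index("subject")
        if set(sub.index) != set(ref_df.index) or sub.index.duplicated().any():
            raise ValueError(f"condition {cond!r} does not pair 1:1 with the reference subjects")
        red = sub.loc[ref_df.index, "failure_load_n"].to_numpy()
        ref = ref_df["failure_load_n"].to_numpy()
        r2, slope, intercept = linreg_r2(ref, red)
        bias, lo, hi = bland_altman(ref, red)
        row = {
            "condition": cond,
            "n": len(ref),
            "fl_mean_n": float(red.mean()),
            "fl_sd_n": float(red.std(ddof=1)),
            "r2": r2,
            "slope": slope,
            "intercept": intercept,
            "rmscv_pct": rmscv(ref, red),
            "bias_n": bias,
            "loa_low_n": lo,
            "loa_high_n": hi,
            "p_paired": paired_test(ref, red),
        }
        if "bmd_mgcc" in results.columns:
            bmd = sub.loc[ref_df.index, "bmd_mgcc"].to_numpy()
            row["bmd_mean_mgcc"] = float(bmd.mean())
            row["bmd_sd_mgcc"] = float(bmd.std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)
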