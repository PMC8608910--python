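"""Agreement and error statistics for clearance/concentration validation.

Implements the usual method-comparison toolbox for measured-GFR work:
RMSE and bias, Lin's concordance correlation coefficient (CCC) with the
conventional category labels, the empirical relative total deviation index
(TDI) as a function of coverage probability (CP), and the P10/P30
percentages of subjects within 10%/30% of the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetricsError",
    "rmse",
    "lin_ccc",
    "ccc_category",
    "tdi_curve",
    "p_within",
    "ConcordanceSummary",
    "concordance_summary",
    "bland_altman_table",
]

DEFAULT_CPS = tuple(np.round(np.arange(0.50, 1.0, 0.05), 2)) + (0.99,)


class MetricsError(ValueError):
    pass


def _pair(pred, ref) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise MetricsError(f"vectors must be 1-D and equal length, got {pred.shape} vs {ref.shape}")
    if pred.size == 0:
        raise MetricsError("empty vectors")
    return pred, ref


def rmse(pred, ref) -> tuple[float, float]:
    """Root-mean-squared error and bias (mean of pred - ref)."""
    pred, ref = _pair(pred, ref)
    d = pred - ref
    return float(np.sqrt(np.mean(d**2))), float(np.mean(d))


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    Moment form ``2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)`` with
    population (1/n) moment estimators.  Penalises both imprecision and
    location/scale shift; equals 1 only for exact agreement.
    """
    x, y = _pair(x, y)
    if x.size < 2:
        raise MetricsError("CCC needs at least two points")
    mx, my = x.mean(), y.mean()
    sxy = np.mean((x - mx) * (y - my))
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        # both vectors constant: perfect agreement iff identical constants
        return 1.0
    return float(2 * sxy / denom)


def ccc_category(ccc: float) -> str:
    """Concordance label from the conventional cut-points.

    Left-closed bands: >= 0.99 almost perfect, [0.95, 0.99) substantial,
    [0.90, 0.95) moderate, < 0.90 poor.
    """
    if not -1.0 <= ccc <= 1.0:
        raise MetricsError(f"CCC must lie in [-1, 1], got {ccc}")
    if ccc >= 0.99:
        return "almost perfect"
    if ccc >= 0.95:
        return "substantial"
    if ccc >= 0.90:
        return "moderate"
    return "poor"


def _relative_differences(est, ref) -> np.ndarray:
    est, ref = _pair(est, ref)
    if np.any(ref == 0):
        raise MetricsError("reference values must be nonzero for relative differences")
    return np.abs(est - ref) / np.abs(ref)


def tdi_curve(est, ref, cps=DEFAULT_CPS) -> pd.DataFrame:
    """Empirical relative TDI (%) per coverage probability.

    TDI at CP = p is the p-quantile (linear interpolation between order
    statistics) of |est - ref| / |ref|, times 100.  Returned as a DataFrame
    with columns ``cp`` and ``tdi_pct``, non-decreasing in cp.
    """
    rel = _relative_differences(est, ref)
    cps = np.asarray(cps, dtype=float)
    if np.any((cps < 0) | (cps > 1)):
        raise MetricsError("coverage probabilities must lie in [0, 1]")
    tdi = 100.0 * np.quantile(rel, cps, method="linear")
    return pd.DataFrame({"cp": cps, "tdi_pct": tdi})


def p_within(est, ref, threshold_pct: float) -> float:
    """Percentage of subjects with |est - ref| / |ref| <= threshold_pct / 100."""
    rel = _relative_differences(est, ref)
    return float(100.0 * np.mean(rel <= threshold_pct / 100.0))


@dataclass(frozen=True)
class ConcordanceSummary:
    """Full agreement report for one estimator/reference pairing."""

    ccc: float
    ccc_category: str
    tdi_curve: pd.DataFrame
    tdi90: float
    p10: float
    p30: float
    rmse: float
    bias: float
    n: int

    def meets_tdi_goal(self, goal_pct: float = 10.0) -> bool:
        """Whether TDI at 90% coverage is at or below the target (default 10%)."""
        return self.tdi90 <= goal_pct

    def as_dict(self) -> dict:
        return {
            "ccc": self.ccc,
            "ccc_category": self.ccc_category,
            "tdi90": self.tdi90,
            "p10": self.p10,
            "p30": self.p30,
            "rmse": self.rmse,
            "bias": self.bias,
            "n": self.n,
        }


def concordance_summary(est, ref, cps=DEFAULT_CPS) -> ConcordanceSummary:
    est, ref = _pair(est, ref)
    curve = tdi_curve(est, ref, cps)
    ccc = lin_ccc(est, ref)
    r, b = rmse(est, ref)
    tdi90 = float(100.0 * np.quantile(_relative_differences(est, ref), 0.90))
    return ConcordanceSummary(
        ccc=ccc,
        ccc_category=ccc_category(ccc),
        tdi_curve=curve,
        tdi90=tdi90,
        p10=p_within(est, ref, 10.0),
        p30=p_within(est, ref, 30.0),
        rmse=r,
        bias=b,
        n=int(est.size),
    )


def bland_altman_table(est, ref) -> pd.DataFrame:
    """Pairwise (mean, difference) table for Bland-Altman style plots."""
    est, ref = _pair(est, ref)
    return pd.DataFrame({"mean": (est + ref) / 2.0, "difference": est - ref})
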