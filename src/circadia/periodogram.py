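"""Chi-square (Sokolove-Bushell) periodogram for circadian rhythm detection.

For a trial period ``P`` spanning ``K`` phase columns the statistic is
the between-column sum of squares of the folded series over the overall
variance estimate,

    Qp = N * sum_h n_h (xbar_h - xbar)^2 / sum_i (x_i - xbar)^2

where ``xbar_h`` are the column means, ``n_h`` the number of points in
column ``h`` and ``N`` the number of data points.  A perfectly periodic
series gives Qp = N; under the white-noise null Qp is asymptotically
chi-square with ``K - 1`` degrees of freedom, which gives the P = 0.05
significance line.  Rhythm strength ("power", %V) is the variance
percentage ``Qp * 100 / N`` at the dominant period, bounded by 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ActivitySeries

__all__ = ["Periodogram", "chi2_periodogram", "normalized_power", "estimate_period"]


@dataclass
class Periodogram:
    """Chi-square periodogram over a grid of trial periods (hours)."""

    trial_periods: np.ndarray  # hours, strictly increasing
    Qp: np.ndarray
    sig_line: np.ndarray  # chi2 0.95 quantile, df = K-1, per trial period
    power_pct: np.ndarray  # Qp * 100 / N
    N: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.trial_periods) <= 0):
            raise ValueError("trial-period grid must be strictly increasing")
        if np.any(self.Qp < 0):
            raise ValueError("Qp must be non-negative")


def _fold_columns(n_bins: int, bin_min: float, period_h: float):
    """Column index of each bin when folding at ``period_h``.

    ``K = round(P / bin_min)`` columns; bin i (start time ``i * bin_min``)
    goes to column ``floor(((t mod P) / P) * K)``.  Trailing partial
    cycles fold in like any other bins.
    """
    p_min = period_h * 60.0
    k = int(round(p_min / bin_min))
    t = np.arange(n_bins) * bin_min
    # small epsilon guards against FP landing just below an exact integer
    cols = np.floor((t % p_min) * (k / p_min) + 1e-9).astype(np.intp)
    np.clip(cols, 0, k - 1, out=cols)
    return cols, k


def chi2_periodogram(
    series: ActivitySeries,
    p_min: float = 20.0,
    p_max: float = 31.0,
    step_min: float = 3.0,
    include_partial: bool = True,
    alpha: float = 0.05,
) -> Periodogram:
    """Chi-square periodogram of an activity series.

    Parameters
    ----------
    p_min, p_max
        Trial-period range in hours (default 20-31 h).
    step_min
        Grid step in minutes (default 3).
    include_partial
        Include bins from the trailing partial cycle in the column means
        (default); if False, each trial period uses only whole cycles.
    alpha
        Significance level of the chi-square line (default 0.05).
    """
    x = np.asarray(series.counts, dtype=float)
    n = x.size
    if n * series.bin_min < 2 * p_max * 60.0:
        raise ValueError("series must span at least twice the longest trial period")
    periods = np.round(
        np.arange(p_min * 60.0, p_max * 60.0 + step_min / 2.0, step_min) / step_min
    ) * step_min / 60.0

    qp = np.empty(periods.size)
    sig = np.empty(periods.size)
    denom_all = float(np.sum((x - x.mean()) ** 2))
    constant = denom_all == 0.0
    if constant:
        warnings.warn("constant series: Qp defined as 0 at every trial period")
    for j, p in enumerate(periods):
        cols, k = _fold_columns(n, series.bin_min, p)
        if include_partial:
            xi, ci = x, cols
        else:
            n_whole = (n * series.bin_min // (p * 60.0)) * p * 60.0 / series.bin_min
            n_whole = int(n_whole)
            xi, ci = x[:n_whole], cols[:n_whole]
        ni = xi.size
        sig[j] = stats.chi2.ppf(1.0 - alpha, df=k - 1)
        if constant or ni == 0:
            qp[j] = 0.0
            continue
        mean = xi.mean()
        denom = float(np.sum((xi - mean) ** 2))
        if denom == 0.0:
            qp[j] = 0.0
            continue
        counts = np.bincount(ci, minlength=k)
        sums = np.bincount(ci, weights=xi, minlength=k)
        occupied = counts > 0
        col_means = sums[occupied] / counts[occupied]
        between_ss = float(np.sum(counts[occupied] * (col_means - mean) ** 2))
        qp[j] = ni * between_ss / denom
    return Periodogram(
        trial_periods=periods, Qp=qp, sig_line=sig, power_pct=qp * 100.0 / n, N=n
    )


def estimate_period(pg: Periodogram):
    """Trial period (h) maximising Qp among supra-significance periods.

    Returns ``None`` when no trial period exceeds its significance line.
    Exact ties resolve to the shorter period (argmax takes the first).
    """
    sig_mask = pg.Qp > pg.sig_line
    if not sig_mask.any():
        return None
    qp = np.where(sig_mask, pg.Qp, -np.inf)
    return float(pg.trial_periods[int(np.argmax(qp))])


def normalized_power(pg: Periodogram, significance_referenced: bool = False):
    """Rhythm power %V at the dominant period.

    Primary definition ``Qp(P*) * 100 / N``; with
    ``significance_referenced=True`` the chi-square significance line is
    subtracted first, ``(Qp(P*) - sig(P*)) * 100 / N``.  Returns 0.0 for a
    series with no supra-significance period.
    """
    p_star = estimate_period(pg)
    if p_star is None:
        return 0.0
    j = int(np.argmin(np.abs(pg.trial_periods - p_star)))
    qp = pg.Qp[j] - (pg.sig_line[j] if significance_referenced else 0.0)
    return float(qp * 100.0 / pg.N)
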