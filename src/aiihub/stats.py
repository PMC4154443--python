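"""Precision and size-distribution statistics.

Coefficient-of-variation precision analysis of synaptic sampling, the
single-outlier CV argument, pooled-variance t-tests from summary statistics,
a two-sample Kolmogorov-Smirnov test with the small-sample corrected
asymptotic p-value, percent differences, and 25-nm size histograms.

Sample standard deviations use the n-1 convention throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PrecisionReport",
    "GJSizeStats",
    "cv",
    "precision_ratio",
    "outlier_sds_to_reach_cv",
    "t_from_summary",
    "ks_two_sample",
    "percent_difference",
    "size_histogram",
    "precision_report",
]


@dataclass
class PrecisionReport:
    """Sampling precision of one counting unit (cells or ribbons)."""

    unit: str
    n: int
    mean: float
    sd: float  # sample SD, n-1

    @property
    def cv(self) -> float:
        return cv(self.mean, self.sd)


def precision_report(unit: str, values) -> PrecisionReport:
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two values")
    return PrecisionReport(
        unit=unit,
        n=len(values),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
    )


def cv(mean: float, sd: float) -> float:
    """Coefficient of variation sd/mean (mean must be positive)."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return sd / mean


def precision_ratio(cv_coarse: float, cv_fine: float) -> tuple[int, float]:
    """Fold improvement of the finer sampling unit: returns the ratio rounded
    to the nearest integer fold alongside the exact ratio."""
    if cv_fine <= 0:
        raise ValueError("reference CV must be positive")
    ratio = cv_coarse / cv_fine
    return round(ratio), ratio


def _append_stats(n: int, mean: float, sd: float, x: float
                  ) -> tuple[float, float]:
    """Mean and sample SD of the (n+1)-sample formed by appending ``x`` to a
    sample known only through its summary statistics."""
    ss = (n - 1) * sd * sd + n * mean * mean  # sum of squares
    new_sum = n * mean + x
    new_ss = ss + x * x
    new_mean = new_sum / (n + 1)
    var = (new_ss - (n + 1) * new_mean * new_mean) / n
    return new_mean, math.sqrt(max(var, 0.0))


def outlier_sds_to_reach_cv(
    n: int, mean: float, sd: float, target_cv: float, max_k: int = 10_000
) -> dict:
    """Smallest integer k such that appending one value ``mean + k*sd`` to an
    n-sample raises the (n+1)-sample CV to at least ``target_cv``.

    Returns a dict with ``k`` and a bracketing certificate (the CV at k and
    at k-1).  If the current CV already meets the target, returns k=0 with a
    note.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    current_cv = cv(mean, sd)
    if target_cv <= current_cv:
        return {"k": 0, "cv_at_k": current_cv, "cv_below": None,
                "note": "target CV not above current CV"}
    prev_cv = None
    for k in range(0, max_k + 1):
        m, s = _append_stats(n, mean, sd, mean + k * sd)
        this_cv = s / m if m > 0 else math.inf
        if this_cv >= target_cv:
            return {"k": k, "cv_at_k": this_cv, "cv_below": prev_cv,
                    "note": None}
        prev_cv = this_cv
    raise RuntimeError(f"no k <= {max_k} reaches the target CV")


def t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance (homoscedastic) two-tailed Student's t-test from
    summary statistics.  Returns (t, df, two-tailed p)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 * s1 + (n2 - 1) * s2 * s2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        return 0.0, df, 1.0
    t = (m1 - m2) / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return t, df, min(p, 1.0)


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(np.sort(x), grid, side="right") / len(x)
    cdf_y = np.searchsorted(np.sort(y), grid, side="right") / len(y)
    return float(np.abs(cdf_x - cdf_y).max())


def _kolmogorov_sf(lam: float, terms: int = 100) -> float:
    if lam <= 0:
        return 1.0
    total = 0.0
    for j in range(1, terms + 1):
        total += (-1.0) ** (j - 1) * math.exp(-2.0 * j * j * lam * lam)
    return min(max(2.0 * total, 0.0), 1.0)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum ECDF difference; the p-value uses the asymptotic
    Kolmogorov distribution with the small-sample correction
    lambda = (sqrt(ne) + 0.12 + 0.11/sqrt(ne)) * D, ne = n*m/(n+m).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    d = _ks_statistic(x, y)
    ne = len(x) * len(y) / (len(x) + len(y))
    lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * d
    return d, _kolmogorov_sf(lam)


def percent_difference(m_ref: float, m_other: float) -> float:
    """Percent by which ``m_other`` differs below ``m_ref``:
    100 * (m_ref - m_other) / m_ref."""
    if m_ref <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (m_ref - m_other) / m_ref


@dataclass
class GJSizeStats:
    """Size statistics of one gap-junction pairing class."""

    pairing: str
    n: int
    mean_nm: float
    sd_nm: float
    max_nm: float
    bin_edges_nm: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    cumulative_freq: np.ndarray = field(repr=False)


def size_histogram(
    diameters_nm, pairing: str = "", bin_nm: float = 25.0
) -> GJSizeStats:
    """Histogram of junction diameters in half-open ``bin_nm``-wide bins
    [k*bin, (k+1)*bin) with cumulative frequency normalized to 1."""
    d = np.asarray(diameters_nm, dtype=float)
    if len(d) == 0:
        raise ValueError("need at least one diameter")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    n_bins = int(math.floor(d.max() / bin_nm)) + 1
    edges = np.arange(0, n_bins + 1) * bin_nm
    counts, _ = np.histogram(d, bins=edges)
    cum = np.cumsum(counts) / len(d)
    return GJSizeStats(
        pairing=pairing,
        n=len(d),
        mean_nm=float(d.mean()),
        sd_nm=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        max_nm=float(d.max()),
        bin_edges_nm=edges,
        counts=counts,
        cumulative_freq=cum,
    )
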