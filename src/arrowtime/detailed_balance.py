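"""Broken detailed balance via time-lagged functional-connectivity asymmetry.

The lagged functional connectivity of a window is
``FC_ij(tau) = corr(x_i(t), x_j(t + tau))`` over the window's valid
overlap of length w - tau.  Under detailed balance the process is
statistically identical to its time reversal and FC(tau) is symmetric;
nonequilibrium dynamics produce an asymmetric part.  Globally we summarize
the asymmetric part as the mean absolute off-diagonal difference
|FC_ij - FC_ji| (the literal signed mean of FC - FC^T is identically zero
for any matrix, so only nonnegative functionals are informative; mean of
squares is available as an option).  Per node, the incoming flow is the
row sum F_in(i) = sum_j FC_ij(tau), the outgoing flow the column sum
F_out(i) = sum_j FC_ji(tau), and the node asymmetry the average of
|F_out(i) - F_in(i)| over windows (and participants).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from arrowtime.signal_io import ParcelTimeSeries


@dataclass
class LaggedFC:
    """One window's lagged correlation matrix with provenance."""

    matrix: np.ndarray
    tau: int
    participant_id: str = ""
    t_start: int = 0


def lagged_fc(window_values: np.ndarray, tau: int,
              region_ids=None) -> np.ndarray:
    """Pearson lagged correlation matrix of one (n_regions, w) window.

    Entry (i, j) correlates region i over t in [0, w - tau) with region j
    over t in [tau, w); both segments are demeaned and standardized within
    the window.  Raises for zero-variance regions, naming the region.
    """
    X = np.asarray(window_values, dtype=float)
    if X.ndim != 2:
        raise ValueError("window must be 2-D (regions x timepoints)")
    w = X.shape[1]
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if w <= tau + 2:
        raise ValueError(f"window length {w} too short for tau={tau}")
    A = X[:, :w - tau] if tau else X
    B = X[:, tau:] if tau else X
    for name, seg in (("leading", A), ("lagged", B)):
        sd = seg.std(axis=1)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            rid = region_ids[flat[0]] if region_ids is not None else flat[0]
            raise ValueError(
                f"zero variance in {name} segment of region {rid!r}"
            )
    A = (A - A.mean(axis=1, keepdims=True)) / A.std(axis=1, keepdims=True)
    B = (B - B.mean(axis=1, keepdims=True)) / B.std(axis=1, keepdims=True)
    return A @ B.T / A.shape[1]


def choose_tau(series: ParcelTimeSeries, decay_threshold: float = 0.5,
               max_tau: int = 10) -> int:
    """Smallest lag at which the mean regional autocorrelation has decayed.

    Returns the smallest tau >= 1 whose mean (over regions) lag-tau
    autocorrelation falls below ``decay_threshold``; if none does within
    ``max_tau``, warns and returns the cap.
    """
    X = series.values - series.values.mean(axis=1, keepdims=True)
    denom = (X * X).sum(axis=1)
    if np.any(denom == 0):
        raise ValueError("zero-variance region; cannot compute autocorrelation")
    for tau in range(1, max_tau + 1):
        ac = (X[:, :-tau] * X[:, tau:]).sum(axis=1) / denom
        if float(np.mean(ac)) < decay_threshold:
            return tau
    warnings.warn(
        f"autocorrelation never fell below {decay_threshold} within "
        f"max_tau={max_tau}; returning the cap", stacklevel=2)
    return max_tau


def global_asymmetry(fc: np.ndarray, mode: str = "abs") -> float:
    """Asymmetry of a lagged FC matrix: mean off-diagonal |FC_ij - FC_ji|.

    ``mode='squared'`` averages squared differences instead.  Exactly zero
    for symmetric matrices.
    """
    M = np.asarray(fc, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("FC matrix must be square")
    diff = M - M.T
    off = ~np.eye(M.shape[0], dtype=bool)
    if mode == "abs":
        return float(np.mean(np.abs(diff[off])))
    if mode == "squared":
        return float(np.mean(diff[off] ** 2))
    raise ValueError(f"unknown mode {mode!r}")


def node_flows(fc: np.ndarray) -> tuple:
    """(f_in, f_out): row sums and column sums of one lagged FC matrix.

    ``sum(f_out - f_in)`` is exactly zero for every matrix — both flows
    sum to the grand total.
    """
    M = np.asarray(fc, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("FC matrix must be square")
    return M.sum(axis=1), M.sum(axis=0)


def node_asymmetry(fc_windows) -> np.ndarray:
    """Per-region mean of |F_out(i) - F_in(i)| over windows (participants).

    ``fc_windows`` is an iterable of square lagged-FC matrices (or
    :class:`LaggedFC`); all must share the same size.
    """
    mats = [fc.matrix if isinstance(fc, LaggedFC) else np.asarray(fc)
            for fc in fc_windows]
    if not mats:
        raise ValueError("need at least one window")
    n = mats[0].shape[0]
    if any(m.shape != (n, n) for m in mats):
        raise ValueError("inconsistent FC matrix sizes across windows")
    acc = np.zeros(n)
    for M in mats:
        f_in, f_out = node_flows(M)
        acc += np.abs(f_out - f_in)
    return acc / len(mats)


@dataclass
class ReversibilityConditioned:
    """Low- vs high-reversibility comparison of detailed-balance breaking."""

    low_asym: np.ndarray
    high_asym: np.ndarray
    statistic: float
    p_value: float
    node_low: np.ndarray
    node_high: np.ndarray

    @property
    def node_delta(self) -> np.ndarray:
        """Change in node asymmetry from low- to high-reversibility windows."""
        return self.node_high - self.node_low


def condition_on_R(r_values, fc_windows, quantile: float = 0.25,
                   min_per_set: int = 10,
                   mode: str = "abs") -> ReversibilityConditioned:
    """Contrast FC asymmetry between low- and high-reversibility windows.

    ``r_values`` and ``fc_windows`` must align element-wise (same window
    order, e.g. matched on (participant, t_start) by the caller).  Windows
    with R below the lower ``quantile`` form the low set, above the upper
    1 - quantile the high set; the two global-asymmetry distributions are
    compared with a two-sided Wilcoxon rank-sum test, and per-node
    asymmetry is reported for both sets.
    """
    R = np.asarray(r_values, dtype=float)
    mats = [fc.matrix if isinstance(fc, LaggedFC) else np.asarray(fc)
            for fc in fc_windows]
    if len(R) != len(mats):
        raise ValueError("r_values and fc_windows lengths differ")
    if not (0 < quantile < 0.5):
        raise ValueError("quantile must be in (0, 0.5)")
    lo_thr = np.quantile(R, quantile)
    hi_thr = np.quantile(R, 1 - quantile)
    low_idx = np.flatnonzero(R < lo_thr)
    high_idx = np.flatnonzero(R > hi_thr)
    if len(low_idx) < min_per_set or len(high_idx) < min_per_set:
        raise ValueError(
            f"too few windows in low/high sets "
            f"({len(low_idx)}/{len(high_idx)}, need >= {min_per_set}); "
            "is the trace (near-)constant?"
        )
    low_asym = np.array([global_asymmetry(mats[i], mode) for i in low_idx])
    high_asym = np.array([global_asymmetry(mats[i], mode) for i in high_idx])
    res = sstats.ranksums(high_asym, low_asym)
    return ReversibilityConditioned(
        low_asym, high_asym, float(res.statistic), float(res.pvalue),
        node_asymmetry([mats[i] for i in low_idx]),
        node_asymmetry([mats[i] for i in high_idx]),
    )
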