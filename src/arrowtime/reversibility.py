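"""Per-window reversibility R(t), temporal aggregates, and group statistics.

For each sliding window the trained direction classifier is applied to the
forward window and to its time reversal, giving simplex outputs
``o_forward`` and ``o_backward``.  The reversibility index is

    R(t) = [(o_f(2) - o_f(1)) + (o_b(1) - o_b(2))] / 2,

clipped to 0 whenever either margin is negative (i.e. either pattern is
misclassified).  R(t) = 1 means both directions are classified with full
confidence — maximal nonreversibility; R(t) = 0 means the window is
indistinguishable from its reversal.  The per-participant mean of R(t) is
the nonreversibility summary; its standard deviation across windows is a
second-order nonstationarity measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from arrowtime.model import DirectionNet
from arrowtime.signal_io import ParcelTimeSeries
from arrowtime.windowing import reverse_window, slide_windows

_SIMPLEX_TOL = 1e-6


def _check_simplex(o, name: str) -> np.ndarray:
    o = np.asarray(o, dtype=float)
    if o.shape[-1] != 2:
        raise ValueError(f"{name} must have 2 entries")
    if np.any(o < -_SIMPLEX_TOL) or np.any(np.abs(o.sum(axis=-1) - 1) > _SIMPLEX_TOL):
        raise ValueError(f"{name} is not on the 2-simplex")
    return o


def window_R(o_forward, o_backward) -> float:
    """Reversibility of one window from the two classifier outputs.

    Both margins (forward correctness ``o_f(2) - o_f(1)`` and backward
    correctness ``o_b(1) - o_b(2)``) must be nonnegative; otherwise the
    classification is incorrect and R is set to 0.  The result lies in
    [0, 1].
    """
    o_f = _check_simplex(o_forward, "o_forward")
    o_b = _check_simplex(o_backward, "o_backward")
    margin_f = o_f[1] - o_f[0]
    margin_b = o_b[0] - o_b[1]
    if margin_f < 0 or margin_b < 0:
        return 0.0
    return float((margin_f + margin_b) / 2.0)


def window_R_batch(o_forward: np.ndarray, o_backward: np.ndarray) -> np.ndarray:
    """Vectorized :func:`window_R` over rows of simplex outputs."""
    o_f = _check_simplex(o_forward, "o_forward")
    o_b = _check_simplex(o_backward, "o_backward")
    margin_f = o_f[:, 1] - o_f[:, 0]
    margin_b = o_b[:, 0] - o_b[:, 1]
    R = (margin_f + margin_b) / 2.0
    R[(margin_f < 0) | (margin_b < 0)] = 0.0
    return np.clip(R, 0.0, 1.0)


@dataclass
class ReversibilityTrace:
    """R(t) across the sliding windows of one participant/condition."""

    values: np.ndarray
    t_starts: np.ndarray
    participant_id: str
    condition: str
    scale: str
    unit: str

    @property
    def mean_R(self) -> float:
        return float(np.mean(self.values))

    @property
    def std_R(self) -> float:
        """Population (n-denominator) standard deviation across windows."""
        return float(np.std(self.values))


def evaluate_trace(net: DirectionNet, series: ParcelTimeSeries,
                   w: int, shift: int,
                   unit_rows=None, unit: str = "whole-brain") -> ReversibilityTrace:
    """Score every sliding window of a held-out series.

    Each window and its time reversal are flattened region-major and passed
    through the classifier; R(t) combines the two outputs.  Refuses series
    whose participant appears in the model's recorded training set, and
    models whose metadata (window size, region count, flattening) does not
    match the request.
    """
    train_pids = net.metadata.get("train_participants")
    if train_pids and series.participant_id in set(train_pids):
        raise ValueError(
            f"participant {series.participant_id!r} was in the training set"
        )
    meta_w = net.metadata.get("w")
    if meta_w is not None and int(meta_w) != w:
        raise ValueError(f"model was trained with w={meta_w}, requested w={w}")
    if net.metadata.get("flatten_order", "region-major") != "region-major":
        raise ValueError("model uses an unknown flattening order")
    values = series.values if unit_rows is None else series.values[np.asarray(unit_rows)]
    windows, starts = slide_windows(values, w, shift)
    k, n_reg = windows.shape[0], windows.shape[1]
    if n_reg * w != net.n_inputs:
        raise ValueError(
            f"window dimensionality {n_reg}x{w}={n_reg * w} does not match "
            f"the model's expected N*w = {net.n_inputs}"
        )
    fwd = windows.reshape(k, n_reg * w)
    bwd = reverse_window(windows).reshape(k, n_reg * w)
    o_f = net.predict_proba(fwd)
    o_b = net.predict_proba(bwd)
    R = window_R_batch(o_f, o_b)
    return ReversibilityTrace(R, starts, series.participant_id,
                              series.condition,
                              net.metadata.get("scale", "global"), unit)


def summarize_trace(trace: ReversibilityTrace) -> tuple:
    """(mean_R, std_R) over the windows of one participant."""
    if trace.values.size == 0:
        raise ValueError("empty trace")
    return trace.mean_R, trace.std_R


def traces_to_frame(traces) -> pd.DataFrame:
    """Long-format table of R values (one row per window) for TSV export."""
    rows = []
    for tr in traces:
        for t, r in zip(tr.t_starts, tr.values):
            rows.append({"participant_id": tr.participant_id,
                         "condition": tr.condition, "scale": tr.scale,
                         "unit": tr.unit, "t_start": int(t), "R": float(r)})
    return pd.DataFrame(rows)


def summaries_by_group(traces) -> dict:
    """{condition: array of per-participant mean_R} plus std in a frame."""
    groups: dict = {}
    for tr in traces:
        groups.setdefault(tr.condition, []).append(tr.mean_R)
    return {c: np.asarray(v) for c, v in groups.items()}


def _rank_biserial(a: np.ndarray, b: np.ndarray) -> float:
    """Effect size r = 2 U / (n_a n_b) - 1 from the Mann-Whitney U of a."""
    U = sstats.mannwhitneyu(a, b, alternative="two-sided").statistic
    return float(2.0 * U / (len(a) * len(b)) - 1.0)


def compare_groups(summaries: dict, measure: str = "mean_R") -> pd.DataFrame:
    """All pairwise Wilcoxon rank-sum tests with BH-FDR correction.

    ``summaries`` maps group label to a 1-D array of per-participant values
    (e.g. mean_R).  Returns a table with columns group_a, group_b,
    statistic, p_value, q_value, effect_size (rank-biserial correlation).
    """
    labels = sorted(summaries)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups to compare")
    for lab in labels:
        if len(np.atleast_1d(summaries[lab])) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 participants")
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            a = np.asarray(summaries[la], dtype=float)
            b = np.asarray(summaries[lb], dtype=float)
            res = sstats.ranksums(a, b)
            rows.append({"group_a": la, "group_b": lb, "measure": measure,
                         "statistic": float(res.statistic),
                         "p_value": float(res.pvalue),
                         "effect_size": _rank_biserial(a, b)})
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df[["group_a", "group_b", "measure", "statistic", "p_value",
               "q_value", "effect_size"]]
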