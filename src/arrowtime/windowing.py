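"""Sliding-window pattern construction for forward/backward classification.

Every sliding window of a (possibly unit-restricted) series yields exactly
two flattened patterns — the window itself labelled *forward* and its
time-reversed copy labelled *backward* — so direction labels are balanced
by construction.  Flattening is region-major: region 0's w samples first,
then region 1's, and so on; the order is recorded in the pattern-set
metadata and enforced at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from arrowtime.signal_io import NetworkAtlas, ParcelTimeSeries

FORWARD = 1   # class index of the forward direction (softmax output 2)
BACKWARD = 0  # class index of the backward direction (softmax output 1)

FLATTEN_ORDER = "region-major"


def n_windows(n_timepoints: int, w: int, shift: int) -> int:
    """Number of sliding windows: floor((T - w)/shift) + 1."""
    if w > n_timepoints:
        raise ValueError(f"window size {w} exceeds series length {n_timepoints}")
    if shift < 1:
        raise ValueError("shift must be >= 1")
    return (n_timepoints - w) // shift + 1

def slide_windows(values: np.ndarray, w: int, shift: int):
    """Slice a (n_regions, T) array into overlapping windows.

    Returns ``(windows, starts)`` where ``windows`` has shape
    (n_windows, n_regions, w) and ``starts`` holds the 0-based start
    timepoints 0, shift, 2*shift, ... while start + w <= T.
    """
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError("values must be 2-D (regions x timepoints)")
    T = values.shape[1]
    k = n_windows(T, w, shift)
    starts = np.arange(k) * shift
    windows = np.stack([values[:, s:s + w] for s in starts])
    return windows, starts


def reverse_window(window: np.ndarray) -> np.ndarray:
    """Reverse the time axis (last axis); the region axis is untouched.

    An involution: ``reverse_window(reverse_window(x)) == x``.
    """
    return np.asarray(window)[..., ::-1]


@dataclass
class WindowPattern:
    """A single flattened window with its direction label and provenance."""

    vector: np.ndarray
    direction: str  # "forward" | "backward"
    t_start: int
    participant_id: str
    condition: str
    unit: str  # "whole-brain" | network label | region id

    def __post_init__(self):
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"bad direction {self.direction!r}")
        self.vector = np.asarray(self.vector).ravel()


@dataclass
class PatternSet:
    """A labelled array of forward/backward patterns for one analysis unit.

    ``X`` has one flattened window per row; ``y`` is 1 for forward and 0
    for backward.  ``participants`` and ``t_starts`` align row-wise with
    ``X`` so that traces can be reassembled and participant-disjoint
    splits enforced.
    """

    X: np.ndarray
    y: np.ndarray
    participants: np.ndarray
    t_starts: np.ndarray
    condition: str
    scale: str          # "global" | "system" | "node"
    unit: str
    n_regions: int
    w: int
    shift: int
    flatten_order: str = FLATTEN_ORDER

    def __post_init__(self):
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.X.shape[1] != self.n_regions * self.w:
            raise ValueError("pattern length must equal n_regions * w")

    @property
    def n_patterns(self) -> int:
        return self.X.shape[0]

    def restrict(self, participant_ids) -> "PatternSet":
        """Row subset containing only the given participants."""
        wanted = set(participant_ids)
        mask = np.array([p in wanted for p in self.participants])
        return PatternSet(self.X[mask], self.y[mask],
                          self.participants[mask], self.t_starts[mask],
                          self.condition, self.scale, self.unit,
                          self.n_regions, self.w, self.shift,
                          self.flatten_order)

    def unflatten(self, row: int) -> np.ndarray:
        """Recover the (n_regions, w) window behind pattern row ``row``."""
        return self.X[row].reshape(self.n_regions, self.w)


def _units_for(scale: str, series: ParcelTimeSeries,
               atlas: NetworkAtlas | None):
    """Yield (unit label, row indices) pairs for one analysis granularity."""
    if scale == "global":
        yield "whole-brain", np.arange(series.n_regions)
    elif scale == "system":
        if atlas is None:
            raise ValueError("system-scale analysis requires an atlas")
        missing = [r for r in series.region_ids if r not in atlas.membership]
        if missing:
            raise ValueError(f"regions absent from atlas: {missing[:5]}")
        for net in atlas.networks:
            rows = np.array([i for i, r in enumerate(series.region_ids)
                             if atlas.membership[r] == net])
            if rows.size:
                yield net, rows
    elif scale == "node":
        for i, rid in enumerate(series.region_ids):
            yield rid, np.array([i])
    else:
        raise ValueError(f"unknown scale {scale!r}")


def build_dataset(cohort, scale: str, w: int, shift: int,
                  truncate_to: int | None = None,
                  atlas: NetworkAtlas | None = None,
                  require_balanced: bool = True) -> dict:
    """Build forward/backward pattern sets per (condition, unit).

    All series are truncated to a common length from timepoint 0 (the
    shortest series, or ``truncate_to``).  Every window contributes one
    forward and one backward pattern, so labels are balanced 50/50 exactly.
    With ``require_balanced`` each condition must contain the same number
    of participants, keeping the conditions comparable downstream.

    Returns ``{(condition, unit): PatternSet}``.
    """
    if not cohort:
        raise ValueError("empty cohort")
    T = min(s.n_timepoints for s in cohort) if truncate_to is None else truncate_to
    short = [s for s in cohort if s.n_timepoints < T]
    if short:
        raise ValueError(
            f"series shorter than truncation length {T}: "
            f"{[s.participant_id for s in short[:5]]}"
        )
    n_windows(T, w, shift)  # validate w <= T up front
    if require_balanced:
        counts = {}
        for s in cohort:
            counts.setdefault(s.condition, set()).add(s.participant_id)
        sizes = {c: len(p) for c, p in counts.items()}
        if len(set(sizes.values())) > 1:
            raise ValueError(f"unbalanced participants per condition: {sizes}")
    out: dict = {}
    buf: dict = {}
    for s in cohort:
        values = s.values[:, :T]
        for unit, rows in _units_for(scale, s, atlas):
            windows, starts = slide_windows(values[rows], w, shift)
            k, n_reg = windows.shape[0], rows.size
            fwd = windows.reshape(k, n_reg * w)
            bwd = reverse_window(windows).reshape(k, n_reg * w)
            X = np.concatenate([fwd, bwd])
            y = np.concatenate([np.full(k, FORWARD), np.full(k, BACKWARD)])
            pids = np.concatenate([np.full(k, s.participant_id)] * 2)
            ts = np.concatenate([starts, starts])
            buf.setdefault((s.condition, unit, n_reg), []).append(
                (X, y, pids, ts))
    for (condition, unit, n_reg), parts in buf.items():
        X = np.concatenate([p[0] for p in parts])
        y = np.concatenate([p[1] for p in parts]).astype(int)
        pids = np.concatenate([p[2] for p in parts])
        ts = np.concatenate([p[3] for p in parts]).astype(int)
        out[(condition, unit)] = PatternSet(X, y, pids, ts, condition,
                                            scale, unit, n_reg, w, shift)
    return out


@dataclass
class SplitSpec:
    """Participant-disjoint train/evaluation split."""

    train_participants: set = field(default_factory=set)
    eval_participants: set = field(default_factory=set)
    seed: int = 0

    def __post_init__(self):
        overlap = self.train_participants & self.eval_participants
        if overlap:
            raise ValueError(f"participants on both sides: {sorted(overlap)[:5]}")

    def assert_disjoint_from_training(self, participant_id: str) -> None:
        if participant_id in self.train_participants:
            raise ValueError(
                f"participant {participant_id!r} was used for training"
            )


def split_by_participant(participant_ids, eval_fraction: float = 0.1,
                         seed: int = 0, strata: dict | None = None) -> SplitSpec:
    """Random participant-disjoint split.

    The evaluation set gets ``max(1, floor(n * eval_fraction))``
    participants; no window from an evaluation participant can appear in
    training because the split is at the participant level.  When cohorts
    contain *different* participants per condition (case/control designs),
    pass ``strata`` mapping participant to condition to draw the
    evaluation fraction within each condition, keeping the split balanced.
    """
    ids = sorted(set(participant_ids))
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 participants to split")
    if not (0 < eval_fraction < 1):
        raise ValueError("eval_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if strata is None:
        groups = [ids]
    else:
        by = {}
        for pid in ids:
            by.setdefault(strata[pid], []).append(pid)
        groups = list(by.values())
    eval_ids: set = set()
    for g in groups:
        n_eval = max(1, int(np.floor(len(g) * eval_fraction)))
        if n_eval >= len(g):
            raise ValueError(
                "eval_fraction leaves no training participants in a stratum")
        perm = rng.permutation(len(g))
        eval_ids |= {g[i] for i in perm[:n_eval]}
    return SplitSpec(set(ids) - eval_ids, eval_ids, seed)
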