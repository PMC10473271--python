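"""Reading, writing, and temporal preprocessing of parcel-level time series.

File conventions
----------------
A time-series file is a TSV/CSV matrix with regions as rows and time as
columns.  The first column holds the region identifier; the header row holds
0-based timepoint indices.  A cohort manifest is a TSV with columns
``participant_id``, ``condition``, ``path``, ``tr_seconds``.  An atlas is a
two-column TSV mapping ``region_id`` to ``network_label``.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal


@dataclass
class ParcelTimeSeries:
    """One participant/condition's regions x timepoints signal matrix.

    Parameters
    ----------
    values : ndarray, shape (n_regions, n_timepoints)
        Signal values (BOLD, arbitrary units).  Must be finite.
    tr_seconds : float
        Sampling interval (fMRI repetition time), seconds.
    region_ids : list of str
        Unique identifiers aligned to rows of ``values``.
    participant_id, condition : str
        Provenance labels used for splitting and grouping.
    """

    values: np.ndarray
    tr_seconds: float
    region_ids: list = field(default_factory=list)
    participant_id: str = ""
    condition: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (regions x timepoints)")
        n_regions, n_timepoints = self.values.shape
        if n_timepoints < 2:
            raise ValueError("need at least 2 timepoints")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not self.region_ids:
            self.region_ids = [f"r{i:03d}" for i in range(n_regions)]
        if len(self.region_ids) != n_regions:
            raise ValueError(
                f"{len(self.region_ids)} region_ids for {n_regions} rows"
            )
        if len(set(self.region_ids)) != n_regions:
            raise ValueError("region_ids must be unique")
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            i, t = bad[0]
            raise ValueError(
                f"non-finite value at region {self.region_ids[i]!r}, "
                f"timepoint {t}"
            )

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def replace(self, **kw) -> "ParcelTimeSeries":
        return dataclasses.replace(self, **kw)


@dataclass
class NetworkAtlas:
    """Mapping from region identifiers to network labels (e.g. Yeo-7)."""

    membership: dict
    networks: list

    def __post_init__(self):
        declared = set(self.networks)
        for rid, lab in self.membership.items():
            if lab not in declared:
                raise ValueError(f"region {rid!r} has undeclared label {lab!r}")

    def regions_in(self, network: str) -> list:
        return [r for r, lab in self.membership.items() if lab == network]


_SEPS = {"tsv": "\t", "csv": ","}


def load_timeseries(path, format=None, tr_seconds=1.0, participant_id="",
                    condition="") -> ParcelTimeSeries:
    """Load a regions x timepoints matrix from a delimited text file.

    Rejects ragged rows, non-numeric cells and NaN/Inf entries, naming the
    offending region/timepoint coordinate.
    """
    if format is None:
        format = os.path.splitext(str(path))[1].lstrip(".").lower() or "tsv"
    if format not in _SEPS:
        raise ValueError(f"format must be one of {sorted(_SEPS)}, got {format!r}")
    df = pd.read_csv(path, sep=_SEPS[format], index_col=0)
    region_ids = [str(r) for r in df.index]
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for i, rid in enumerate(region_ids):
            for t, cell in enumerate(df.iloc[i]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at region {rid!r}, timepoint {t}: "
                        f"{cell!r}"
                    ) from None
        raise
    return ParcelTimeSeries(values, tr_seconds, region_ids,
                            participant_id, condition)


def save_timeseries(series: ParcelTimeSeries, path, format=None) -> None:
    """Write a series in the package's TSV/CSV matrix convention."""
    if format is None:
        format = os.path.splitext(str(path))[1].lstrip(".").lower() or "tsv"
    df = pd.DataFrame(series.values, index=series.region_ids,
                      columns=range(series.n_timepoints))
    df.index.name = "region_id"
    df.to_csv(path, sep=_SEPS[format], float_format="%.12g")


def load_manifest(path) -> pd.DataFrame:
    """Load a cohort manifest TSV (participant_id, condition, path, tr_seconds)."""
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str, "condition": str})
    required = {"participant_id", "condition", "path", "tr_seconds"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def load_cohort(manifest_path) -> list:
    """Load every series referenced by a manifest (paths relative to it)."""
    df = load_manifest(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    cohort = []
    for row in df.itertuples():
        p = row.path if os.path.isabs(row.path) else os.path.join(base, row.path)
        cohort.append(load_timeseries(p, tr_seconds=float(row.tr_seconds),
                                      participant_id=str(row.participant_id),
                                      condition=str(row.condition)))
    return cohort


def load_atlas(path) -> NetworkAtlas:
    """Load a two-column region_id -> network_label TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("atlas must have two columns: region_id, network_label")
    rid_col, lab_col = df.columns[:2]
    rids = df[rid_col].tolist()
    labs = df[lab_col].tolist()
    if len(set(rids)) != len(rids):
        dup = sorted({r for r in rids if rids.count(r) > 1})
        raise ValueError(f"duplicate region_id in atlas: {dup}")
    for r, lab in zip(rids, labs):
        if lab is None or (isinstance(lab, float) and np.isnan(lab)) or str(lab).strip() == "":
            raise ValueError(f"empty network label for region {r!r}")
    networks = list(dict.fromkeys(labs))  # stable order of first appearance
    return NetworkAtlas(dict(zip(rids, labs)), networks)


def save_atlas(atlas: NetworkAtlas, path) -> None:
    df = pd.DataFrame(
        {"region_id": list(atlas.membership),
         "network_label": list(atlas.membership.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def bandpass_filter(series: ParcelTimeSeries, low_hz: float = 0.008,
                    high_hz: float = 0.08, order: int = 2) -> ParcelTimeSeries:
    """Zero-phase Butterworth band-pass along the time axis, per region.

    The filter is the second-order Butterworth band commonly applied to BOLD
    signals (0.008-0.08 Hz by default), applied forward-backward
    (``sosfiltfilt``) so that preprocessing itself injects no temporal
    asymmetry; the magnitude response is therefore squared relative to a
    single pass.  Edges are handled with odd reflection padding of up to
    three times the slow-edge settling length (capped by series length).
    """
    nyquist = 0.5 / series.tr_seconds
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency "
            f"{nyquist:.4g} Hz for TR={series.tr_seconds} s"
        )
    sos = _signal.butter(order, [low_hz, high_hz], btype="bandpass",
                         fs=1.0 / series.tr_seconds, output="sos")
    settle = int(3.0 / (low_hz * series.tr_seconds))
    padlen = min(series.n_timepoints - 1, settle)
    filtered = _signal.sosfiltfilt(sos, series.values, axis=1,
                                   padtype="odd", padlen=padlen)
    return series.replace(values=filtered)


def normalize_series(series: ParcelTimeSeries,
                     mode: str = "per_region_zscore") -> ParcelTimeSeries:
    """Z-score each region over the full series (not per window).

    Removes amplitude differences between participants and regions so that
    downstream window classification reflects temporal structure, not scale.
    """
    if mode != "per_region_zscore":
        raise ValueError(f"unknown normalization mode {mode!r}")
    mu = series.values.mean(axis=1, keepdims=True)
    sd = series.values.std(axis=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValueError(
            f"zero-variance region {series.region_ids[flat[0]]!r} "
            "cannot be z-scored"
        )
    return series.replace(values=(series.values - mu) / sd)
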