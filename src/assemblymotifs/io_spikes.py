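"""Data model and I/O for sessions of parallel spike trains.

A :class:`Session` is the raw input to everything downstream: a set of
simultaneously recorded units, each carrying a sorted list of spike times in
seconds and an anatomical area label, plus the recording duration and the
focal area of the analysis (the zona incerta, "ZI", by default).

Conventions fixed here, used consistently by all other modules:

* time is measured in seconds from the session start (``t = 0``), as floats;
* binning uses half-open bins ``[i*Δ, (i+1)*Δ)`` anchored at 0, with a spike
  exactly at ``duration`` clipped into the final bin;
* duplicate timestamps within a unit are kept (bins may count > 1 spike);
  detection binarizes downstream.

The on-disk format is a plain TSV with header
``unit_id  area  session_id  time_s``, one spike per row.  An optional units
table (``unit_id  area  session_id``) declares silent units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SPIKES_COLUMNS = ("unit_id", "area", "session_id", "time_s")
UNITS_COLUMNS = ("unit_id", "area", "session_id")

#: Inclusion rule used across the analysis: a unit enters only with strictly
#: more than this many spikes over the whole session.
DEFAULT_MIN_SPIKES = 100


@dataclass
class SpikeTrain:
    """Spike times of one unit.

    Parameters
    ----------
    unit_id : str
        Identifier, unique within a session.
    area : str
        Anatomical area label (e.g. ``"ZI"``, ``"MS"``).
    spike_times : array-like of float
        Event times in seconds; sorted on construction.
    session_id : str
        Identifier of the session the unit belongs to.
    """

    unit_id: str
    area: str
    spike_times: np.ndarray
    session_id: str

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        if times.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if times.size and times.min() < 0:
            raise ValueError(f"unit {self.unit_id}: negative spike times")
        self.spike_times = np.sort(times)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def rate(self, duration: float) -> float:
        """Mean firing rate in Hz over ``duration`` seconds."""
        return self.n_spikes / duration


@dataclass
class Session:
    """A set of simultaneously recorded spike trains.

    Invariants enforced on construction: positive duration, all spike times
    within ``[0, duration]``, unit ids unique.
    """

    session_id: str
    duration: float
    trains: list[SpikeTrain] = field(default_factory=list)
    focal_area: str = "ZI"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        seen: set[str] = set()
        for tr in self.trains:
            if tr.unit_id in seen:
                raise ValueError(f"duplicate unit_id {tr.unit_id!r}")
            seen.add(tr.unit_id)
            if tr.spike_times.size and tr.spike_times[-1] > self.duration:
                raise ValueError(
                    f"unit {tr.unit_id}: spike time beyond session duration"
                )

    @property
    def areas(self) -> tuple[str, ...]:
        """Sorted tuple of distinct area labels present in the session."""
        return tuple(sorted({tr.area for tr in self.trains}))

    @property
    def unit_ids(self) -> tuple[str, ...]:
        return tuple(tr.unit_id for tr in self.trains)

    @property
    def n_units(self) -> int:
        return len(self.trains)

    def unit_area(self, unit_id: str) -> str:
        return self.train(unit_id).area

    def train(self, unit_id: str) -> SpikeTrain:
        for tr in self.trains:
            if tr.unit_id == unit_id:
                return tr
        raise KeyError(unit_id)

    def subset(self, unit_ids: Iterable[str]) -> "Session":
        wanted = set(unit_ids)
        return replace(self, trains=[t for t in self.trains if t.unit_id in wanted])


@dataclass
class BinnedSession:
    """Binned spike-count matrix plus the bin-edge convention record."""

    counts: np.ndarray  # (n_units, n_bins) int64
    unit_ids: tuple[str, ...]
    areas: tuple[str, ...]
    bin_size: float
    n_bins: int
    duration: float
    convention: str = "half-open [i*bin, (i+1)*bin) anchored at t=0; t=duration clipped to last bin"


def read_session(
    path: str | Path,
    duration: float | str = "auto",
    focal_area: str = "ZI",
    units_path: str | Path | None = None,
) -> Session:
    """Read a spikes TSV into a :class:`Session`.

    ``duration="auto"`` uses the maximum spike time.  Unknown or missing
    columns raise; times are sorted per unit; duplicate timestamps are kept.
    ``units_path`` may declare silent units (zero spikes).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"unit_id": str, "area": str, "session_id": str},
        float_precision="round_trip",
    )
    if tuple(df.columns) != SPIKES_COLUMNS:
        raise ValueError(
            f"expected columns {SPIKES_COLUMNS}, found {tuple(df.columns)}"
        )
    if df.empty:
        raise ValueError("no units: spikes table is empty")
    if (df["time_s"] < 0).any():
        raise ValueError("negative spike times in table")
    session_ids = df["session_id"].unique()
    if len(session_ids) != 1:
        raise ValueError(f"expected a single session_id, found {list(session_ids)}")
    session_id = str(session_ids[0])

    if duration == "auto":
        dur = float(df["time_s"].max())
    else:
        dur = float(duration)
        if df["time_s"].max() > dur:
            raise ValueError("spike times exceed the provided duration")

    trains = []
    meta: dict[str, str] = {}
    for (unit_id, area), grp in df.groupby(["unit_id", "area"], sort=True):
        if unit_id in meta:
            raise ValueError(f"unit {unit_id!r} listed under two areas")
        meta[unit_id] = area
        trains.append(
            SpikeTrain(unit_id, area, grp["time_s"].to_numpy(), session_id)
        )

    if units_path is not None:
        units = pd.read_csv(units_path, sep="\t", dtype=str)
        if tuple(units.columns) != UNITS_COLUMNS:
            raise ValueError(f"expected columns {UNITS_COLUMNS} in units table")
        for row in units.itertuples(index=False):
            if row.unit_id not in meta:
                meta[row.unit_id] = row.area
                trains.append(
                    SpikeTrain(row.unit_id, row.area, np.empty(0), session_id)
                )

    trains.sort(key=lambda t: t.unit_id)
    return Session(session_id, dur, trains, focal_area=focal_area)


def write_session(session: Session, path: str | Path) -> None:
    """Write a session to the spikes TSV format (round-trips with
    :func:`read_session` at full float precision)."""
    rows = []
    for tr in sorted(session.trains, key=lambda t: t.unit_id):
        for t in tr.spike_times:
            rows.append((tr.unit_id, tr.area, session.session_id, repr(float(t))))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SPIKES_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def filter_min_spikes(
    session: Session, min_spikes: int = DEFAULT_MIN_SPIKES
) -> tuple[Session, list[str]]:
    """Keep units with strictly more than ``min_spikes`` spikes.

    Returns the filtered session and the list of removed unit ids.  The strict
    inequality means a unit with exactly ``min_spikes`` spikes is removed.
    Idempotent.
    """
    if min_spikes < 0:
        raise ValueError("min_spikes must be >= 0")
    kept = [tr for tr in session.trains if tr.n_spikes > min_spikes]
    removed = [tr.unit_id for tr in session.trains if tr.n_spikes <= min_spikes]
    return replace(session, trains=kept), removed


def bin_session(session: Session, bin_size: float) -> BinnedSession:
    """Bin every train at ``bin_size`` seconds.

    Entry ``(u, i)`` counts the spikes of unit ``u`` in
    ``[i*bin_size, (i+1)*bin_size)``; the number of bins is
    ``ceil(duration / bin_size)`` and the total spike count is conserved.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_bins = max(1, math.ceil(session.duration / bin_size))
    counts = np.zeros((session.n_units, n_bins), dtype=np.int64)
    for i, tr in enumerate(session.trains):
        if tr.n_spikes == 0:
            continue
        idx = np.floor(tr.spike_times / bin_size).astype(np.int64)
        np.clip(idx, 0, n_bins - 1, out=idx)  # t == duration -> last bin
        counts[i] = np.bincount(idx, minlength=n_bins)
    return BinnedSession(
        counts=counts,
        unit_ids=session.unit_ids,
        areas=tuple(tr.area for tr in session.trains),
        bin_size=float(bin_size),
        n_bins=n_bins,
        duration=session.duration,
    )
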