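"""Per-frame distance metrics over trajectories and per-chain summaries.

Metrics mirror the quantities used to characterise the resting-state
dynamics of the T2Cu pocket: the hydrogen-bond distance from the Tyr323
phenolic hydrogen to the nearest sidechain acceptor of Asp/Asn97, and the
distances from the T2Cu ion to the sidechain centres of mass of Tyr323 and
Asp/Asn97.  Summaries report mean and standard deviation, optionally split
at a displacement-event time into before/after segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .structures_io import ActiveSite

__all__ = [
    "DistanceSeries",
    "SegmentSummary",
    "SeriesSummary",
    "hbond_series",
    "com_distance_series",
    "summarize",
    "hbond_occupancy",
    "series_table",
]

#: Default donor-H...acceptor distance (Angstrom) below which the hydrogen
#: bond counts as formed.
DEFAULT_HBOND_CUTOFF = 2.5

#: Sidechain atoms of Asp (OD1/OD2) and Asn (OD1/ND2) that can accept the
#: Tyr323 phenolic hydrogen.
DEFAULT_ACCEPTOR_ATOMS = ("OD1", "OD2", "ND2")


@dataclass
class DistanceSeries:
    """A per-frame distance metric: label, times (ns) and values (Angstrom)."""

    label: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class SegmentSummary:
    start: float
    end: float
    mean: float
    std: float
    n_frames: int


@dataclass(frozen=True)
class SeriesSummary:
    mean: float
    std: float
    n_frames: int
    segments: tuple[SegmentSummary, ...] | None = None


def _frame_times(frames: Sequence[ActiveSite], times, dt: float, t0: float) -> np.ndarray:
    if times is not None:
        times = np.asarray(times, dtype=float)
        if len(times) != len(frames):
            raise ValueError("times must have one entry per frame")
        return times
    return t0 + dt * np.arange(len(frames))


def hbond_series(
    frames: Sequence[ActiveSite],
    donor_role: str = "Tyr323",
    donor_atom: str = "HH",
    acceptor_role: str = "Asp97",
    acceptor_atoms: Sequence[str] | None = None,
    times=None,
    dt: float = 1.0,
    t0: float = 0.0,
    label: str | None = None,
) -> DistanceSeries:
    """Donor-to-nearest-acceptor distance per frame.

    The acceptor is re-selected every frame: the reported value is the
    minimum distance from the donor atom (by default the Tyr323 phenolic H)
    to any candidate acceptor atom of the acceptor residue (for Asp the two
    carboxylate oxygens; for Asn the sidechain O and N — the default atom
    set covers both).
    """
    acceptor_atoms = tuple(acceptor_atoms) if acceptor_atoms else DEFAULT_ACCEPTOR_ATOMS
    bad_frames = []
    values = np.empty(len(frames))
    for i, frame in enumerate(frames):
        donor_group = frame.aux.get(donor_role)
        acc_group = frame.aux.get(acceptor_role)
        donor = donor_group.select([donor_atom]) if donor_group is not None else None
        acceptors = acc_group.select(acceptor_atoms) if acc_group is not None else None
        if donor is None or len(donor) == 0 or acceptors is None or len(acceptors) == 0:
            bad_frames.append(frame.frame_index)
            continue
        d = np.linalg.norm(acceptors.positions - donor.positions[0], axis=1)
        values[i] = d.min()
    if bad_frames:
        raise ValueError(
            f"missing donor {donor_role}/{donor_atom} or acceptors "
            f"{acceptor_role}/{acceptor_atoms} in frame(s) {bad_frames}"
        )
    return DistanceSeries(
        label=label or f"{donor_role}({donor_atom})...{acceptor_role}",
        times=_frame_times(frames, times, dt, t0),
        values=values,
    )


def com_distance_series(
    frames: Sequence[ActiveSite],
    residue_role: str,
    times=None,
    dt: float = 1.0,
    t0: float = 0.0,
    include_hydrogens: bool = False,
    label: str | None = None,
) -> DistanceSeries:
    """|Cu - sidechain COM| of the named auxiliary residue, per frame."""
    bad_frames = []
    values = np.empty(len(frames))
    for i, frame in enumerate(frames):
        group = frame.aux.get(residue_role)
        if group is None or len(group) == 0:
            bad_frames.append(frame.frame_index)
            continue
        values[i] = np.linalg.norm(frame.cu - group.com(include_hydrogens=include_hydrogens))
    if bad_frames:
        raise ValueError(f"residue role {residue_role!r} missing in frame(s) {bad_frames}")
    return DistanceSeries(
        label=label or f"Cu-{residue_role}(COM)",
        times=_frame_times(frames, times, dt, t0),
        values=values,
    )


def _mean_std(values: np.ndarray, sample_std: bool) -> tuple[float, float]:
    ddof = 1 if sample_std and len(values) > 1 else 0
    return float(values.mean()), float(values.std(ddof=ddof))


def summarize(
    series: DistanceSeries, split_time: float | None = None, sample_std: bool = False
) -> SeriesSummary:
    """Mean and standard deviation of a series, optionally split at a time.

    Population standard deviation by default (``sample_std`` switches to
    n-1).  With ``split_time`` the summary also carries separate segments
    for frames before (t < split) and after (t >= split) the event, the
    layout used to report a displacement such as the Tyr323 break-away.
    """
    if len(series) == 0:
        raise ValueError("cannot summarize an empty series")
    mean, std = _mean_std(series.values, sample_std)
    segments = None
    if split_time is not None:
        if not (series.times[0] <= split_time <= series.times[-1]):
            raise ValueError(
                f"split_time {split_time} outside series range "
                f"[{series.times[0]}, {series.times[-1]}]"
            )
        segs = []
        for mask, (start, end) in (
            (series.times < split_time, (series.times[0], split_time)),
            (series.times >= split_time, (split_time, series.times[-1])),
        ):
            if mask.any():
                m, s = _mean_std(series.values[mask], sample_std)
                segs.append(SegmentSummary(float(start), float(end), m, s, int(mask.sum())))
        segments = tuple(segs)
    return SeriesSummary(mean=mean, std=std, n_frames=len(series), segments=segments)


def hbond_occupancy(series: DistanceSeries, cutoff: float = DEFAULT_HBOND_CUTOFF) -> float:
    """Fraction of frames with distance <= cutoff (hydrogen bond formed)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if len(series) == 0:
        return 0.0
    return float(np.mean(series.values <= cutoff))


def series_table(series_list: Sequence[DistanceSeries], chain: str = "") -> pd.DataFrame:
    """Tidy (time, metric, chain, value) table for a set of series."""
    parts = [
        pd.DataFrame(
            {"time": s.times, "metric": s.label, "chain": chain, "value": s.values}
        )
        for s in series_list
    ]
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["time", "metric", "chain", "value"]
    )
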