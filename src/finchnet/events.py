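"""Clustering feeder-detection streams into flock-feeding events.

RFID antennae log instantaneous tag reads as birds enter a feeder; a *flock
feeding event* is a cluster of reads at one feeder around the same time. Two
detectors are provided, applied independently to each (aviary, feeder, day):

``gmm``
    Fit 1-D Gaussian mixtures over the timestamps for k = 1..k_max by EM,
    select k by BIC, assign each detection to its maximum-responsibility
    component, then merge components whose means are closer than
    ``merge_window`` seconds.
``gap``
    Split the sorted timestamps wherever two successive detections are more
    than ``gap_threshold`` seconds apart. Transparent and fast; agrees with
    the GMM detector whenever clusters are well separated.

Each resulting cluster becomes one event; a bird detected several times in a
cluster appears once in the member set. Events feed the per-day
group-by-individual (GBI) matrices that the association networks and the
datastream permutations operate on.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from ._util import require_columns

__all__ = [
    "ForagingEvent",
    "GroupByIndividual",
    "detect_events",
    "build_gbi",
    "summarize_events",
]

DEFAULT_GAP_THRESHOLD = 120.0
DEFAULT_MERGE_WINDOW = 60.0


@dataclass(frozen=True)
class ForagingEvent:
    aviary_id: int
    feeder_id: int
    day: int
    start_s: float
    end_s: float
    members: frozenset

    def __post_init__(self):
        if self.start_s > self.end_s:
            raise ValueError("event start must not exceed end")
        if not self.members:
            raise ValueError("event must have at least one member")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class GroupByIndividual:
    """Binary events x individuals matrix for one (aviary, day).

    Rows are ordered by event start time; columns follow the fixed aviary
    roster. Row metadata (feeder, start, end) is retained because the
    permutation null model blocks swaps by feeder.
    """

    aviary_id: int
    day: int
    matrix: np.ndarray  # (E, N) int8
    roster: tuple
    feeders: np.ndarray  # (E,)
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.roster):
            raise ValueError("GBI matrix shape inconsistent with roster")
        if self.matrix.size and not np.all((self.matrix == 0) | (self.matrix == 1)):
            raise ValueError("GBI entries must be 0/1")
        if self.matrix.shape[0] and (self.matrix.sum(axis=1) < 1).any():
            raise ValueError("every GBI row must contain at least one bird")

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]

    def event_sizes(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def bout_counts(self) -> np.ndarray:
        """Per-bird number of daily visit bouts (column sums)."""
        return self.matrix.sum(axis=0)

    def copy(self) -> "GroupByIndividual":
        return GroupByIndividual(
            self.aviary_id, self.day, self.matrix.copy(), self.roster,
            self.feeders.copy(), self.starts.copy(), self.ends.copy(),
        )


def _feeder_day_seed(day: int, feeder: int) -> int:
    # crc32, not hash(): Python's hash is salted per process
    return zlib.crc32(f"{day}:{feeder}".encode()) & 0x7FFFFFFF


def _gap_labels(times: np.ndarray, gap_threshold: float) -> np.ndarray:
    if len(times) == 0:
        return np.empty(0, dtype=int)
    breaks = np.diff(times) > gap_threshold
    return np.concatenate([[0], np.cumsum(breaks)])


def _gmm_labels(times, k_max, merge_window, seed, n_init=2, patience=10):
    n = len(times)
    if n == 1:
        return np.zeros(1, dtype=int)
    if k_max is None:
        k_max = math.ceil(n / 3)
    k_max = max(1, min(k_max, n))
    X = times.reshape(-1, 1)
    best = None
    best_bic = np.inf
    since_best = 0
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k, n_init=n_init, random_state=seed,
            reg_covar=1e-3, init_params="k-means++",
        )
        gm.fit(X)
        bic = gm.bic(X)
        if bic < best_bic:
            best_bic = bic
            best = gm
            since_best = 0
        else:
            # BIC is close to unimodal in k here; stop once it has not
            # improved for `patience` consecutive candidates
            since_best += 1
            if since_best >= patience:
                break
    labels = best.predict(X)
    # merge components whose means are within merge_window of each other
    means = best.means_.ravel()
    order = np.argsort(means)
    merged = np.empty(len(means), dtype=int)
    group = 0
    merged[order[0]] = 0
    for prev, cur in zip(order[:-1], order[1:]):
        if means[cur] - means[prev] >= merge_window:
            group += 1
        merged[cur] = group
    return merged[labels]


def detect_events(
    stream: pd.DataFrame,
    method: str = "gap",
    *,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
    k_max: int | None = None,
    merge_window: float = DEFAULT_MERGE_WINDOW,
    return_labels: bool = False,
):
    """Cluster a visit stream into foraging events, per (aviary, feeder, day).

    Returns the list of :class:`ForagingEvent` (sorted by aviary, day, start
    time); with ``return_labels=True`` also a Series of event identifiers
    aligned to the stream rows, for comparison with ground-truth labellings.
    """
    if method not in ("gap", "gmm"):
        raise ValueError(f"unknown event-detection method: {method!r}")
    events: list = []
    labels = pd.Series("", index=stream.index, dtype=object, name="event")
    if len(stream) == 0:
        return (events, labels) if return_labels else events
    require_columns(
        stream, ["bird_id", "aviary_id", "feeder_id", "day", "time_s"], "visit stream"
    )
    for (a, f, d), grp in stream.groupby(["aviary_id", "feeder_id", "day"]):
        order = np.argsort(grp["time_s"].to_numpy(), kind="stable")
        times = grp["time_s"].to_numpy()[order]
        birds = grp["bird_id"].to_numpy()[order]
        idx = grp.index.to_numpy()[order]
        if method == "gap":
            lab = _gap_labels(times, gap_threshold)
        else:
            lab = _gmm_labels(times, k_max, merge_window, _feeder_day_seed(d, f))
        for cl in np.unique(lab):
            mask = lab == cl
            events.append(ForagingEvent(
                aviary_id=int(a), feeder_id=int(f), day=int(d),
                start_s=float(times[mask].min()), end_s=float(times[mask].max()),
                members=frozenset(birds[mask]),
            ))
        labels.loc[idx] = [f"A{a}F{f}D{d}:{c}" for c in lab]
    events.sort(key=lambda e: (e.aviary_id, e.day, e.start_s, e.feeder_id))
    return (events, labels) if return_labels else events


def build_gbi(
    events: Sequence[ForagingEvent],
    rosters: Mapping[int, Sequence[str]] | Sequence[str],
    days: Sequence[int] | None = None,
) -> dict:
    """Assemble per-(aviary, day) group-by-individual matrices.

    ``rosters`` is either a mapping aviary_id -> bird list or a single list
    applied to every aviary. ``days`` optionally forces a key for every listed
    day even when no event occurred (yielding a 0 x N matrix). Rows are
    ordered by event start; columns by the roster as given.
    """
    events = list(events)
    aviaries = sorted({e.aviary_id for e in events})
    if not isinstance(rosters, Mapping):
        rosters = {a: list(rosters) for a in aviaries} if aviaries else {}
    out: dict = {}
    keys = {(e.aviary_id, e.day) for e in events}
    if days is not None:
        keys |= {(a, d) for a in rosters for d in days}
    for a, d in sorted(keys):
        roster = tuple(rosters[a])
        pos = {b: i for i, b in enumerate(roster)}
        evs = sorted(
            (e for e in events if e.aviary_id == a and e.day == d),
            key=lambda e: (e.start_s, e.feeder_id),
        )
        M = np.zeros((len(evs), len(roster)), dtype=np.int8)
        for r, e in enumerate(evs):
            for b in e.members:
                if b not in pos:
                    raise ValueError(
                        f"bird {b!r} in event at aviary {a} day {d} "
                        f"is missing from the roster"
                    )
                M[r, pos[b]] = 1
        out[(a, d)] = GroupByIndividual(
            aviary_id=a, day=d, matrix=M, roster=roster,
            feeders=np.array([e.feeder_id for e in evs]),
            starts=np.array([e.start_s for e in evs]),
            ends=np.array([e.end_s for e in evs]),
        )
    return out


def summarize_events(events: Sequence[ForagingEvent]):
    """Mean event duration and its 2.5th/97.5th percentiles (linear interpolation)."""
    events = list(events)
    if not events:
        raise ValueError("cannot summarize an empty event list")
    durations = np.array([e.duration_s for e in events])
    lo, hi = np.percentile(durations, [2.5, 97.5], method="linear")
    return float(durations.mean()), float(lo), float(hi)
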