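"""Dynamic-time-warping song comparison and tutor ranking.

A male zebra finch sings a single stereotyped *motif*: an ordered sequence of
*elements*, each of which is here represented as a short multivariate trace of
acoustic features (for example fundamental frequency and amplitude sampled
along the element). Two elements are compared by dynamic time warping (DTW)
with Euclidean frame-to-frame cost; two motifs are compared by a second DTW
over their element sequences, using the element-level dissimilarities as step
costs; and two males are compared by symmetrized best-fit averaging over their
motif renditions. Sorting all candidate males by dissimilarity to a focal
juvenile yields the tutor ranking (rank 1 = inferred primary song tutor).

Features are assumed to be standardized dataset-wide (z-score per feature,
:func:`standardize_elements`) before any distance is computed, so that no
single acoustic feature dominates the Euclidean cost.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "ElementTrace",
    "TutorRanking",
    "standardize_elements",
    "dtw_distance",
    "element_dissimilarity_matrix",
    "motif_dissimilarity",
    "male_dissimilarity",
    "motif_pair_dissimilarity",
    "motif_dissimilarity_matrix",
    "tutor_ranking",
]


# --------------------------------------------------------------------------- #
# core DTW dynamic program
# --------------------------------------------------------------------------- #

def _dtw_core_py(cost):
    """Accumulate a full-alignment DTW table over a precomputed cost matrix.

    Returns (total accumulated cost, length of the optimal warping path).
    Ties between predecessor cells prefer the diagonal step, then the left
    (advance in b), then the up (advance in a) step, which makes the reported
    path length deterministic.
    """
    n, m = cost.shape
    D = np.empty((n, m))
    L = np.empty((n, m), dtype=np.int64)
    D[0, 0] = cost[0, 0]
    L[0, 0] = 1
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + cost[0, j]
        L[0, j] = j + 1
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + cost[i, 0]
        L[i, 0] = i + 1
        for j in range(1, m):
            best = D[i - 1, j - 1]
            blen = L[i - 1, j - 1]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
                blen = L[i, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
                blen = L[i - 1, j]
            D[i, j] = cost[i, j] + best
            L[i, j] = blen + 1
    return D[n - 1, m - 1], L[n - 1, m - 1]


try:  # numba gives ~100x on the inner DP; the pure-Python path is equivalent
    from numba import njit

    _dtw_core = njit(cache=False)(_dtw_core_py)
except ImportError:  # pragma: no cover - numba present in supported envs
    _dtw_core = _dtw_core_py


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ElementTrace:
    """One song element: a (T, k) array of k acoustic features over T frames."""

    values: np.ndarray
    bird_id: str = ""
    motif_idx: int = 0
    element_idx: int = 0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2 or v.shape[0] < 1:
            raise ValueError("element trace must be a non-empty (T, k) array")
        if not np.all(np.isfinite(v)):
            raise ValueError("element trace contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def key(self) -> tuple:
        return (self.bird_id, self.motif_idx, self.element_idx)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


Motif = Sequence[ElementTrace]
MotifSet = Mapping[str, Sequence[Motif]]


@dataclass
class TutorRanking:
    """Candidate tutors of one juvenile, sorted by motif dissimilarity."""

    focal: str
    table: pd.DataFrame  # columns: candidate, dissimilarity, rank
    father_rank: int | None = None

    @property
    def primary_tutor(self) -> str:
        return self.table.iloc[0]["candidate"]

    @property
    def primary_dissimilarity(self) -> float:
        return float(self.table.iloc[0]["dissimilarity"])


# --------------------------------------------------------------------------- #
# standardization
# --------------------------------------------------------------------------- #

def standardize_elements(motifs: MotifSet) -> dict:
    """Z-score every acoustic feature over all frames of all elements.

    The statistics are dataset-wide, so relative differences between birds are
    preserved. A feature with zero spread is left centred but unscaled.
    """
    stacks = [
        el.values
        for renditions in motifs.values()
        for motif in renditions
        for el in motif
    ]
    if not stacks:
        raise ValueError("no elements to standardize")
    allv = np.concatenate(stacks, axis=0)
    mean = allv.mean(axis=0)
    sd = allv.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    out: dict = {}
    for bird, renditions in motifs.items():
        out[bird] = [
            [
                ElementTrace(
                    (el.values - mean) / sd, el.bird_id, el.motif_idx, el.element_idx
                )
                for el in motif
            ]
            for motif in renditions
        ]
    return out


# --------------------------------------------------------------------------- #
# element-level DTW
# --------------------------------------------------------------------------- #

def _as_values(trace) -> np.ndarray:
    if isinstance(trace, ElementTrace):
        return trace.values
    v = np.asarray(trace, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if v.size == 0:
        raise ValueError("empty trace")
    return v


def dtw_distance(a, b, normalize: bool = False) -> float:
    """DTW distance between two element traces.

    Full boundary-matched alignment with Euclidean cost between feature
    vectors; with ``normalize=True`` the accumulated cost is divided by the
    optimal warping-path length, making scores comparable across trace
    lengths.
    """
    av, bv = _as_values(a), _as_values(b)
    if av.shape[1] != bv.shape[1]:
        raise ValueError(
            f"feature dimensions differ: {av.shape[1]} vs {bv.shape[1]}"
        )
    cost = cdist(av, bv)
    total, plen = _dtw_core(cost)
    return float(total / plen) if normalize else float(total)


def element_dissimilarity_matrix(
    elements: Sequence[ElementTrace], normalize: bool = True
) -> pd.DataFrame:
    """Pairwise DTW dissimilarity between every element in the dataset.

    Indexed by (bird_id, motif_idx, element_idx); symmetric with zero
    diagonal. This matrix is the substrate for all motif-level comparisons.
    """
    if len(elements) < 2:
        raise ValueError("need at least 2 elements")
    keys = [el.key for el in elements]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate element keys in the input set")
    n = len(elements)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dtw_distance(elements[i], elements[j], normalize=normalize)
            M[i, j] = M[j, i] = d
    idx = pd.MultiIndex.from_tuples(keys, names=["bird_id", "motif_idx", "element_idx"])
    return pd.DataFrame(M, index=idx, columns=idx)


# --------------------------------------------------------------------------- #
# motif- and male-level combination
# --------------------------------------------------------------------------- #

def _element_cost_submatrix(motif_a: Motif, motif_b: Motif, element_matrix: pd.DataFrame):
    pos = {k: i for i, k in enumerate(element_matrix.index)}
    try:
        ia = [pos[el.key] for el in motif_a]
        ib = [pos[el.key] for el in motif_b]
    except KeyError as exc:  # noqa: PERF203
        raise KeyError(f"element {exc.args[0]} missing from element matrix") from exc
    vals = element_matrix.to_numpy()
    return vals[np.ix_(ia, ib)]


def motif_dissimilarity(
    motif_a: Motif,
    motif_b: Motif,
    element_matrix: pd.DataFrame,
    normalize: bool = True,
) -> float:
    """DTW over the two element *sequences* using element dissimilarities as costs.

    Normalizing by the warping-path length (default) makes motifs of different
    element counts comparable; set ``normalize=False`` for the raw accumulated
    cost.
    """
    if len(motif_a) == 0 or len(motif_b) == 0:
        raise ValueError("motifs must be non-empty")
    cost = _element_cost_submatrix(motif_a, motif_b, element_matrix)
    total, plen = _dtw_core(cost)
    return float(total / plen) if normalize else float(total)


def male_dissimilarity(
    motifs_a: Sequence[Motif],
    motifs_b: Sequence[Motif],
    element_matrix: pd.DataFrame,
    normalize: bool = True,
) -> float:
    """Symmetrized best-fit average between two males' motif repertoires.

    For each rendition of male A, take the best (minimum) fit onto male B's
    renditions; average those; do the same from B onto A; return the mean of
    the two directions. With one rendition per male this reduces to the plain
    motif dissimilarity.
    """
    d = np.array(
        [
            [motif_dissimilarity(ma, mb, element_matrix, normalize) for mb in motifs_b]
            for ma in motifs_a
        ]
    )
    fit_ab = d.min(axis=1).mean()
    fit_ba = d.min(axis=0).mean()
    return float((fit_ab + fit_ba) / 2.0)


def motif_pair_dissimilarity(
    motifs_a: Sequence[Motif],
    motifs_b: Sequence[Motif],
    normalize: bool = True,
) -> float:
    """Male-to-male dissimilarity computed directly, without a global element matrix.

    Equivalent to :func:`male_dissimilarity` on the submatrix of element DTW
    distances between the two males only; used when just a handful of dyads is
    needed (e.g. father-son scores for every son). Assumes traces are already
    standardized.
    """

    def _motif_d(ma, mb):
        cost = np.array(
            [[dtw_distance(ea, eb, normalize=normalize) for eb in mb] for ea in ma]
        )
        total, plen = _dtw_core(cost)
        return total / plen if normalize else total

    d = np.array([[_motif_d(ma, mb) for mb in motifs_b] for ma in motifs_a])
    return float((d.min(axis=1).mean() + d.min(axis=0).mean()) / 2.0)


def motif_dissimilarity_matrix(
    motifs: MotifSet,
    element_matrix: pd.DataFrame | None = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Symmetric male-by-male motif dissimilarity matrix (zero diagonal).

    Computes the element dissimilarity matrix over every element in the
    dataset first unless one is supplied.
    """
    males = sorted(motifs)
    if element_matrix is None:
        elements = [
            el for m in males for motif in motifs[m] for el in motif
        ]
        element_matrix = element_dissimilarity_matrix(elements, normalize=normalize)
    n = len(males)
    M = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = male_dissimilarity(
            motifs[males[i]], motifs[males[j]], element_matrix, normalize
        )
        M[i, j] = M[j, i] = d
    return pd.DataFrame(M, index=males, columns=males)


# --------------------------------------------------------------------------- #
# tutor ranking
# --------------------------------------------------------------------------- #

def tutor_ranking(
    matrix: pd.DataFrame,
    focal: str,
    candidates: Sequence[str],
    father: str | None = None,
) -> TutorRanking:
    """Rank candidate song tutors of ``focal`` by ascending dissimilarity.

    Rank 1 is the male with the most similar motif (the inferred primary song
    tutor). Ties are broken by lexicographic bird ID, which makes the ranking
    deterministic across runs. ``father_rank`` is filled when the father is
    among the candidates.
    """
    candidates = list(candidates)
    if focal in candidates:
        raise ValueError(f"focal bird {focal!r} must not be among its own candidates")
    if len(candidates) == 0:
        raise ValueError("no candidate tutors supplied")
    scores = [(float(matrix.loc[focal, c]), c) for c in candidates]
    scores.sort()
    table = pd.DataFrame(
        {
            "candidate": [c for _, c in scores],
            "dissimilarity": [s for s, _ in scores],
            "rank": np.arange(1, len(scores) + 1),
        }
    )
    father_rank = None
    if father is not None and father in candidates:
        father_rank = int(table.loc[table["candidate"] == father, "rank"].iloc[0])
    return TutorRanking(focal=focal, table=table, father_rank=father_rank)
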