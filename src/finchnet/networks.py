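"""Simple-ratio-index association networks and the daily dyadic predictors.

For each dyad (i, j) the simple ratio index (SRI) is

    SRI = x / (x + y_i + y_j)

where x is the number of foraging events containing both birds and y_i (y_j)
the number containing i but not j (j but not i). It ranges from 0 (never in
the same foraging group) to 1 (always together). Counting is at the event
level — a bird detected several times in one event counts once — and dyads
never observed at all are assigned 0 so that daily matrices are complete.

Three predictors are derived per father-son dyad and day: the father-son
association strength, the father's weighted degree excluding the son
("father gregariousness") and the son's weighted degree excluding the father
("son gregariousness"). All metrics are computed on the full network,
including female associates; matrices are per aviary, cross-aviary dyads are
structurally zero and never enter the models.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import require_columns
from .events import GroupByIndividual

__all__ = [
    "sri_matrix",
    "weighted_degree_excluding",
    "father_son_dyads",
    "dyad_metrics",
    "daily_network_series",
]


def sri_from_counts(G: np.ndarray) -> np.ndarray:
    """SRI matrix from a binary events-by-individuals array (internal fast path)."""
    G = np.asarray(G, dtype=float)
    if G.size == 0:
        n = G.shape[1] if G.ndim == 2 else 0
        return np.zeros((n, n))
    X = G.T @ G  # co-occurrence counts
    n_obs = np.diag(X)
    denom = n_obs[:, None] + n_obs[None, :] - X
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(denom > 0, X / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(S, 0.0)
    return S


def sri_matrix(gbi: GroupByIndividual) -> pd.DataFrame:
    """Daily symmetric SRI matrix in [0, 1], zero diagonal, indexed by roster."""
    return pd.DataFrame(
        sri_from_counts(gbi.matrix), index=list(gbi.roster), columns=list(gbi.roster)
    )


def weighted_degree_excluding(matrix: pd.DataFrame, focal: str, excluded: str) -> float:
    """Sum of the focal bird's SRI values over all others except ``excluded``."""
    if focal == excluded:
        raise ValueError("focal and excluded bird must differ")
    row = matrix.loc[focal]
    drop = [b for b in (focal, excluded) if b in row.index]
    return float(row.drop(labels=drop).sum())


def father_son_dyads(birds: pd.DataFrame) -> pd.DataFrame:
    """All father-son dyads of a colony (one row per son)."""
    require_columns(birds, ["bird_id", "aviary_id", "family_id", "role"], "birds")
    sons = birds[birds["role"] == "son"]
    fathers = birds[birds["role"] == "father"].set_index("family_id")["bird_id"]
    rows = []
    for _, s in sons.iterrows():
        if s["family_id"] in fathers.index:
            rows.append((
                int(s["aviary_id"]), s["family_id"], s["bird_id"],
                fathers[s["family_id"]],
            ))
    return pd.DataFrame(rows, columns=["aviary_id", "family_id", "son_id", "father_id"])


def dyad_metrics(matrix: pd.DataFrame, dyads: pd.DataFrame) -> pd.DataFrame:
    """The three network predictors for each father-son dyad on one matrix."""
    rows = []
    for _, d in dyads.iterrows():
        f, s = d["father_id"], d["son_id"]
        strength = float(matrix.loc[f, s])
        rows.append((
            d["son_id"], d["father_id"], strength,
            weighted_degree_excluding(matrix, f, s),
            weighted_degree_excluding(matrix, s, f),
        ))
    return pd.DataFrame(rows, columns=[
        "son_id", "father_id", "father_son_strength",
        "father_gregariousness", "son_gregariousness",
    ])


def daily_network_series(gbis: Mapping[tuple, GroupByIndividual],
                         dyads: pd.DataFrame):
    """One SRI matrix plus father-son metrics per logged (aviary, day).

    Requires a consistent roster across days within each aviary. Returns
    ``(matrices, metrics)`` where ``matrices`` maps (aviary_id, day) to the
    SRI DataFrame and ``metrics`` is a long table with columns aviary_id,
    day, son_id, father_id, father_son_strength, father_gregariousness,
    son_gregariousness.
    """
    rosters: dict = {}
    for (a, d), gbi in gbis.items():
        if a in rosters and rosters[a] != gbi.roster:
            raise ValueError(f"roster mismatch across days in aviary {a}")
        rosters.setdefault(a, gbi.roster)
    matrices: dict = {}
    parts = []
    for (a, d), gbi in sorted(gbis.items()):
        M = sri_matrix(gbi)
        matrices[(a, d)] = M
        sub = dyads[dyads["aviary_id"] == a]
        if len(sub):
            m = dyad_metrics(M, sub)
            m.insert(0, "day", d)
            m.insert(0, "aviary_id", a)
            parts.append(m)
    metrics = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=[
            "aviary_id", "day", "son_id", "father_id", "father_son_strength",
            "father_gregariousness", "son_gregariousness",
        ])
    )
    return matrices, metrics
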