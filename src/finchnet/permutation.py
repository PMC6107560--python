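"""Datastream permutations of foraging groups and permutation p-values.

Social-network predictors violate the independence assumptions of parametric
mixed-model tests, so significance is assessed against a null distribution
built by *datastream permutation*: repeatedly swap two individuals between
two foraging events recorded at the same aviary, day and feeder, refit the
model after every swap, and record the slope. The swaps preserve event sizes
(row sums), each bird's number of visit bouts (column sums), the rosters and
the blocking structure, so the null distribution reflects "who could have
been in which group" given exactly the observed sampling.

The reference chain refits the linear mixed model by REML after every swap.
Because that dominates cost, a documented fast mode (``refit='gls'``,
non-reference) freezes the variance components at the observed REML fit and
solves the GLS normal equations in closed form per swap; at the observed
variance components the GLS fixed effects coincide with the REML fixed
effects, so observed slopes are identical between modes.

Two-tailed p-values use the add-one rule
``p = 2 * min(#{null >= obs} + 1, #{null <= obs} + 1) / (N + 1)``, capped at
1; one-tailed alternatives are exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from ._util import as_rng
from .events import GroupByIndividual
from .models import fit_lmm
from .networks import sri_from_counts

__all__ = [
    "PermutationResult",
    "swap_step",
    "run_swap_chain",
    "p_rand",
    "permutation_test",
]

NETWORK_COLUMNS = (
    "father_son_association",
    "father_gregariousness",
    "son_gregariousness",
)


@dataclass
class PermutationResult:
    term: str
    observed_slope: float
    null_slopes: np.ndarray
    p_rand: float
    null_range_95: tuple
    n_permutations: int
    seed: int

    def summary(self) -> dict:
        lo, hi = self.null_range_95
        return {
            "term": self.term,
            "observed_slope": self.observed_slope,
            "p_rand": self.p_rand,
            "null_2.5": lo,
            "null_97.5": hi,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def p_rand(observed: float, null_slopes, alternative: str = "two-sided") -> float:
    """Permutation p-value with add-one correction.

    Two-sided (default): twice the smaller tail, capped at 1. The observed
    value is counted as one member of the null (the +1), so p is never 0.
    """
    null_slopes = np.asarray(null_slopes, dtype=float)
    if null_slopes.size == 0:
        raise ValueError("null_slopes must be non-empty")
    n = null_slopes.size
    ge = int(np.sum(null_slopes >= observed)) + 1
    le = int(np.sum(null_slopes <= observed)) + 1
    if alternative == "greater":
        return min(ge / (n + 1), 1.0)
    if alternative == "less":
        return min(le / (n + 1), 1.0)
    if alternative == "two-sided":
        return min(2.0 * min(ge, le) / (n + 1), 1.0)
    raise ValueError(f"unknown alternative {alternative!r}")


# --------------------------------------------------------------------------- #
# swaps
# --------------------------------------------------------------------------- #

def _attempt_swap(G: np.ndarray, rows: np.ndarray, rng, max_tries: int = 100):
    """Try to swap two birds between two events (rows) of one block.

    Picks two distinct events uniformly, then a bird in the first but not the
    second and vice versa, uniformly among candidates. Returns
    (e1, e2, a, b) row/column indices, or None if no legal swap was found in
    ``max_tries`` attempts.
    """
    if len(rows) < 2:
        return None
    for _ in range(max_tries):
        i1, i2 = rng.choice(len(rows), size=2, replace=False)
        e1, e2 = rows[i1], rows[i2]
        r1, r2 = G[e1], G[e2]
        a_cand = np.flatnonzero((r1 == 1) & (r2 == 0))
        b_cand = np.flatnonzero((r2 == 1) & (r1 == 0))
        if a_cand.size and b_cand.size:
            a = int(a_cand[rng.integers(a_cand.size)])
            b = int(b_cand[rng.integers(b_cand.size)])
            G[e1, a] = 0
            G[e1, b] = 1
            G[e2, b] = 0
            G[e2, a] = 1
            return int(e1), int(e2), a, b
    return None


def swap_step(gbi: GroupByIndividual, rng=None, in_place: bool = False):
    """One constrained swap on a single day's GBI (blocks = feeders).

    Chooses a feeder block uniformly among those with at least two events,
    then attempts a legal swap within it. If no legal swap exists the input
    is returned unchanged with a warning. Row sums (event sizes) and column
    sums (per-bird bout counts) are invariant.
    """
    rng = as_rng(rng)
    out = gbi if in_place else gbi.copy()
    feeders = [f for f in np.unique(out.feeders) if np.sum(out.feeders == f) >= 2]
    if feeders:
        f = feeders[int(rng.integers(len(feeders)))]
        rows = np.flatnonzero(out.feeders == f)
        if _attempt_swap(out.matrix, rows, rng) is not None:
            return out
    warnings.warn(
        f"no legal swap in aviary {gbi.aviary_id} day {gbi.day}; GBI unchanged",
        stacklevel=2,
    )
    return out


def _block_index(gbis: dict) -> list:
    """(key, feeder, row indices) for every block with >= 2 events."""
    blocks = []
    for key in sorted(gbis):
        gbi = gbis[key]
        for f in np.unique(gbi.feeders):
            rows = np.flatnonzero(gbi.feeders == f)
            if rows.size >= 2:
                blocks.append((key, int(f), rows))
    return blocks


def run_swap_chain(gbis: dict, n_swaps: int, seed: int = 0, log: list | None = None):
    """Chain ``n_swaps`` constrained swaps across all (aviary, day) GBIs.

    Each step picks a block (aviary, day, feeder) uniformly among those with
    at least two events. Returns ``(swapped copy of gbis, number of accepted
    swaps)``; with ``log`` a list, appends (aviary, day, feeder, e1, e2,
    bird_out, bird_in) per accepted swap for auditing.
    """
    rng = np.random.default_rng(seed)
    out = {k: g.copy() for k, g in gbis.items()}
    blocks = _block_index(out)
    if not blocks:
        return out, 0
    accepted = 0
    for _ in range(n_swaps):
        key, f, rows = blocks[int(rng.integers(len(blocks)))]
        res = _attempt_swap(out[key].matrix, rows, rng)
        if res is not None:
            accepted += 1
            if log is not None:
                e1, e2, a, b = res
                roster = out[key].roster
                log.append((key[0], key[1], f, e1, e2, roster[a], roster[b]))
    return out, accepted


# --------------------------------------------------------------------------- #
# GLS refit with frozen variance components
# --------------------------------------------------------------------------- #

def _gls_beta(X, y, codes, n_groups, rho):
    """Fixed effects of a random-intercept model with known variance ratio.

    With V = sigma_e^2 (I + rho Z Z'), per group g of size n_g the inverse is
    (I - c_g J)/sigma_e^2 with c_g = rho / (1 + n_g rho); sigma_e^2 cancels
    from the normal equations.
    """
    Sg = np.zeros((n_groups, X.shape[1]))
    np.add.at(Sg, codes, X)
    tg = np.bincount(codes, weights=y, minlength=n_groups)
    ng = np.bincount(codes, minlength=n_groups)
    c = rho / (1.0 + ng * rho)
    A = X.T @ X - (Sg * c[:, None]).T @ Sg
    b = X.T @ y - Sg.T @ (c * tg)
    return np.linalg.solve(A, b)


def _reml_beta(X, y, groups):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        res = sm.MixedLM(y, X, groups=groups).fit(reml=True, method="lbfgs")
    return np.asarray(res.fe_params, dtype=float)


# --------------------------------------------------------------------------- #
# the full chain: swap -> update network metrics -> refit -> record slope
# --------------------------------------------------------------------------- #

def permutation_test(
    gbis: dict,
    dyads: pd.DataFrame,
    table: pd.DataFrame,
    response: str,
    fixed_effects: list,
    *,
    group: str = "family_id",
    response_is_network: bool = False,
    n_permutations: int = 10_000,
    seed: int = 0,
    refit: str = "gls",
    focal_terms: list | None = None,
    burn_in: int = 0,
    thin: int = 1,
    audit_every: int = 1000,
    max_fail_frac: float = 0.01,
    log: list | None = None,
) -> dict:
    """Permutation p-values for mixed-model slopes under datastream swaps.

    ``table`` must be a day-level model table (one row per son and day) whose
    network columns (``father_son_association``, ``father_gregariousness``,
    ``son_gregariousness`` — whichever the model uses, or the response when
    ``response_is_network``) were computed from ``gbis``. After every swap the
    SRI matrix and the father-son metrics of the affected (aviary, day) are
    recomputed, the model refit, and every fixed-effect slope recorded
    (``thin`` > 1 records every thin-th swap; ``burn_in`` swaps are discarded
    first).

    ``refit='reml'`` is the reference (full REML refit per swap);
    ``refit='gls'`` is the documented fast mode with variance components
    frozen at the observed fit. Margins are audited every ``audit_every``
    swaps; more than ``max_fail_frac`` failed refits aborts.

    Returns a dict term -> :class:`PermutationResult` for ``focal_terms``
    (default: every fixed effect).
    """
    if refit not in ("gls", "reml"):
        raise ValueError(f"unknown refit mode {refit!r}")
    if "day" not in table.columns:
        raise ValueError("permutation_test needs a day-level model table")
    rng = np.random.default_rng(seed)

    # observed fit (reference REML); defines frozen variance components
    observed = fit_lmm(table, response, fixed_effects, group=group)
    sigma_f, sigma_e = observed.random_variance, observed.residual_variance
    rho = sigma_f / sigma_e if sigma_e > 0 else 0.0

    gbis = {k: g.copy() for k, g in gbis.items()}
    blocks = _block_index(gbis)
    if not blocks:
        raise ValueError("no permutable blocks: every feeder-day has < 2 events")

    names = ["intercept", *fixed_effects]
    X = np.column_stack(
        [np.ones(len(table))]
        + [np.asarray(table[c], dtype=float) for c in fixed_effects]
    )
    y = np.asarray(table[response], dtype=float)
    codes, levels = pd.factorize(table[group])
    col_pos = {c: i + 1 for i, c in enumerate(fixed_effects)}
    groups = np.asarray(table[group])

    # map each (aviary, day) to its table rows and roster positions
    av = np.asarray(table["aviary_id"])
    dy = np.asarray(table["day"])
    rowmap: dict = {}
    for key, gbi in gbis.items():
        a, d = key
        rows = np.flatnonzero((av == a) & (dy == d))
        if rows.size == 0:
            continue
        pos = {b: i for i, b in enumerate(gbi.roster)}
        sub = table.iloc[rows]
        fidx = np.array([pos[b] for b in sub["father_id"]])
        sidx = np.array([pos[b] for b in sub["son_id"]])
        rowmap[key] = (rows, fidx, sidx)

    def _update(key):
        if key not in rowmap:
            return
        rows, fidx, sidx = rowmap[key]
        S = sri_from_counts(gbis[key].matrix)
        rs = S.sum(axis=1)
        strength = S[fidx, sidx]
        if response_is_network:
            y[rows] = strength
        if "father_son_association" in col_pos:
            X[rows, col_pos["father_son_association"]] = strength
        if "father_gregariousness" in col_pos:
            X[rows, col_pos["father_gregariousness"]] = rs[fidx] - strength
        if "son_gregariousness" in col_pos:
            X[rows, col_pos["son_gregariousness"]] = rs[sidx] - strength

    # margins for conservation audits
    margins0 = {
        k: (g.event_sizes().copy(), g.bout_counts().copy()) for k, g in gbis.items()
    }

    n_recorded = 0
    null = np.empty((n_permutations, len(names)))
    n_fail = 0
    step = 0
    while n_recorded < n_permutations:
        step += 1
        key, f, rows = blocks[int(rng.integers(len(blocks)))]
        res = _attempt_swap(gbis[key].matrix, rows, rng)
        if res is not None:
            _update(key)
            if log is not None:
                e1, e2, a, b = res
                roster = gbis[key].roster
                log.append((key[0], key[1], f, e1, e2, roster[a], roster[b]))
        if audit_every and step % audit_every == 0:
            for k, (es, bc) in margins0.items():
                g = gbis[k]
                if not (np.array_equal(g.event_sizes(), es)
                        and np.array_equal(g.bout_counts(), bc)):
                    raise AssertionError(
                        f"margin conservation violated at {k} after {step} swaps"
                    )
        if step <= burn_in or (step - burn_in) % thin != 0:
            continue
        try:
            if refit == "gls":
                beta = _gls_beta(X, y, codes, len(levels), rho)
            else:
                beta = _reml_beta(X, y, groups)
        except Exception:
            n_fail += 1
            if n_fail > max(10, max_fail_frac * n_permutations):
                raise RuntimeError(
                    f"{n_fail} permutation refits failed "
                    f"(> {max_fail_frac:.0%} of {n_permutations})"
                )
            continue
        null[n_recorded] = beta
        n_recorded += 1

    if focal_terms is None:
        focal_terms = list(fixed_effects)
    out = {}
    for term in focal_terms:
        i = names.index(term)
        slopes = null[:, i]
        lo, hi = np.percentile(slopes, [2.5, 97.5])
        out[term] = PermutationResult(
            term=term,
            observed_slope=observed.slope(term),
            null_slopes=slopes,
            p_rand=p_rand(observed.slope(term), slopes),
            null_range_95=(float(lo), float(hi)),
            n_permutations=n_permutations,
            seed=seed,
        )
    return out


def null_slope_distribution(
    gbis, dyads, table, response, fixed_effects, focal_term, **kwargs
) -> PermutationResult:
    """Null slope distribution for a single focal fixed effect (see
    :func:`permutation_test` for the chain semantics)."""
    res = permutation_test(
        gbis, dyads, table, response, fixed_effects,
        focal_terms=[focal_term], **kwargs,
    )
    return res[focal_term]
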