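"""Desk-scale validation experiments on synthetic colonies.

These runners quantify, with known ground truth, the properties a user
should demand of the pipeline before trusting it on real colonies:

* conservation — chained datastream swaps leave every event size and every
  bird's bout count untouched;
* calibration — when songs are generated independently of the foraging
  network, the permutation test of the association slope rejects at the
  nominal rate;
* recovery — the father is recovered as the rank-1 tutor when copy noise is
  small; the LMM recovers known generator slopes within its standard errors;
  and strongly generated association-similarity effects yield small
  permutation p-values;
* event detection — detected event partitions match the generator's labels.

Each runner takes an explicit seed and is deterministic given it. Replicate
seeds are drawn from a child generator so runners can be scaled without
correlating replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from ._util import child_seed
from .events import build_gbi, detect_events
from .models import build_dissimilarity_table, fit_lmm
from .networks import daily_network_series, father_son_dyads
from .permutation import permutation_test, run_swap_chain
from .song import motif_pair_dissimilarity, standardize_elements
from .synthetic import (
    ColonyConfig,
    generate_colony,
    simulate_visit_stream,
    synthesize_songs,
)

__all__ = [
    "null_colony_config",
    "strong_effect_config",
    "father_son_scores",
    "colony_model_inputs",
    "swap_conservation",
    "type1_calibration",
    "permutation_power",
    "tutor_recovery",
    "lmm_slope_recovery",
    "event_detection_ari",
]

DISSIM_FIXED = [
    "cort_treatment",
    "father_son_association",
    "father_gregariousness",
    "son_gregariousness",
    "n_fledglings",
]


def null_colony_config(seed: int) -> ColonyConfig:
    """Study conditions with every generated effect switched off.

    Tutors are chosen uniformly among adult males (no association-similarity
    link) and both CORT effects are zero, so any father-son song
    dissimilarity pattern is unrelated to the foraging network.
    """
    return ColonyConfig(
        seed=seed,
        tutor_weight_exponent=0.0,
        cort_affinity_effect=0.0,
        cort_copy_noise_effect=0.0,
    )


def strong_effect_config(seed: int) -> ColonyConfig:
    """Study conditions with strong association-similarity coupling.

    Heterogeneous affinities plus a steep tutor-choice exponent make sons
    with strong father ties copy the father (low dissimilarity) and weakly
    tied sons copy someone else (high dissimilarity); CORT effects are large.
    """
    return ColonyConfig(
        seed=seed,
        affinity_sd=0.8,
        tutor_weight_exponent=6.0,
        copy_noise_sd=0.05,
        cort_copy_noise_effect=0.2,
        cort_affinity_effect=-0.4,
    )


def father_son_scores(colony, songs) -> dict:
    """Father-son motif dissimilarity per son, on standardized traces."""
    std = standardize_elements(songs)
    return {
        son: motif_pair_dissimilarity(std[tutor_father], std[son])
        for son, tutor_father in (
            (row["son_id"], row["father_id"])
            for _, row in father_son_dyads(colony.birds).iterrows()
        )
    }


def colony_model_inputs(config: ColonyConfig, event_method: str = "gap"):
    """Generate a colony and run it to the model table (the fast gap detector
    by default). Returns (colony, gbis, dyads, day-level dissimilarity table)."""
    colony = generate_colony(config)
    stream, _labels = simulate_visit_stream(colony, config)
    songs = synthesize_songs(colony, config)
    events = detect_events(stream, event_method)
    rosters = {a: colony.roster(a) for a in colony.aviaries}
    gbis = build_gbi(events, rosters, days=range(1, config.n_days + 1))
    dyads = father_son_dyads(colony.birds)
    _, metrics = daily_network_series(gbis, dyads)
    table = build_dissimilarity_table(
        metrics, colony.birds, colony.family_sizes(),
        father_son_scores(colony, songs), aggregate="day",
    )
    return colony, gbis, dyads, table


# --------------------------------------------------------------------------- #
# runners
# --------------------------------------------------------------------------- #

def swap_conservation(n_swaps: int = 10_000, seed: int = 0) -> dict:
    """Chain swaps over a full 33-day colony; count margin violations."""
    config = ColonyConfig(seed=child_seed(seed, "conservation"))
    colony = generate_colony(config)
    stream, _ = simulate_visit_stream(colony, config)
    events = detect_events(stream, "gap")
    gbis = build_gbi(events, {a: colony.roster(a) for a in colony.aviaries})
    swapped, accepted = run_swap_chain(gbis, n_swaps, seed=child_seed(seed, "chain"))
    violations = 0
    for key, gbi in gbis.items():
        after = swapped[key]
        if not np.array_equal(gbi.event_sizes(), after.event_sizes()):
            violations += 1
        if not np.array_equal(gbi.bout_counts(), after.bout_counts()):
            violations += 1
        if gbi.roster != after.roster or not np.array_equal(gbi.feeders, after.feeders):
            violations += 1
    return {"n_swaps": n_swaps, "accepted": accepted, "violations": violations}


def _association_p(config: ColonyConfig, n_permutations: int, seed: int) -> float:
    _colony, gbis, dyads, table = colony_model_inputs(config)
    res = permutation_test(
        gbis, dyads, table, "response", DISSIM_FIXED,
        n_permutations=n_permutations, seed=seed, refit="gls",
        focal_terms=["father_son_association"], audit_every=0,
    )
    return res["father_son_association"].p_rand


def type1_calibration(n_replicates: int = 200, n_permutations: int = 1000,
                      alpha: float = 0.05, seed: int = 0) -> dict:
    """Rejection rate of the association-slope permutation test on null colonies."""
    rng = np.random.default_rng(child_seed(seed, "type1"))
    rejections = 0
    for _ in range(n_replicates):
        s = int(rng.integers(2**31))
        p = _association_p(null_colony_config(s), n_permutations, seed=s)
        rejections += p < alpha
    return {
        "n_replicates": n_replicates,
        "n_permutations": n_permutations,
        "rejection_rate": rejections / n_replicates,
    }


def permutation_power(n_replicates: int = 50, n_permutations: int = 1000,
                      alpha: float = 0.05, seed: int = 0) -> dict:
    """Power of the association-slope test under strong generated effects."""
    rng = np.random.default_rng(child_seed(seed, "power"))
    hits = 0
    for _ in range(n_replicates):
        s = int(rng.integers(2**31))
        p = _association_p(strong_effect_config(s), n_permutations, seed=s)
        hits += p < alpha
    return {
        "n_replicates": n_replicates,
        "n_permutations": n_permutations,
        "power": hits / n_replicates,
    }


def tutor_recovery(n_colonies: int = 3, seed: int = 0) -> dict:
    """How often the father is the rank-1 tutor when he is the true tutor.

    Uses small copy noise relative to founder-motif separation, the regime in
    which the DTW ranking should recover the generative tutor.
    """
    from .pipeline import rank_all_tutors
    from .song import motif_dissimilarity_matrix

    rng = np.random.default_rng(child_seed(seed, "tutor"))
    hits = total = 0
    for _ in range(n_colonies):
        config = ColonyConfig(
            seed=int(rng.integers(2**31)),
            copy_noise_sd=0.05, cort_copy_noise_effect=0.0,
        )
        colony = generate_colony(config)
        songs = synthesize_songs(colony, config)
        D = motif_dissimilarity_matrix(standardize_elements(songs))
        rankings = rank_all_tutors(D, colony.birds)
        fathers = colony.birds[colony.birds["role"] == "father"].set_index(
            "family_id")["bird_id"]
        meta = colony.birds.set_index("bird_id")
        for son, r in rankings.items():
            if colony.true_tutor[son] == fathers[meta.loc[son, "family_id"]]:
                total += 1
                hits += r.father_rank == 1
    return {"n_sons": total, "father_rank1_rate": hits / total if total else np.nan}


def lmm_slope_recovery(n_replicates: int = 200, n_obs: int = 200,
                       slope: float = 0.5, noise_sd: float = 0.1,
                       group_sd: float = 0.1, seed: int = 0) -> dict:
    """Fraction of replicates whose LMM slope lands within 3 s.e. of truth."""
    rng = np.random.default_rng(child_seed(seed, "lmm"))
    n_groups = 40
    per = n_obs // n_groups
    hits = 0
    for _ in range(n_replicates):
        g = np.repeat(np.arange(n_groups), per)
        x = rng.normal(size=n_obs)
        y = slope * x + rng.normal(0, group_sd, n_groups)[g] + rng.normal(
            0, noise_sd, n_obs)
        table = pd.DataFrame({"y": y, "x": x, "family_id": g})
        fit = fit_lmm(table, "y", ["x"])
        hits += abs(fit.slope("x") - slope) <= 3 * fit.se("x")
    return {"n_replicates": n_replicates, "coverage_3se": hits / n_replicates}


def event_detection_ari(n_days: int = 3, seed: int = 0) -> dict:
    """Adjusted Rand index of detected vs true event partitions, both methods."""
    config = ColonyConfig(seed=child_seed(seed, "ari"), n_days=n_days)
    colony = generate_colony(config)
    stream, labels = simulate_visit_stream(colony, config)
    out = {}
    for method in ("gap", "gmm"):
        _events, detected = detect_events(stream, method, return_labels=True)
        out[f"ari_{method}"] = float(adjusted_rand_score(labels, detected))
    return out
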