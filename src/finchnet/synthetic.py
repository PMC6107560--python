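"""Synthetic zebra-finch colonies with known social and vocal ground truth.

The generator emulates the study system the pipeline analyses: two indoor
aviaries each housing six to seven families (a father, a mother and a brood of
fledglings), with every bird's visits to two feeders per aviary logged for 33
days. Half of each brood received an early-life corticosterone (CORT)
treatment, balanced within the brood. Latent dyadic *affinities* (elevated
within families, optionally perturbed for CORT sons' father-son dyads) drive
who forages together; each son acquires his crystallized song motif by copying
a *true tutor* chosen among the aviary's adult males with probability
proportional to affinity raised to a configurable exponent, with elementwise
copy noise that can be inflated by the CORT treatment.

Because affinities, gregariousness, tutors and copy noise are all returned as
ground truth, every downstream stage (event detection, simple-ratio-index
networks, DTW song comparison, mixed models, permutation inference) can be
tested for recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.special import expit

from ._util import SEC_PER_DAY, as_rng, child_seed
from .song import ElementTrace

__all__ = ["ColonyConfig", "ColonyTruth", "generate_colony",
           "simulate_visit_stream", "synthesize_songs", "generate_dataset"]

#: Gaussian jitter (s) applied to each bird's timestamp around the event
#: centre; gives event durations of the same order as real flock-feeding
#: bouts (a few minutes).
TIME_JITTER_SD = 30.0


@dataclass(frozen=True)
class ColonyConfig:
    """Study-design constants and generative parameters of a colony.

    Defaults mirror the study conditions: 2 aviaries of 7 and 6 families,
    33 days of visit logging, 2 feeders per aviary, broods balanced between
    CORT and control chicks.
    """

    n_aviaries: int = 2
    families_per_aviary: tuple | int = (7, 6)
    brood_size_range: tuple = (2, 4)
    p_male: float = 0.5
    n_days: int = 33
    feeders_per_aviary: int = 2
    #: expected flock-feeding events per feeder per day (Poisson)
    event_rate: float = 30.0
    #: minimum separation between event centres within a feeder-day (s)
    min_event_spacing_s: float = 900.0
    #: latent affinity of a dyad from different families
    affinity_baseline: float = 0.3
    #: additive bonus for dyads within the same family
    affinity_within_family: float = 1.5
    #: sd of symmetric dyad-level jitter on affinities
    affinity_sd: float = 0.2
    #: additive shift on father-son affinity for CORT-treated sons
    cort_affinity_effect: float = -0.15
    #: sd of per-bird gregariousness (log-odds offset on joining events)
    gregariousness_sd: float = 0.5
    #: baseline log-odds of joining an event (before gregariousness/affinity)
    join_base_logit: float = -1.5
    #: tutor sampled with probability ~ affinity**exponent (0 = uniform)
    tutor_weight_exponent: float = 2.0
    #: elementwise copy-noise sd for control sons
    copy_noise_sd: float = 0.12
    #: additive copy-noise increment for CORT sons
    cort_copy_noise_effect: float = 0.08
    elements_per_motif: int = 4
    n_motifs_per_male: int = 1
    trace_length_range: tuple = (20, 30)
    n_features: int = 2
    seed: int = 0

    def __post_init__(self):
        fams = self.families_per_aviary
        if isinstance(fams, int):
            fams = (fams,) * self.n_aviaries
        else:
            fams = tuple(int(f) for f in fams)
        if len(fams) != self.n_aviaries:
            raise ValueError(
                "families_per_aviary must be an int or one entry per aviary"
            )
        object.__setattr__(self, "families_per_aviary", fams)
        counts = {
            "n_aviaries": self.n_aviaries,
            "feeders_per_aviary": self.feeders_per_aviary,
            "elements_per_motif": self.elements_per_motif,
            "n_motifs_per_male": self.n_motifs_per_male,
            "n_features": self.n_features,
            **{f"families_per_aviary[{i}]": f for i, f in enumerate(fams)},
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"invalid config: {name} must be >= 1, got {value}")
        if self.n_days < 0:
            raise ValueError("invalid config: n_days must be >= 0")
        if not (0.0 <= self.p_male <= 1.0):
            raise ValueError("invalid config: p_male must be in [0, 1]")
        lo, hi = self.brood_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid config: brood_size_range must be [lo, hi], lo >= 1")
        lo, hi = self.trace_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid config: trace_length_range must be [lo, hi], lo >= 1")
        for name in ("event_rate", "affinity_baseline", "affinity_within_family",
                     "affinity_sd", "gregariousness_sd", "copy_noise_sd",
                     "tutor_weight_exponent", "min_event_spacing_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid config: {name} must be >= 0")


@dataclass
class ColonyTruth:
    """Ground truth of a generated colony.

    ``birds`` holds one row per bird (bird_id, aviary_id, family_id, sex,
    role, treatment); ``affinity`` one symmetric non-negative matrix per
    aviary (zero diagonal) indexed by the aviary roster; ``true_tutor`` and
    ``true_copy_noise`` are keyed by son ID.
    """

    birds: pd.DataFrame
    affinity: dict  # aviary_id -> pd.DataFrame
    gregariousness: pd.Series
    true_tutor: dict
    true_copy_noise: dict

    def roster(self, aviary_id: int) -> list:
        sel = self.birds.loc[self.birds["aviary_id"] == aviary_id, "bird_id"]
        return sorted(sel)

    @property
    def aviaries(self) -> list:
        return sorted(self.birds["aviary_id"].unique())

    @property
    def sons(self) -> pd.DataFrame:
        return self.birds[self.birds["role"] == "son"]

    @property
    def males(self) -> pd.DataFrame:
        return self.birds[self.birds["sex"] == "M"]

    def family_sizes(self) -> pd.DataFrame:
        """Per family: number of fledglings and number of male offspring."""
        off = self.birds[self.birds["role"].isin(["son", "daughter"])]
        n_fled = off.groupby("family_id").size().rename("n_fledglings")
        n_male = (
            off[off["role"] == "son"].groupby("family_id").size()
            .reindex(n_fled.index, fill_value=0).rename("n_male_offspring")
        )
        return pd.concat([n_fled, n_male], axis=1).reset_index()


def _balanced_treatments(n: int, rng: np.random.Generator) -> list:
    """CORT/control split of a brood with |#CORT - #control| <= 1."""
    half = n // 2
    labels = ["CORT"] * half + ["control"] * half
    if n % 2:
        labels.append("CORT" if rng.random() < 0.5 else "control")
    rng.shuffle(labels)
    return labels


def generate_colony(config: ColonyConfig) -> ColonyTruth:
    """Draw family structure, treatments, affinities, gregariousness and tutors."""
    rng = np.random.default_rng(child_seed(config.seed, "colony"))
    lo, hi = config.brood_size_range

    rows = []
    fam_counter = 0
    for a in range(1, config.n_aviaries + 1):
        for _f in range(config.families_per_aviary[a - 1]):
            fam_counter += 1
            fid = f"F{fam_counter:02d}"
            rows.append((f"{fid}DAD", a, fid, "M", "father", "adult"))
            rows.append((f"{fid}MUM", a, fid, "F", "mother", "adult"))
            n_chicks = int(rng.integers(lo, hi + 1))
            treatments = _balanced_treatments(n_chicks, rng)
            for c in range(n_chicks):
                male = rng.random() < config.p_male
                rows.append((
                    f"{fid}C{c + 1}", a, fid,
                    "M" if male else "F",
                    "son" if male else "daughter",
                    treatments[c],
                ))
    birds = pd.DataFrame(
        rows, columns=["bird_id", "aviary_id", "family_id", "sex", "role", "treatment"]
    )

    gregariousness = pd.Series(
        rng.normal(0.0, config.gregariousness_sd, len(birds)),
        index=birds["bird_id"].to_numpy(), name="gregariousness",
    )

    affinity: dict = {}
    for a in range(1, config.n_aviaries + 1):
        roster = sorted(birds.loc[birds["aviary_id"] == a, "bird_id"])
        n = len(roster)
        fam = birds.set_index("bird_id").loc[roster, "family_id"].to_numpy()
        A = np.full((n, n), config.affinity_baseline)
        A += config.affinity_within_family * (fam[:, None] == fam[None, :])
        if config.affinity_sd > 0:
            jit = rng.normal(0.0, config.affinity_sd, (n, n))
            A += np.triu(jit, 1) + np.triu(jit, 1).T
        # CORT shift on father-son dyads of treated sons
        sub = birds[birds["aviary_id"] == a].set_index("bird_id")
        pos = {b: i for i, b in enumerate(roster)}
        for son, row in sub[(sub["role"] == "son") & (sub["treatment"] == "CORT")].iterrows():
            father = f"{row['family_id']}DAD"
            i, j = pos[son], pos[father]
            A[i, j] += config.cort_affinity_effect
            A[j, i] += config.cort_affinity_effect
        np.clip(A, 0.0, None, out=A)
        np.fill_diagonal(A, 0.0)
        affinity[a] = pd.DataFrame(A, index=roster, columns=roster)

    # true tutors: adult males of the son's aviary, weighted by affinity**w
    true_tutor: dict = {}
    w = config.tutor_weight_exponent
    for a in range(1, config.n_aviaries + 1):
        sub = birds[birds["aviary_id"] == a]
        adult_males = sorted(sub.loc[sub["role"] == "father", "bird_id"])
        A = affinity[a]
        for son in sorted(sub.loc[sub["role"] == "son", "bird_id"]):
            if not adult_males:
                raise ValueError(f"son {son}: no candidate tutors in aviary {a}")
            weights = A.loc[son, adult_males].to_numpy() ** w if w > 0 else np.ones(
                len(adult_males)
            )
            if weights.sum() <= 0:
                weights = np.ones(len(adult_males))
            true_tutor[son] = str(rng.choice(adult_males, p=weights / weights.sum()))

    noise = {}
    sub = birds.set_index("bird_id")
    for son in true_tutor:
        bump = config.cort_copy_noise_effect if sub.loc[son, "treatment"] == "CORT" else 0.0
        noise[son] = max(config.copy_noise_sd + bump, 0.0)

    return ColonyTruth(birds, affinity, gregariousness, true_tutor, noise)


def _spaced_centres(n: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """n sorted event centres in [0, 86400) with pairwise gaps >= spacing."""
    if n == 0:
        return np.empty(0)
    n = min(n, int(SEC_PER_DAY // max(spacing, 1.0)))
    slack = SEC_PER_DAY - (n - 1) * spacing
    u = np.sort(rng.uniform(0.0, slack, n))
    return u + np.arange(n) * spacing


def simulate_visit_stream(colony: ColonyTruth, config: ColonyConfig):
    """Simulate the RFID detection stream of flock-feeding events.

    Events per feeder-day are Poisson(``event_rate``) with centres at least
    ``min_event_spacing_s`` apart. Each event starts from one uniformly chosen
    seed bird; the remaining roster is visited in a per-event shuffled order
    and each bird joins with probability
    sigmoid(join_base_logit + gregariousness + mean affinity to current
    members). Joining birds get timestamps = centre + N(0, 30 s) truncated to
    the day.

    Returns ``(stream, labels)``: a detection table with columns
    (bird_id, aviary_id, feeder_id, day, time_s) and a Series of ground-truth
    event identifiers aligned with it.
    """
    rng = np.random.default_rng(child_seed(config.seed, "visits"))
    records = []
    labels = []
    for a in colony.aviaries:
        roster = colony.roster(a)
        n = len(roster)
        A = colony.affinity[a].to_numpy()
        greg = colony.gregariousness.loc[roster].to_numpy()
        for day in range(1, config.n_days + 1):
            for feeder in range(1, config.feeders_per_aviary + 1):
                n_ev = int(rng.poisson(config.event_rate))
                centres = _spaced_centres(n_ev, config.min_event_spacing_s, rng)
                for k, centre in enumerate(centres):
                    order = rng.permutation(n)
                    seed_bird = int(order[0])
                    members = [seed_bird]
                    aff_sum = A[:, seed_bird].copy()
                    for i in order[1:]:
                        logit = (
                            config.join_base_logit
                            + greg[i]
                            + aff_sum[i] / len(members)
                        )
                        if rng.random() < expit(logit):
                            members.append(int(i))
                            aff_sum += A[:, i]
                    times = np.clip(
                        centre + rng.normal(0.0, TIME_JITTER_SD, len(members)),
                        0.0, SEC_PER_DAY - 1e-6,
                    )
                    uid = f"A{a}D{day}F{feeder}E{k}"
                    for m, t in zip(members, times):
                        records.append((roster[m], a, feeder, day, float(t)))
                        labels.append(uid)
    stream = pd.DataFrame(
        records, columns=["bird_id", "aviary_id", "feeder_id", "day", "time_s"]
    )
    return stream, pd.Series(labels, index=stream.index, name="true_event")


def _founder_element(length: int, n_features: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth random feature trajectory: a sum of low-order random sinusoids."""
    t = np.linspace(0.0, 1.0, length)
    vals = np.empty((length, n_features))
    for f in range(n_features):
        y = np.zeros(length)
        f0 = rng.uniform(0.7, 1.6)
        for h in range(1, 4):
            amp = rng.normal(0.0, 1.0 / h)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            y += amp * np.sin(2.0 * np.pi * h * f0 * t + phase)
        y += rng.normal(0.0, 0.5) * (t - 0.5)  # gentle trend
        vals[:, f] = y
    return vals


def synthesize_songs(colony: ColonyTruth, config: ColonyConfig) -> dict:
    """Founder motifs for adult males; noisy tutor copies for sons.

    Each adult male gets ``n_motifs_per_male`` independent founder motifs of
    ``elements_per_motif`` smooth random elements. Each son copies his true
    tutor's motifs element-by-element with additive Gaussian noise of sd
    ``true_copy_noise`` (copy_noise_sd, plus cort_copy_noise_effect if
    CORT-treated). Females receive no motifs (female zebra finches do not
    sing).
    """
    rng = np.random.default_rng(child_seed(config.seed, "songs"))
    lo, hi = config.trace_length_range
    motifs: dict = {}
    fathers = sorted(colony.birds.loc[colony.birds["role"] == "father", "bird_id"])
    for male in fathers:
        renditions = []
        for m in range(config.n_motifs_per_male):
            motif = []
            for e in range(config.elements_per_motif):
                length = int(rng.integers(lo, hi + 1))
                motif.append(ElementTrace(
                    _founder_element(length, config.n_features, rng), male, m, e
                ))
            renditions.append(motif)
        motifs[male] = renditions

    for son in sorted(colony.sons["bird_id"]):
        tutor = colony.true_tutor.get(son)
        if tutor is None or tutor not in motifs:
            raise ValueError(f"son {son} has no candidate tutor with a motif")
        sd = colony.true_copy_noise[son]
        renditions = []
        for m, motif in enumerate(motifs[tutor]):
            copied = []
            for el in motif:
                vals = el.values + rng.normal(0.0, sd, el.values.shape)
                copied.append(ElementTrace(vals, son, m, el.element_idx))
            renditions.append(copied)
        motifs[son] = renditions
    return motifs


def generate_dataset(config: ColonyConfig):
    """Convenience wrapper: colony + visit stream + truth labels + songs."""
    colony = generate_colony(config)
    stream, labels = simulate_visit_stream(colony, config)
    songs = synthesize_songs(colony, config)
    return colony, stream, labels, songs
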