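"""Colony generator: design constants, determinism, treatment balance."""

import numpy as np
import pandas as pd
import pytest

from finchnet.song import motif_pair_dissimilarity, standardize_elements
from finchnet.synthetic import (
    ColonyConfig,
    _balanced_treatments,
    generate_colony,
    simulate_visit_stream,
    synthesize_songs,
)


class TestGenerateColony:
    def test_identical_seed_identical_colony(self, small_config):
        a = generate_colony(small_config)
        b = generate_colony(small_config)
        pd.testing.assert_frame_equal(a.birds, b.birds)
        assert a.true_tutor == b.true_tutor
        for av in a.affinity:
            pd.testing.assert_frame_equal(a.affinity[av], b.affinity[av])

    def test_study_design_defaults(self):
        colony = generate_colony(ColonyConfig(seed=0))
        fams = colony.birds.groupby("aviary_id")["family_id"].nunique()
        assert fams[1] == 7 and fams[2] == 6
        assert set(colony.birds["role"]) <= {"father", "mother", "son", "daughter"}
        # adults untreated, treatments only on offspring
        adults = colony.birds[colony.birds["role"].isin(["father", "mother"])]
        assert (adults["treatment"] == "adult").all()

    def test_brood_sizes_within_range(self):
        cfg = ColonyConfig(seed=3, brood_size_range=(2, 5))
        colony = generate_colony(cfg)
        sizes = (
            colony.birds[colony.birds["role"].isin(["son", "daughter"])]
            .groupby("family_id").size()
        )
        assert sizes.between(2, 5).all()

    def test_treatment_balanced_within_every_brood(self):
        for seed in range(5):
            colony = generate_colony(ColonyConfig(seed=seed, brood_size_range=(2, 6)))
            off = colony.birds[colony.birds["role"].isin(["son", "daughter"])]
            for _, fam in off.groupby("family_id"):
                n_cort = (fam["treatment"] == "CORT").sum()
                n_ctrl = (fam["treatment"] == "control").sum()
                assert abs(n_cort - n_ctrl) <= 1

    def test_balanced_assignment_rule_exhaustively(self):
        # 10,000 odd-sized broods: counts always split 2/3
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            t = _balanced_treatments(5, rng)
            assert sorted((t.count("CORT"), t.count("control"))) == [2, 3]

    def test_affinity_symmetric_zero_diagonal_nonnegative(self, small_colony):
        for A in small_colony.affinity.values():
            arr = A.to_numpy()
            assert np.allclose(arr, arr.T)
            assert np.all(np.diag(arr) == 0)
            assert (arr >= 0).all()

    def test_degenerate_weighting_makes_father_the_tutor(self):
        cfg = ColonyConfig(
            seed=5, cort_affinity_effect=0.0, tutor_weight_exponent=50.0,
            affinity_within_family=5.0, affinity_baseline=0.1, affinity_sd=0.0,
        )
        colony = generate_colony(cfg)
        fathers = colony.birds[colony.birds["role"] == "father"].set_index(
            "family_id")["bird_id"]
        meta = colony.birds.set_index("bird_id")
        for son, tutor in colony.true_tutor.items():
            assert tutor == fathers[meta.loc[son, "family_id"]]

    def test_tutor_is_male_in_same_aviary(self, small_colony):
        meta = small_colony.birds.set_index("bird_id")
        for son, tutor in small_colony.true_tutor.items():
            assert meta.loc[tutor, "sex"] == "M"
            assert meta.loc[tutor, "aviary_id"] == meta.loc[son, "aviary_id"]

    def test_zero_families_rejected(self):
        with pytest.raises(ValueError, match="families_per_aviary"):
            ColonyConfig(families_per_aviary=0)

    def test_cort_copy_noise_shift(self, small_colony, small_config):
        meta = small_colony.birds.set_index("bird_id")
        for son, noise in small_colony.true_copy_noise.items():
            expected = small_config.copy_noise_sd
            if meta.loc[son, "treatment"] == "CORT":
                expected += small_config.cort_copy_noise_effect
            assert noise == pytest.approx(expected)


class TestVisitStream:
    def test_zero_days_gives_empty_stream(self, small_colony):
        cfg = ColonyConfig(seed=7, n_days=0)
        stream, labels = simulate_visit_stream(small_colony, cfg)
        assert len(stream) == 0 and len(labels) == 0

    def test_identical_seed_identical_stream(self, small_colony, small_config):
        s1, l1 = simulate_visit_stream(small_colony, small_config)
        s2, l2 = simulate_visit_stream(small_colony, small_config)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_series_equal(l1, l2)

    def test_times_within_day_and_days_one_based(self, small_stream, small_config):
        stream, _ = small_stream
        assert stream["time_s"].between(0, 86400).all()
        assert stream["day"].between(1, small_config.n_days).all()

    def test_within_family_co_membership_exceeds_between(self):
        # ground-truth labels: family dyads share events more often, every replicate
        for rep in range(10):
            cfg = ColonyConfig(
                seed=200 + rep, n_days=1, families_per_aviary=(4,), n_aviaries=1,
                affinity_within_family=2.5, affinity_baseline=0.1, affinity_sd=0.0,
            )
            colony = generate_colony(cfg)
            stream, labels = simulate_visit_stream(colony, cfg)
            fam = colony.birds.set_index("bird_id")["family_id"]
            events = stream.assign(event=labels).groupby("event")["bird_id"].apply(set)
            within = between = n_w = n_b = 0
            roster = colony.roster(1)
            for i, bi in enumerate(roster):
                for bj in roster[i + 1:]:
                    co = sum((bi in e) and (bj in e) for e in events)
                    if fam[bi] == fam[bj]:
                        within += co
                        n_w += 1
                    else:
                        between += co
                        n_b += 1
            assert within / n_w > between / n_b


class TestSynthesizeSongs:
    def test_noiseless_copy_is_identical(self):
        cfg = ColonyConfig(seed=9, copy_noise_sd=0.0, cort_copy_noise_effect=0.0,
                           families_per_aviary=(3, 3), n_days=1)
        colony = generate_colony(cfg)
        songs = synthesize_songs(colony, cfg)
        std = standardize_elements(songs)
        for son, tutor in colony.true_tutor.items():
            if son in songs:
                assert motif_pair_dissimilarity(std[son], std[tutor]) == 0.0

    def test_cort_increases_son_tutor_dissimilarity_on_average(self):
        # Monte Carlo over replicates: CORT sons' copies are noisier
        cort_d, ctrl_d = [], []
        for rep in range(15):
            cfg = ColonyConfig(seed=300 + rep, n_days=1,
                               copy_noise_sd=0.05, cort_copy_noise_effect=0.25)
            colony = generate_colony(cfg)
            songs = synthesize_songs(colony, cfg)
            std = standardize_elements(songs)
            meta = colony.birds.set_index("bird_id")
            for son, tutor in colony.true_tutor.items():
                d = motif_pair_dissimilarity(std[son], std[tutor])
                (cort_d if meta.loc[son, "treatment"] == "CORT" else ctrl_d).append(d)
        assert np.mean(cort_d) > np.mean(ctrl_d)

    def test_identical_seed_identical_motifs(self, small_colony, small_config):
        a = synthesize_songs(small_colony, small_config)
        b = synthesize_songs(small_colony, small_config)
        for bird in a:
            for ma, mb in zip(a[bird], b[bird]):
                for ea, eb in zip(ma, mb):
                    np.testing.assert_array_equal(ea.values, eb.values)

    def test_females_receive_no_motifs(self, small_colony, small_config):
        songs = synthesize_songs(small_colony, small_config)
        females = set(
            small_colony.birds.loc[small_colony.birds["sex"] == "F", "bird_id"]
        )
        assert not (set(songs) & females)

    def test_trace_lengths_within_range(self, small_colony, small_config):
        lo, hi = small_config.trace_length_range
        songs = synthesize_songs(small_colony, small_config)
        for renditions in songs.values():
            for motif in renditions:
                assert len(motif) == small_config.elements_per_motif
                for el in motif:
                    assert lo <= el.values.shape[0] <= hi


def test_config_validation_errors():
    with pytest.raises(ValueError):
        ColonyConfig(p_male=1.5)
    with pytest.raises(ValueError):
        ColonyConfig(copy_noise_sd=-0.1)
    with pytest.raises(ValueError):
        ColonyConfig(brood_size_range=(0, 2))
    with pytest.raises(ValueError):
        ColonyConfig(families_per_aviary=(3,))  # one entry for two aviaries
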