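"""Semiglobal gene-order alignment, rotation/orientation search, distances."""

import numpy as np
import pytest

from goatalign import (
    AlignmentParams,
    FamilySimilarityMatrix,
    GenomeProfile,
    best_score,
    distance_matrix,
    goat_distance,
    read_phylip,
    semiglobal_align,
    write_phylip,
)
from goatalign.align import ANTISENSE, SENSE, MissingLabelError

from conftest import random_profile_pair
from oracles import brute_best_score, brute_goat_distance


class TestSemiglobalAlign:
    def test_identical_sequences(self, profile, identity_matrix, half_gap_params):
        res = semiglobal_align(
            profile("ABC", "a"), profile("ABC", "b"),
            identity_matrix, half_gap_params,
        )
        assert res.score == pytest.approx(3.0)
        assert res.aligned_pairs == ((0, 0), (1, 1), (2, 2))
        assert res.rotation_offset == 0 and res.orientation == SENSE

    def test_internal_gap_penalized(self, profile, identity_matrix, half_gap_params):
        res = semiglobal_align(
            profile("ABC", "a"), profile("AC", "b"),
            identity_matrix, half_gap_params,
        )
        assert res.score == pytest.approx(1.5)  # two matches minus one gap

    def test_disjoint_alphabets_score_zero(self, profile, identity_matrix,
                                           half_gap_params):
        res = semiglobal_align(
            profile("AB", "a"), profile("XY", "b"),
            identity_matrix, half_gap_params,
        )
        assert res.score == pytest.approx(0.0)

    def test_free_end_gaps_unpenalized(self, profile, identity_matrix,
                                       half_gap_params):
        # B is a strict interior fragment of A: no penalty for the overhangs
        res = semiglobal_align(
            profile("XABCY", "a"), profile("ABC", "b"),
            identity_matrix, half_gap_params,
        )
        assert res.score == pytest.approx(3.0)

    def test_score_consistent_with_pairs_and_gaps(self, rng):
        labels = list("ABCDEFGH")
        scores = rng.uniform(0, 5, size=(8, 8))
        scores = (scores + scores.T) / 2
        np.fill_diagonal(scores, rng.uniform(5, 9, size=8))
        m = FamilySimilarityMatrix(labels, scores)
        params = AlignmentParams(gap_penalty=1.25)
        for _ in range(50):
            a, b = random_profile_pair(rng)
            res = semiglobal_align(a, b, m, params)
            rescored = sum(
                m.score(a.families[i], b.families[j])
                for i, j in res.aligned_pairs
            ) - 1.25 * res.n_internal_gaps
            assert res.score == pytest.approx(rescored)

    def test_missing_label_error_names_label(self, profile, half_gap_params):
        m = FamilySimilarityMatrix.identity(["A", "B"])
        with pytest.raises(MissingLabelError, match="Z"):
            semiglobal_align(
                profile("AB", "a"), profile("AZ", "b"),
                m, half_gap_params, auto_extend=False,
            )


class TestBestScore:
    def test_rotation_recovered(self, profile, identity_matrix, half_gap_params):
        res = best_score(
            profile("ABCD", "a"), profile("CDAB", "b"),
            identity_matrix, half_gap_params,
        )
        assert res.score == pytest.approx(4.0)
        assert res.rotation_offset == 2
        assert res.orientation == SENSE

    def test_antisense_recovered(self, profile, identity_matrix):
        params = AlignmentParams(gap_penalty=0.5, search_rotations=False)
        res = best_score(
            profile("ABC", "a", circular=False),
            profile("CBA", "b", circular=False),
            identity_matrix, params,
        )
        assert res.score == pytest.approx(3.0)
        assert res.orientation == ANTISENSE

    def test_linear_profile_never_rotated(self, profile, identity_matrix,
                                          half_gap_params):
        res = best_score(
            profile("ABCD", "a"), profile("CDAB", "b", circular=False),
            identity_matrix, half_gap_params,
        )
        assert res.rotation_offset == 0
        assert res.score == pytest.approx(2.0)  # only the CD block aligns

    def test_matches_chaining_oracle(self, rng, identity_matrix):
        params = AlignmentParams(gap_penalty=0.5)
        for _ in range(40):
            a, b = random_profile_pair(rng)
            got = best_score(a, b, identity_matrix, params).score
            want = brute_best_score(
                list(a.families), list(b.families),
                identity_matrix.score, 0.5,
            )
            assert got == pytest.approx(want), (a.families, b.families)

    def test_oracle_with_weighted_matrix(self, rng):
        labels = list("ABCDEF")
        scores = rng.uniform(0, 4, size=(6, 6))
        scores = (scores + scores.T) / 2
        np.fill_diagonal(scores, rng.uniform(4, 8, size=6))
        m = FamilySimilarityMatrix(labels, scores)
        params = AlignmentParams(gap_penalty=1.0)
        for _ in range(25):
            a, b = random_profile_pair(rng, max_len=7, alphabet="ABCDEF")
            got = best_score(a, b, m, params).score
            want = brute_best_score(
                list(a.families), list(b.families), m.score, 1.0,
            )
            assert got == pytest.approx(want)


class TestGoatDistance:
    def test_self_distance_zero(self, profile, identity_matrix, half_gap_params):
        a = profile("ABCD", "a")
        b = profile("ABCD", "b")
        assert goat_distance(a, b, identity_matrix, half_gap_params) == 0.0

    def test_disjoint_profiles_distance_one(self, profile, identity_matrix,
                                            half_gap_params):
        a = profile("AB", "a")
        b = profile("XY", "b")
        assert goat_distance(a, b, identity_matrix, half_gap_params) == 1.0

    def test_half_shared_distance(self, profile, identity_matrix, half_gap_params):
        a = profile("ABCD", "a")
        b = profile("ABXY", "b")
        d = goat_distance(a, b, identity_matrix, half_gap_params)
        assert d == pytest.approx(0.5)  # 1 - (2 + 2) / (4 + 4)

    def test_symmetry_and_range(self, rng, identity_matrix, half_gap_params):
        for _ in range(30):
            a, b = random_profile_pair(rng)
            d_ab = goat_distance(a, b, identity_matrix, half_gap_params)
            d_ba = goat_distance(b, a, identity_matrix, half_gap_params)
            assert d_ab == pytest.approx(d_ba)
            assert 0.0 <= d_ab <= 1.0

    def test_rotation_invariance(self, rng, identity_matrix, half_gap_params):
        for _ in range(15):
            a, b = random_profile_pair(rng)
            d = goat_distance(a, b, identity_matrix, half_gap_params)
            for off in (1, len(b) // 2, len(b) - 1):
                assert goat_distance(
                    a, b.rotated(off), identity_matrix, half_gap_params
                ) == pytest.approx(d)

    def test_reversal_invariance(self, rng, identity_matrix, half_gap_params):
        for _ in range(15):
            a, b = random_profile_pair(rng)
            d = goat_distance(a, b, identity_matrix, half_gap_params)
            assert goat_distance(
                a, b.reversed(), identity_matrix, half_gap_params
            ) == pytest.approx(d)
            assert goat_distance(
                a.reversed(), b, identity_matrix, half_gap_params
            ) == pytest.approx(d)


class TestDistanceMatrix:
    def test_identical_genomes_all_zero(self, profile, identity_matrix,
                                        half_gap_params):
        dm = distance_matrix(
            [profile("ABCD", "g1"), profile("ABCD", "g2")],
            identity_matrix, half_gap_params,
        )
        assert np.allclose(dm.data, 0.0)

    def test_matches_brute_force_elementwise(self, rng, identity_matrix,
                                             half_gap_params):
        profs = [random_profile_pair(rng)[0] for _ in range(3)]
        profs = [
            GenomeProfile(f"g{i}", p.families, None, True)
            for i, p in enumerate(profs)
        ]
        dm = distance_matrix(profs, identity_matrix, half_gap_params)
        assert np.allclose(dm.data, dm.data.T)
        for i in range(3):
            for j in range(i + 1, 3):
                want = brute_goat_distance(
                    list(profs[i].families), list(profs[j].families),
                    identity_matrix.score, 0.5,
                )
                assert dm.data[i, j] == pytest.approx(want)

    def test_mean_distance_monotone_in_event_count(self):
        """More rearrangement + indel events => larger expected distance."""
        from goatalign import EvolutionConfig, apply_events, random_profile

        cfg = EvolutionConfig(seed=11, genome_length=30, n_families=200)
        rng = cfg.rng()
        m = FamilySimilarityMatrix.identity(
            [f"F{i:04d}" for i in range(200)] + [f"GAIN:{i:05d}" for i in range(1, 4000)]
        )
        params = AlignmentParams(gap_penalty=0.5)
        means = []
        for n_events in (0, 2, 5, 10):
            dists = []
            for _ in range(25):
                base = random_profile(cfg, rng=rng)
                mutated, _ = apply_events(base, cfg, n_events, rng=rng)
                dists.append(goat_distance(base, mutated, m, params))
            means.append(float(np.mean(dists)))
        assert means == sorted(means)


def test_phylip_round_trip(tmp_path, profile, identity_matrix, half_gap_params):
    dm = distance_matrix(
        [profile("ABCD", "g1"), profile("ABXY", "g2"), profile("CDAB", "g3")],
        identity_matrix, half_gap_params,
    )
    path = tmp_path / "dist.phy"
    write_phylip(dm, path)
    back = read_phylip(path)
    assert list(back.ids) == list(dm.ids)
    assert np.allclose(back.data, dm.data, atol=1e-6)
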