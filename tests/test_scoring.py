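"""Propensities, diversity metrics, rolling average, feature vector."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from foldswitch.fragdb import build_index
from foldswitch.picking import WindowHits
from foldswitch.scoring import (
    SUBSTITUTION_MATRIX,
    FeatureVector,
    PropensityTriple,
    default_scores,
    diversity_index,
    entropy,
    feature_vector,
    propensities,
    rolling_average,
    score_protein,
    score_windows,
    ss3_class,
    substitution_score,
    uncertainty,
    window_width,
)

from conftest import make_record
from test_picking import hit


def window_with(ss_states):
    hits = [hit(f"p{i}", ss=s, cluster=f"c{i}")
            for i, s in enumerate(ss_states)]
    return WindowHits(query_position=3, fragment="ACDEFGH",
                      hits_raw=hits, hits_filtered=hits, hits_unique=hits)


class TestSS3Class:
    @pytest.mark.parametrize("letter,cls", [
        ("H", "helix"), ("G", "helix"), ("I", "helix"),
        ("E", "strand"), ("B", "strand"),
        ("T", "loop"), ("S", "loop"), ("-", "loop"),
    ])
    def test_every_dssp_letter_maps_to_one_class(self, letter, cls):
        assert ss3_class(letter) == cls

    def test_unknown_letter_raises(self):
        with pytest.raises(ValueError):
            ss3_class("Q")


class TestPropensities:
    def test_mixed_window_counts(self):
        p = propensities(window_with("HHET"))
        assert p.as_tuple() == (0.5, 0.25, 0.25)

    def test_pure_strand(self):
        assert propensities(window_with("EEE")).as_tuple() == (0.0, 1.0, 0.0)

    def test_permutation_invariance(self):
        a = propensities(window_with("HHEETTS-"))
        b = propensities(window_with("-STTEEHH"))
        assert a == b

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            propensities(window_with(""))

    @given(st.lists(st.sampled_from("HGIEBTS-"), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_triple_sums_to_one(self, states):
        p = propensities(window_with(states))
        assert math.isclose(sum(p.as_tuple()), 1.0)


class TestDiversityAndEntropy:
    @pytest.mark.parametrize("triple,di", [
        ((1, 0, 0), 1.0),
        ((1 / 3, 1 / 3, 1 / 3), 3.0),
        ((0.5, 0.5, 0), 2.0),
    ])
    def test_diversity_closed_forms(self, triple, di):
        assert diversity_index(PropensityTriple(*triple)) == pytest.approx(di)

    @pytest.mark.parametrize("triple,ent", [
        ((1, 0, 0), 0.0),
        ((1 / 3, 1 / 3, 1 / 3), math.log(3)),
        ((0.5, 0.5, 0), math.log(2)),
    ])
    def test_entropy_closed_forms(self, triple, ent):
        assert entropy(PropensityTriple(*triple)) == pytest.approx(ent)

    def test_rank_correlation_over_random_triples(self):
        """Both metrics order random propensity triples almost identically."""
        rng = np.random.default_rng(0)
        draws = rng.dirichlet(np.ones(3), size=1000)
        triples = [PropensityTriple(*d) for d in draws]
        rho = spearmanr([diversity_index(t) for t in triples],
                        [entropy(t) for t in triples]).statistic
        assert rho >= 0.9

    @given(st.integers(1, 1000))
    @settings(max_examples=100, deadline=None)
    def test_range_conservation(self, seed):
        h, e, l = np.random.default_rng(seed).dirichlet(np.ones(3))
        t = PropensityTriple(h, e, l)
        assert 1.0 <= diversity_index(t) <= 3.0 + 1e-12
        assert 0.0 <= entropy(t) <= math.log(3) + 1e-12


class TestSubstitutionScore:
    def test_matrix_entries(self):
        assert SUBSTITUTION_MATRIX["helix", "strand"] == 0.7
        assert SUBSTITUTION_MATRIX["helix", "loop"] == 0.3
        assert SUBSTITUTION_MATRIX["strand", "loop"] == 1.0
        for cls in ("helix", "strand", "loop"):
            assert SUBSTITUTION_MATRIX[cls, cls] == 0.0
        for a, b in SUBSTITUTION_MATRIX:
            assert SUBSTITUTION_MATRIX[a, b] == SUBSTITUTION_MATRIX[b, a]

    def test_helix_strand_pair(self):
        assert substitution_score(window_with("HE")) == pytest.approx(0.7)

    def test_three_class_mean_over_pairs(self):
        assert substitution_score(window_with("HET")) == pytest.approx(
            (0.7 + 0.3 + 1.0) / 3)

    @pytest.mark.parametrize("states", ["H", "HHHH", "GGII", "EEBB", "TS--"])
    def test_single_class_scores_zero(self, states):
        assert substitution_score(window_with(states)) == 0.0

    def test_brute_force_pair_enumeration(self):
        """Mean over unordered pairs, checked against itertools enumeration."""
        import itertools
        states = "HHEETGB-S"
        classes = [ss3_class(s) for s in states]
        pairs = list(itertools.combinations(classes, 2))
        expected = sum(SUBSTITUTION_MATRIX[p] for p in pairs) / len(pairs)
        assert substitution_score(window_with(states)) == pytest.approx(expected)


class TestUncertaintyAndDefaults:
    def test_values(self):
        assert uncertainty(0) == 1.0
        assert uncertainty(2) == pytest.approx(math.exp(-1))

    def test_strictly_decreasing(self):
        vals = [uncertainty(n) for n in range(50)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_negative_count_raises(self):
        with pytest.raises(ValueError):
            uncertainty(-1)

    def test_default_scores_exact(self):
        assert default_scores() == (1.0, 0.0, 0.0, 1.0)

    def test_empty_database_query_all_defaults(self):
        index = build_index([])
        track = score_protein(index, "ACDEFGHIKLMNP")
        assert np.all(track.diversity == 1.0)
        assert np.all(track.entropy == 0.0)
        assert np.all(track.substitution == 0.0)
        assert np.all(track.uncertainty == 1.0)
        assert np.all(np.isnan(track.h))


class TestRollingAverage:
    def test_hand_computed(self):
        assert rolling_average([0, 0, 1, 1], 2) == pytest.approx([0, 0.5, 1])

    def test_constant_track(self):
        assert rolling_average([3.5] * 10, 4) == pytest.approx([3.5] * 7)

    def test_short_track_falls_back_to_single_window(self):
        assert rolling_average([1.0, 2.0, 3.0], 8) == pytest.approx([2.0])

    def test_equals_naive_window_means(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(1, 60))
            ww = int(rng.integers(1, n + 1))
            track = rng.normal(size=n)
            naive = [track[i:i + ww].mean() for i in range(n - ww + 1)]
            assert rolling_average(track, ww) == pytest.approx(naive)


class TestWindowWidth:
    @pytest.mark.parametrize("length,ww", [
        (100, 8), (251, 8), (252, 18), (300, 18)])
    def test_step_function(self, length, ww):
        assert window_width(length) == ww


class TestFeatureVector:
    def test_all_default_track(self):
        index = build_index([])
        track = score_protein(index, "ACDEFGHIKLMNPQRSTVWY")
        fv = feature_vector(track)
        assert fv.as_array() == pytest.approx([1.0, 0.0, 0.0, 1.0])

    def test_plateau_maximum_recovered(self, planted_scenario):
        """A planted plateau longer than WW yields its value as the rolled max."""
        spec, query, truth, records, _ = planted_scenario
        index = build_index(records)
        track = score_protein(index, query)
        fv = feature_vector(track, ww=8)
        # plateau is 12 windows of (0.5, 0.5, 0): DI 2, entropy ln 2
        assert fv.max_rolled_diversity == pytest.approx(2.0)
        assert fv.max_rolled_entropy == pytest.approx(math.log(2))
        assert fv.mean_uncertainty == pytest.approx(
            np.mean(track.uncertainty))

    def test_invariant_under_track_reversal(self):
        rng = np.random.default_rng(9)
        n = 40
        track_vals = {name: rng.uniform(size=n)
                      for name in ("diversity", "entropy", "substitution",
                                   "uncertainty")}

        def fv_of(direction):
            from foldswitch.scoring import ResidueScoreTrack
            track = ResidueScoreTrack(
                protein_id="t", sequence="A" * (n + 6),
                positions=np.arange(3, 3 + n),
                h=np.full(n, np.nan), e=np.full(n, np.nan),
                l=np.full(n, np.nan),
                diversity=track_vals["diversity"][::direction].copy(),
                entropy=track_vals["entropy"][::direction].copy(),
                substitution=track_vals["substitution"][::direction].copy(),
                uncertainty=track_vals["uncertainty"][::direction].copy(),
                n_unique_clusters=np.ones(n, dtype=int),
            )
            return feature_vector(track, ww=8)

        # equal up to summation order inside the moving mean
        assert fv_of(1).as_array() == pytest.approx(fv_of(-1).as_array())


class TestEndToEndDeterminism:
    def test_identical_inputs_identical_tracks(self, planted_scenario):
        spec, query, truth, records, _ = planted_scenario
        index = build_index(records)
        t1 = score_protein(index, query)
        t2 = score_protein(index, query)
        for name in ("diversity", "entropy", "substitution", "uncertainty"):
            assert np.array_equal(getattr(t1, name), getattr(t2, name))
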