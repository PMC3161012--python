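"""Redundancy collapsing: types a/b/c and the similarity arbitration."""

import numpy as np
import pytest

from paraconv.grouping import (
    TripleSimilarity,
    boundaries_similar,
    classify_type_c,
    collapse_type_a,
    collapse_type_b,
    collapse_type_c,
    deduplicate,
    events_to_tables,
)
from paraconv.io import GenomicInterval, OrthologyMap

from conftest import make_alignment, make_observation


class TestBoundariesSimilar:
    def test_identical_intervals(self):
        a = make_observation(conv1=(100, 200))
        b = make_observation(conv1=(100, 200))
        assert boundaries_similar(a, b)

    def test_disjoint_intervals(self):
        a = make_observation(conv1=(100, 200))
        b = make_observation(conv1=(400, 500))
        assert not boundaries_similar(a, b)

    def test_sixty_percent_reciprocal_overlap(self):
        a = make_observation(conv1=(0, 100))
        b = make_observation(conv1=(40, 140))
        assert boundaries_similar(a, b, tolerance=0.5)
        assert not boundaries_similar(a, b, tolerance=0.7)


class TestTypeA:
    def test_three_outgroups_one_event_min_p_kept(self):
        obs = [
            make_observation(outgroup="B", p_value=1e-3),
            make_observation(outgroup="C", p_value=1e-5),
            make_observation(outgroup="D", p_value=1e-4),
        ]
        events = collapse_type_a(obs)
        assert len(events) == 1
        assert events[0].representative.p_value == 1e-5
        assert len(events[0].observations) == 3

    def test_repeated_conversions_stay_separate(self):
        # same pair, non-overlapping intervals: repeated conversion events
        obs = [
            make_observation(outgroup="B", conv1=(100, 200)),
            make_observation(outgroup="C", conv1=(600, 900)),
        ]
        assert len(collapse_type_a(obs)) == 2

    def test_single_observation_single_event(self):
        events = collapse_type_a([make_observation()])
        assert len(events) == 1
        assert len(events[0].observations) == 1

    def test_different_pairs_never_merge(self):
        obs = [
            make_observation(conv1=(100, 200), par1=(0, 1000)),
            make_observation(conv1=(100, 200), par1=(2000, 3000),
                             par2=(3000, 4000)),
        ]
        assert len(collapse_type_a(obs)) == 2


def _cross_species_orthology(length=1000):
    """A<->B orthology for two paralog slots at [0,1000) and [1000,2000)."""
    omap = OrthologyMap()
    seq = "A" * length
    for start in (0, 1000):
        omap.add(make_alignment(seq, seq, "A", "B", start1=start, start2=start))
    return omap


class TestTypeB:
    def test_orthologous_pairs_same_outgroup_merge(self):
        obs_a = make_observation(primary="A", outgroup="G", conv1=(100, 200),
                                 p_value=1e-4)
        obs_b = make_observation(primary="B", outgroup="G", conv1=(100, 200),
                                 p_value=1e-6)
        events = collapse_type_a([obs_a]) + collapse_type_a([obs_b])
        merged = collapse_type_b(events, _cross_species_orthology())
        assert len(merged) == 1
        assert merged[0].representative.p_value == 1e-6

    def test_different_outgroups_not_merged(self):
        obs_a = make_observation(primary="A", outgroup="G", conv1=(100, 200))
        obs_b = make_observation(primary="B", outgroup="H", conv1=(100, 200))
        events = collapse_type_a([obs_a]) + collapse_type_a([obs_b])
        merged = collapse_type_b(events, _cross_species_orthology())
        assert len(merged) == 2

    def test_no_orthology_no_merge(self):
        obs_a = make_observation(primary="A", outgroup="G")
        obs_b = make_observation(primary="B", outgroup="G")
        events = collapse_type_a([obs_a]) + collapse_type_a([obs_b])
        assert len(collapse_type_b(events, OrthologyMap())) == 2

    def test_dissimilar_mapped_boundaries_not_merged(self):
        obs_a = make_observation(primary="A", outgroup="G", conv1=(100, 200))
        obs_b = make_observation(primary="B", outgroup="G", conv1=(700, 800))
        events = collapse_type_a([obs_a]) + collapse_type_a([obs_b])
        assert len(collapse_type_b(events, _cross_species_orthology())) == 2


class TestTypeC:
    @pytest.mark.parametrize(
        "sims,expected",
        [
            ((0.99, 0.95, 0.95), "before-duplication"),
            ((0.90, 0.99, 0.92), "pairwise-1"),
            ((0.90, 0.92, 0.99), "pairwise-2"),
        ],
    )
    def test_similarity_rule(self, sims, expected):
        a, b = make_observation(), make_observation()
        assert classify_type_c(a, b, TripleSimilarity(*sims)) == expected

    def test_tie_resolves_to_before_duplication(self):
        a, b = make_observation(), make_observation()
        case = classify_type_c(a, b, TripleSimilarity(0.99, 0.99, 0.9))
        assert case == "before-duplication"


def _type_c_fixture(case: str):
    """Two observations A1->A3, A2->A3 plus alignments realizing a case.

    A1 at [0,1000), A2 at [1000,2000), A3 at [2000,3000); conversion region
    [200,400) within each copy.  Sequences differ only inside the region so
    the intended similarity ordering holds there.
    """
    rng = np.random.default_rng(5)
    base = "".join(rng.choice(list("ACGT"), size=1000))
    region = slice(200, 400)

    def mutate(seq: str, rate: float, rng) -> str:
        out = list(seq)
        for i in range(region.start, region.stop):
            if rng.random() < rate:
                out[i] = "ACGT"[(("ACGT".index(out[i])) + 1) % 4]
        return "".join(out)

    rng2 = np.random.default_rng(6)
    if case == "before-duplication":
        # A1 == A2 in region; A3 diverged: S1 highest
        a1 = a2 = base
        a3 = mutate(base, 0.10, rng2)
    elif case == "pairwise-1":
        # A1 == A3 (real conversion); A2 diverged: S2 highest
        a1 = a3 = base
        a2 = mutate(base, 0.10, rng2)
    else:
        # A2 == A3: S3 highest
        a2 = a3 = base
        a1 = mutate(base, 0.10, rng2)

    alignments = [
        make_alignment(a1, a2, start1=0, start2=1000),
        make_alignment(a1, a3, start1=0, start2=2000),
        make_alignment(a2, a3, start1=1000, start2=2000),
    ]
    obs1 = make_observation(
        par1=(0, 1000), par2=(2000, 3000), conv1=(200, 400), conv2=(2200, 2400),
        p_value=1e-6,
    )
    obs2 = make_observation(
        par1=(1000, 2000), par2=(2000, 3000), conv1=(1200, 1400),
        conv2=(2200, 2400), p_value=1e-4,
    )
    return obs1, obs2, alignments


class TestTypeCCollapse:
    def test_before_duplication_keeps_min_p(self):
        obs1, obs2, alignments = _type_c_fixture("before-duplication")
        events = collapse_type_a([obs1]) + collapse_type_a([obs2])
        merged = collapse_type_c(events, alignments)
        assert len(merged) == 1
        assert merged[0].inferred_case == "before-duplication"
        assert merged[0].representative is obs1  # lower P

    def test_pairwise_1_keeps_real_observation(self):
        obs1, obs2, alignments = _type_c_fixture("pairwise-1")
        events = collapse_type_a([obs1]) + collapse_type_a([obs2])
        merged = collapse_type_c(events, alignments)
        assert len(merged) == 1
        assert merged[0].inferred_case == "pairwise-1"
        assert merged[0].representative is obs1  # the A1<->A3 observation

    def test_pairwise_2_keeps_other_observation(self):
        obs1, obs2, alignments = _type_c_fixture("pairwise-2")
        events = collapse_type_a([obs1]) + collapse_type_a([obs2])
        merged = collapse_type_c(events, alignments)
        assert len(merged) == 1
        assert merged[0].inferred_case == "pairwise-2"
        assert merged[0].representative is obs2

    def test_dissimilar_boundaries_stay_separate(self):
        obs1, obs2, alignments = _type_c_fixture("before-duplication")
        obs2.conv1 = (1700, 1900)
        obs2.conv2 = (2700, 2900)
        events = collapse_type_a([obs1]) + collapse_type_a([obs2])
        merged = collapse_type_c(events, alignments)
        assert len(merged) == 2


class TestDeduplicate:
    def test_empty_input(self):
        assert deduplicate([]) == []

    def test_no_redundancy_is_bijection(self):
        obs = [
            make_observation(primary="A", outgroup="B", conv1=(0, 100)),
            make_observation(primary="A", outgroup="B", conv1=(500, 600)),
        ]
        events = deduplicate(obs)
        assert len(events) == 2
        assert {e.event_id for e in events} == {1, 2}
        assert all(o.event_id is not None for o in obs)

    def test_idempotent(self):
        obs = [
            make_observation(outgroup="B", p_value=1e-3),
            make_observation(outgroup="C", p_value=1e-5),
            make_observation(outgroup="D", conv1=(600, 900), p_value=1e-4),
        ]
        events1 = deduplicate(obs)
        reps = [e.representative for e in events1]
        events2 = deduplicate(reps)
        assert len(events2) == len(events1)
        assert [e.representative.p_value for e in events2] == [
            e.representative.p_value for e in events1
        ]

    def test_event_ids_ordered_by_primary_and_start(self):
        obs = [
            make_observation(primary="B", conv1=(0, 100)),
            make_observation(primary="A", conv1=(500, 600)),
            make_observation(primary="A", conv1=(0, 100)),
        ]
        events = deduplicate(obs)
        keys = [(e.representative.primary_species,
                 e.representative.converted_interval[0]) for e in events]
        assert keys == sorted(keys)
        assert [e.event_id for e in events] == [1, 2, 3]

    def test_tables_shapes(self):
        obs = [
            make_observation(outgroup="B", p_value=1e-3),
            make_observation(outgroup="C", p_value=1e-5),
        ]
        events = deduplicate(obs)
        full, nr = events_to_tables(events)
        assert len(full) == 2
        assert len(nr) == 1
        assert set(full["event_id"]) == {1}
        assert nr["p_value"].iloc[0] == 1e-5
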