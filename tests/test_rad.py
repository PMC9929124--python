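import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from levinsfert import (
    build_rad,
    compare_communities,
    evenness,
    rad_slope,
    richness,
    solve_equilibrium,
)

freq_vectors = hnp.arrays(
    dtype=float,
    shape=st.integers(1, 30),
    elements=st.floats(0, 0.5, allow_nan=False),
)


class TestBuildRad:
    def test_filter_and_sort(self):
        rad = build_rad(np.array([0.5, 1e-6, 0.1]), threshold=1e-5,
                        convention="raw")
        assert rad.entries == [(1, 0.5), (3, 0.1)]
        assert rad.richness == 2

    def test_all_below_threshold(self):
        rad = build_rad(np.array([1e-7, 1e-8]), threshold=1e-5,
                        convention="raw")
        assert rad.richness == 0

    def test_equilibrium_f1_has_31_species(self, f1, params):
        st_ = solve_equilibrium(f1, params)
        rad = build_rad(st_.frequencies)  # relative convention, 1e-5
        assert rad.richness == 31

    def test_tie_broken_by_competitive_index(self):
        rad = build_rad(np.array([0.2, 0.3, 0.2]), convention="raw")
        assert [s for s, _ in rad.entries] == [2, 1, 3]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            build_rad(np.array([0.1, -0.2]))

    def test_idempotent_under_rethreshold(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 0.01, 40)
        rad = build_rad(p, threshold=1e-3, convention="raw")
        again = build_rad(rad.abundances, threshold=1e-3, convention="raw")
        np.testing.assert_array_equal(again.abundances, rad.abundances)

    def test_relative_vs_raw_convention(self):
        # occupied fraction 0.5 doubles relative abundances
        p = np.array([0.25, 0.25, 6e-6])
        assert richness(p, convention="raw") == 2
        assert richness(p, convention="relative") == 3


class TestRichness:
    def test_zero_vector(self):
        assert richness(np.zeros(10)) == 0

    def test_equilibrium_f2_has_28_species(self, f2, params):
        st_ = solve_equilibrium(f2, params)
        assert richness(st_.frequencies) == 28

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(p=freq_vectors)
    def test_equals_rad_length(self, p):
        assert richness(p, convention="raw") == build_rad(
            p, convention="raw").richness


class TestCompare:
    def test_identity(self):
        p = np.array([0.3, 0.0, 0.2])
        comp = compare_communities(p, p)
        assert comp.new == comp.lost == frozenset()
        assert comp.retained == {1, 3}

    def test_set_bookkeeping(self):
        before = np.array([0.3, 0.2, 0.0])
        after = np.array([0.0, 0.2, 0.3])
        comp = compare_communities(before, after)
        assert comp.new == {3}
        assert comp.lost == {1}
        assert comp.retained == {2}

    def test_f0_to_f1_total(self, f0, f1, params):
        before = solve_equilibrium(f0, params).frequencies
        after = solve_equilibrium(f1, params).frequencies
        comp = compare_communities(before, after)
        assert len(comp.new) + len(comp.retained) == 31

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_partition_identities(self, data):
        """new/lost/retained partition the union of detectable sets and
        satisfy the counting identities."""
        n = data.draw(st.integers(1, 20))
        elems = st.floats(0, 0.05, allow_nan=False)
        before = np.array(data.draw(st.lists(elems, min_size=n, max_size=n)))
        after = np.array(data.draw(st.lists(elems, min_size=n, max_size=n)))
        comp = compare_communities(before, after, threshold=1e-3,
                                   convention="raw")
        union = comp.new | comp.lost | comp.retained
        assert union == set(comp.before.species) | set(comp.after.species)
        assert comp.new & comp.lost == set()
        assert comp.after.richness == len(comp.retained) + len(comp.new)
        assert comp.before.richness == len(comp.retained) + len(comp.lost)

    def test_top_k_tracking(self):
        before = np.array([0.4, 0.3, 0.01])
        after = np.array([0.0, 0.3, 0.4])
        comp = compare_communities(before, after, k=2)
        assert comp.top_k_tracking == {1: None, 2: 2}


class TestSummaries:
    def test_equal_abundances(self):
        rad = build_rad(np.array([0.2, 0.2]), convention="raw")
        assert rad_slope(rad) == pytest.approx(0.0, abs=1e-12)
        assert evenness(rad) == pytest.approx(1.0, abs=1e-12)

    def test_geometric_sequence_slope(self):
        rad = build_rad(np.array([0.1, 0.01, 0.001]), convention="raw")
        assert rad_slope(rad) == pytest.approx(-1.0, abs=1e-12)

    def test_undefined_below_two_entries(self):
        rad = build_rad(np.array([0.5]), convention="raw")
        with pytest.raises(ValueError):
            rad_slope(rad)
        with pytest.raises(ValueError):
            evenness(rad)

    def test_fertilization_steepens_slope(self, f0, f1, params):
        rad0 = build_rad(solve_equilibrium(f0, params).frequencies)
        rad1 = build_rad(solve_equilibrium(f1, params).frequencies)
        assert rad_slope(rad1) < rad_slope(rad0)


@pytest.fixture(scope="module")
def states(f0, f1, f2):
    from levinsfert import CommunityParams
    cp = CommunityParams(q=0.3, m=0.2)
    return {name: solve_equilibrium(prof, cp)
            for name, prof in (("f0", f0), ("f1", f1), ("f2", f2))}


class TestFertilizationTrendSuite:
    """The three headline community responses at equilibrium."""

    def test_richness_declines(self, states):
        r0 = richness(states["f0"].frequencies)
        assert richness(states["f1"].frequencies) < r0
        assert richness(states["f2"].frequencies) < r0

    def test_top8_reordering(self, states):
        comp = compare_communities(states["f0"].frequencies,
                                   states["f1"].frequencies, k=8)
        before_top8 = [int(s) for s in comp.before.species[:8]]
        after_top8 = [int(s) for s in comp.after.species[:8]]
        assert before_top8 != after_top8

    def test_occupied_fraction_rises_f0_to_f1(self, states):
        assert (states["f1"].occupied_fraction
                > states["f0"].occupied_fraction)
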