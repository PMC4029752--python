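import pytest
from hypothesis import given, settings, strategies as st

from natsirna.annotation import GenomicInterval
from natsirna.pairs import (
    classify_orientation,
    exclude_mirna_overlaps,
    find_pairs,
    pair_id,
    pair_set_union,
)

from conftest import make_model, make_set
from oracles import brute_force_pairs


def _iv(start, end, strand="+", chrom="Chr1"):
    return GenomicInterval(chrom, start, end, strand)


class TestFindPairs:
    def test_basic_overlap_detected(self):
        ann = make_set(
            make_model("gA", "Chr1", 100, 500, "+"),
            make_model("gB", "Chr1", 400, 800, "-"),
        )
        found = find_pairs(ann)
        assert len(found) == 1
        p = found[0]
        assert (p.gene_a, p.gene_b) == ("gA", "gB")
        assert (p.overlap.start, p.overlap.end) == (400, 500)

    def test_overlap_of_exactly_25_nt_is_excluded(self):
        # "more than 25 nt" is strict: 25 fails, 26 passes
        ann = make_set(
            make_model("gA", "Chr1", 100, 500, "+"),
            make_model("gB", "Chr1", 475, 800, "-"),
        )
        assert find_pairs(ann) == []
        ann26 = make_set(
            make_model("gA", "Chr1", 100, 500, "+"),
            make_model("gB", "Chr1", 474, 800, "-"),
        )
        assert len(find_pairs(ann26)) == 1

    def test_overlap_cap_excludes_long_duplexes(self):
        ann = make_set(
            make_model("gA", "Chr1", 0, 3000, "+"),
            make_model("gB", "Chr1", 500, 2800, "-"),
        )
        assert find_pairs(ann) == []  # overlap 2300 >= 2000
        assert len(find_pairs(ann, max_overlap=5000)) == 1

    def test_same_strand_models_never_pair(self):
        ann = make_set(
            make_model("gA", "Chr1", 100, 500, "+"),
            make_model("gB", "Chr1", 400, 800, "+"),
        )
        assert find_pairs(ann) == []

    def test_premirna_models_do_not_pair(self):
        ann = make_set(
            make_model("gA", "Chr1", 100, 500, "+"),
            make_model("m1", "Chr1", 400, 800, "-", biotype="pre_miRNA"),
        )
        assert find_pairs(ann) == []


class TestClassifyOrientation:
    def test_three_prime_overlap_is_convergent(self):
        assert classify_orientation(_iv(100, 500, "+"), _iv(400, 800, "-")) == "convergent"

    def test_five_prime_overlap_is_divergent(self):
        assert classify_orientation(_iv(400, 800, "+"), _iv(100, 500, "-")) == "divergent"

    def test_containment_is_enclosed(self):
        assert classify_orientation(_iv(100, 900, "+"), _iv(300, 500, "-")) == "enclosed"
        assert classify_orientation(_iv(300, 500, "+"), _iv(100, 900, "-")) == "enclosed"

    def test_boundary_tie_resolves_to_enclosed(self):
        assert classify_orientation(_iv(100, 500, "+"), _iv(100, 500, "-")) == "enclosed"
        assert classify_orientation(_iv(100, 500, "+"), _iv(100, 400, "-")) == "enclosed"

    def test_disjoint_spans_rejected(self):
        with pytest.raises(ValueError):
            classify_orientation(_iv(100, 200, "+"), _iv(300, 400, "-"))

    @given(
        a1=st.integers(0, 500), la=st.integers(1, 500),
        b1=st.integers(0, 500), lb=st.integers(1, 500),
    )
    @settings(derandomize=True, max_examples=300)
    def test_exhaustive_and_exclusive_over_overlapping_geometries(self, a1, la, b1, lb):
        plus, minus = _iv(a1, a1 + la, "+"), _iv(b1, b1 + lb, "-")
        if plus.overlap_length(minus) == 0:
            return
        assert classify_orientation(plus, minus) in (
            "convergent", "divergent", "enclosed",
        )

    @given(
        a1=st.integers(0, 500), la=st.integers(1, 500),
        b1=st.integers(0, 500), lb=st.integers(1, 500),
    )
    @settings(derandomize=True, max_examples=300)
    def test_strand_relabeling_swaps_convergent_and_divergent(self, a1, la, b1, lb):
        """Swapping which member carries the plus strand (same coordinates)
        turns a 3' overlap into a 5' overlap and vice versa; containment is
        unaffected."""
        plus, minus = _iv(a1, a1 + la, "+"), _iv(b1, b1 + lb, "-")
        if plus.overlap_length(minus) == 0:
            return
        orient = classify_orientation(plus, minus)
        flipped = classify_orientation(
            _iv(b1, b1 + lb, "+"), _iv(a1, a1 + la, "-")
        )
        swap = {"convergent": "divergent", "divergent": "convergent",
                "enclosed": "enclosed"}
        assert flipped == swap[orient]

    @given(
        a1=st.integers(0, 500), la=st.integers(1, 500),
        b1=st.integers(0, 500), lb=st.integers(1, 500),
    )
    @settings(derandomize=True, max_examples=300)
    def test_mirror_reflection_preserves_orientation(self, a1, la, b1, lb):
        """A mirror image of the locus (coordinates reflected, every
        transcript's strand flipping with it) leaves which ends meet
        unchanged, so the orientation class is invariant."""
        plus, minus = _iv(a1, a1 + la, "+"), _iv(b1, b1 + lb, "-")
        if plus.overlap_length(minus) == 0:
            return
        orient = classify_orientation(plus, minus)
        C = 2000
        r_plus = _iv(C - minus.end, C - minus.start, "+")
        r_minus = _iv(C - plus.end, C - plus.start, "-")
        assert classify_orientation(r_plus, r_minus) == orient


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.data())
def test_find_pairs_matches_brute_force_oracle(data):
    n = data.draw(st.integers(2, 60))
    rng_models = []
    for i in range(n):
        chrom = data.draw(st.sampled_from(["Chr1", "Chr2"]))
        start = data.draw(st.integers(0, 4000))
        length = data.draw(st.integers(10, 2500))
        strand = data.draw(st.sampled_from("+-"))
        rng_models.append((f"g{i:03d}", chrom, start, start + length, strand))
    lo = data.draw(st.integers(1, 100))
    hi = data.draw(st.integers(100, 3000))
    ann = make_set(*[
        make_model(g, c, s, e, strand) for g, c, s, e, strand in rng_models
    ])
    got = {
        (tuple(sorted((p.gene_a, p.gene_b))), p.orientation)
        for p in find_pairs(ann, lo, hi)
    }
    assert got == brute_force_pairs(rng_models, lo, hi)


class TestExcludeMirnaOverlaps:
    def _world(self):
        ann = make_set(
            make_model("gA", "Chr1", 100, 500, "+"),
            make_model("gB", "Chr1", 400, 800, "-"),
            make_model("gC", "Chr1", 5000, 5400, "+"),
            make_model("gD", "Chr1", 5300, 5700, "-"),
        )
        return ann, find_pairs(ann)

    def test_one_nt_overlap_with_precursor_excludes_pair(self):
        ann, found = self._world()
        pre = make_set(make_model("mir", "Chr1", 499, 600, "-", biotype="pre_miRNA"))
        kept, excluded = exclude_mirna_overlaps(found, pre, ann)
        assert [p.id for p in excluded] == [pair_id("gA", "gB")]
        assert all(p.mirna_excluded for p in excluded)
        assert len(kept) == 1

    def test_no_precursors_is_identity(self):
        ann, found = self._world()
        kept, excluded = exclude_mirna_overlaps(found, make_set(), ann)
        assert kept == found and excluded == []


class TestPairSetUnion:
    def _pair(self, a, b, orientation="convergent", start=0):
        from natsirna.pairs import CisNatPair

        return CisNatPair(a, b, _iv(start, start + 100), orientation)

    def test_union_with_membership_flags(self):
        P, Q, R = self._pair("p1", "p2"), self._pair("q1", "q2"), self._pair("r1", "r2")
        union = pair_set_union({"s1": [P, Q], "s2": [Q, R]})
        by_id = {p.id: p.sets for p in union}
        assert by_id[Q.id] == frozenset({"s1", "s2"})
        assert by_id[P.id] == frozenset({"s1"})
        assert len(union) == 3

    def test_union_with_empty_second_set(self):
        P = self._pair("p1", "p2")
        union = pair_set_union({"s1": [P], "s2": []})
        assert [p.id for p in union] == [P.id]

    def test_conflicting_orientation_raises(self):
        P1 = self._pair("p1", "p2", "convergent")
        P2 = self._pair("p1", "p2", "divergent")
        with pytest.raises(ValueError, match="conflicting"):
            pair_set_union({"s1": [P1], "s2": [P2]})

    def test_inclusion_exclusion_for_two_sets(self):
        shared = [self._pair(f"s{i}a", f"s{i}b") for i in range(5)]
        only1 = [self._pair(f"x{i}a", f"x{i}b") for i in range(3)]
        only2 = [self._pair(f"y{i}a", f"y{i}b") for i in range(4)]
        union = pair_set_union({"A": shared + only1, "B": shared + only2})
        assert len(union) == 8 + 4 - 0
        assert len(union) == len(shared) + len(only1) + len(only2)
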