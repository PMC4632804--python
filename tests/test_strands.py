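"""Unit and property tests for the tube algebra primitives."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnassign.strands import (
    SymbolAtom,
    SymbolicStrand,
    Tube,
    TubeUsageError,
    anneal_ligate_pool,
    append_tail,
    copy,
    detect,
    discard,
    merge,
    parse_strand_label,
    read,
    selection,
    separation,
    sort_split,
)

T = 5


def edge(i, j, t=T):
    return SymbolicStrand(
        [SymbolAtom.s(t), SymbolAtom.individual(i, t), SymbolAtom.e(t), SymbolAtom.job(j, t)]
    )


def strand(label, **kw):
    return parse_strand_label(label, t=T, **kw)


class TestPrimitives:
    def test_merge_unions_and_empties_source(self):
        t1 = Tube([strand("sA1eB1")])
        t2 = Tube([strand("sA2eB2")])
        out = merge(t1, t2)
        assert out is t1
        assert set(map(str, t1)) == {"sA1eB1", "sA2eB2"}
        assert len(t2) == 0

    def test_copy_preserves_multiplicity_and_leaves_original(self):
        x = strand("sA1eB1")
        t1 = Tube({x: 2})
        t2 = copy(t1)
        assert t2.contents == {x: 2}
        assert t1.contents == {x: 2}
        assert t2 is not t1

    def test_detect_empty_vs_nonempty(self):
        assert detect(Tube()) is False
        assert detect(Tube([strand("sA1eB1")])) is True

    def test_discarded_tube_rejects_further_operations(self):
        t = Tube([strand("sA1eB1")])
        discard(t)
        with pytest.raises(TubeUsageError):
            detect(t)

    def test_operations_increment_shared_counter_once_each(self):
        t = Tube([strand("sA1eB1"), strand("sA2eB2")])
        assert t.op_count == 0
        detect(t)
        t, matched = separation(t, [(SymbolAtom.e(T), SymbolAtom.job(2, T))])
        assert matched.op_count == t.op_count == 2
        detect(matched)  # shared counter: visible from both tubes
        assert t.op_count == 3


class TestSeparation:
    def test_single_motif_splits_by_containment(self):
        t = Tube([strand("sA1eB1"), strand("sA2eB2")])
        remaining, matched = separation(t, [(SymbolAtom.e(T), SymbolAtom.job(1, T))])
        assert set(map(str, matched)) == {"sA1eB1"}
        assert set(map(str, remaining)) == {"sA2eB2"}

    def test_universal_motif_matches_every_pool_strand(self):
        pool = anneal_ligate_pool([edge(i, j) for i in (1, 2) for j in (1, 2)], 2)
        size = len(pool)
        remaining, matched = separation(pool, [(SymbolAtom.s(T),)])
        assert len(matched) == size
        assert len(remaining) == 0

    def test_job_motif_count_matches_enumeration(self):
        """Strands with >= one job-2 edge among all 3-edge pools: 6^3 - 4^3."""
        edges = [edge(i, j) for i in (1, 2) for j in (1, 2, 3)]
        pool = anneal_ligate_pool(edges, 3)
        _, matched = separation(pool, [(SymbolAtom.e(T), SymbolAtom.job(2, T))])
        # independent count: enumerate edge triples directly
        expected = sum(
            1
            for combo in itertools.product([(i, j) for i in (1, 2) for j in (1, 2, 3)], repeat=3)
            if any(j == 2 for _, j in combo)
        )
        assert expected == 6**3 - 4**3 == 152
        assert len(matched) == expected

    def test_empty_motif_is_a_usage_error(self):
        with pytest.raises(TubeUsageError):
            separation(Tube([strand("sA1eB1")]), [()])

    def test_conservation_with_multiplicity(self):
        a, b = strand("sA1eB1"), strand("sA2eB2")
        t = Tube({a: 3, b: 2})
        remaining, matched = separation(t, [(SymbolAtom.job(2, T),)])
        combined = dict(remaining.contents)
        for s, c in matched.contents.items():
            combined[s] = combined.get(s, 0) + c
        assert combined == {a: 3, b: 2}


class TestSelection:
    def test_exact_length_filter(self):
        short = strand("sA1eB1sA2eB2")  # 40 mer
        full = strand("sA1eB1sA2eB2sA1eB2")  # 60 mer
        t = Tube([short, full])
        remaining, selected = selection(t, 60)
        assert set(selected) == {full}
        assert set(remaining) == {short}

    def test_empty_tube_selects_nothing(self):
        remaining, selected = selection(Tube(), 60)
        assert len(remaining) == len(selected) == 0

    def test_nonpositive_length_rejected(self):
        with pytest.raises(TubeUsageError):
            selection(Tube(), 0)


class TestSortSplit:
    def test_three_length_classes(self):
        s58 = strand("sA1eB1sA2eB2w11", weight_length=lambda i, j: 18)
        s60 = strand("sA1eB1sA2eB2w12", weight_length=lambda i, j: 20)
        s62 = strand("sA1eB1sA2eB2w21", weight_length=lambda i, j: 22)
        rest, shortest, longest = sort_split(Tube([s58, s60, s62]))
        assert set(shortest) == {s58}
        assert set(longest) == {s62}
        assert set(rest) == {s60}

    def test_two_classes_with_multiplicity(self):
        s60 = strand("sA1eB1sA2eB2sA1eB2")
        s65 = strand("sA1eB1sA2eB2sA1eB2w11")
        rest, shortest, longest = sort_split(Tube({s60: 1, s65: 2}))
        assert shortest.contents == {s60: 1}
        assert longest.contents == {s65: 2}
        assert len(rest) == 0

    def test_single_length_class_goes_to_shortest(self):
        s = strand("sA1eB1sA2eB2sA1eB2")
        rest, shortest, longest = sort_split(Tube({s: 4}))
        assert shortest.contents == {s: 4}
        assert len(longest) == 0
        assert len(rest) == 0

    def test_empty_tube_is_an_error(self):
        with pytest.raises(TubeUsageError, match="nothing to sort"):
            sort_split(Tube())


class TestAppendTail:
    def test_length_arithmetic(self):
        t = Tube([strand("sA1eB3")])
        append_tail(t, SymbolAtom.weight(1, 3, 1))
        (s,) = list(t)
        assert str(s) == "sA1eB3w13"
        assert s.length_mer == 21

    def test_empty_tube_is_noop(self):
        t = Tube()
        append_tail(t, SymbolAtom.weight(1, 1, 1))
        assert len(t) == 0


class TestPoolAssembly:
    def test_single_edge_single_slot(self):
        pool = anneal_ligate_pool([edge(1, 1)], 1)
        assert set(map(str, pool)) == {"sA1eB1"}

    def test_two_individuals_three_jobs(self):
        pool = anneal_ligate_pool([edge(i, j) for i in (1, 2) for j in (1, 2, 3)], 3)
        assert len(pool) == 216
        assert all(s.length_mer == 60 for s in pool)

    def test_rejects_bad_inputs(self):
        with pytest.raises(TubeUsageError):
            anneal_ligate_pool([], 2)
        with pytest.raises(TubeUsageError):
            anneal_ligate_pool([edge(1, 1)], 0)


class TestRead:
    def test_single_strand(self):
        x = strand("sA1eB1")
        assert read(Tube([x])) == x

    def test_empty_tube_is_an_error(self):
        with pytest.raises(TubeUsageError, match="no strand to read"):
            read(Tube())

    def test_tie_break_is_lexicographically_least(self):
        tube = Tube([strand(lbl) for lbl in
                     ["sA2eB1sA1eB3", "sA1eB3sA2eB1", "sA1eB2sA2eB3"]])
        assert str(read(tube)) == "sA1eB2sA2eB3"


class TestStrandNotation:
    def test_label_round_trip(self):
        label = "sA1eB3sA2eB1sA2eB2w13w21w22"
        s = parse_strand_label(label, t=5)
        assert str(s) == label

    def test_grammar_recognition(self):
        assert strand("sA1eB1sA2eB2w11").is_pool_strand()
        bad = SymbolicStrand([SymbolAtom.e(T), SymbolAtom.s(T)])
        assert not bad.is_pool_strand()


# ---------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------

EDGE_PAIRS = [(i, j) for i in (1, 2) for j in (1, 2, 3)]


@st.composite
def tubes(draw):
    n_strands = draw(st.integers(1, 8))
    contents = {}
    for _ in range(n_strands):
        k = draw(st.integers(1, 4))
        pairs = draw(st.lists(st.sampled_from(EDGE_PAIRS), min_size=k, max_size=k))
        label = "".join(f"sA{i}eB{j}" for i, j in pairs)
        contents[parse_strand_label(label, t=T)] = draw(st.integers(1, 3))
    return Tube(contents)


@given(tubes(), st.sampled_from([1, 2, 3]))
@settings(max_examples=60, derandomize=True)
def test_separation_partitions_exactly(tube, job):
    before = dict(tube.contents)
    remaining, matched = separation(tube, [(SymbolAtom.e(T), SymbolAtom.job(job, T))])
    combined = dict(remaining.contents)
    for s, c in matched.contents.items():
        assert s not in combined
        combined[s] = c
    assert combined == before
    assert all(s.contains_motif([SymbolAtom.e(T), SymbolAtom.job(job, T)]) for s in matched)


@given(tubes())
@settings(max_examples=60, derandomize=True)
def test_sort_split_conserves_and_orders(tube):
    before = dict(tube.contents)
    rest, shortest, longest = sort_split(tube)
    combined = {}
    for part in (rest.contents, shortest.contents, longest.contents):
        for s, c in part.items():
            assert s not in combined
            combined[s] = c
    assert combined == before
    if shortest.contents and longest.contents:
        assert max(s.length_mer for s in shortest) <= min(s.length_mer for s in longest)


@given(tubes())
@settings(max_examples=40, derandomize=True)
def test_append_tail_preserves_grammar_and_multiplicity(tube):
    before_total = len(tube)
    append_tail(tube, SymbolAtom.weight(1, 1, 3))
    assert len(tube) == before_total
    assert all(s.is_pool_strand() for s in tube)
    assert all(s.weight_atoms()[-1].length_mer == 3 for s in tube)
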