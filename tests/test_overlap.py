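import pytest
from hypothesis import given
from hypothesis import strategies as st

from omrlap.annotations import ConceptKey, ConceptSet
from omrlap.overlap import (
    REGION_LABELS,
    UndefinedRatioError,
    best_flexible_match,
    brute_force_partition,
    exact_intersection_ratio,
    flexible_intersection_ratio,
    partition_regions,
    percent,
    round_half_up,
    section_distribution,
    semtype_coverage_table,
    partition_regions as _pr,
)
from omrlap.terminology import TerminologyGraph
from .conftest import make_record


def cs(label, *terms, group="FIND", patient="p0"):
    return ConceptSet(label, frozenset(ConceptKey(t, group, patient) for t in terms))


POOL = [
    ConceptKey(f"t{i}", g, p)
    for i in range(5)
    for g in ("FIND", "PROC")
    for p in ("p0", "p1", "p2")
]


class TestPartition:
    def test_worked_example(self):
        p = partition_regions(
            cs("C_OMR", "a", "b", "c"), cs("C_ICN", "b", "c", "d"), cs("C_FCN", "c", "d", "e")
        )
        got = {label: {k.term for k in p[label]} for label in REGION_LABELS}
        assert got == {
            "A": {"c"}, "B": {"b"}, "C": set(), "D": {"d"},
            "E": set(), "F": {"e"}, "G": {"a"},
        }

    def test_all_empty(self):
        p = partition_regions(cs("C_OMR"), cs("C_ICN"), cs("C_FCN"))
        assert all(len(p[label]) == 0 for label in REGION_LABELS)

    @given(
        st.tuples(
            st.sets(st.sampled_from(POOL), max_size=30),
            st.sets(st.sampled_from(POOL), max_size=30),
            st.sets(st.sampled_from(POOL), max_size=30),
        )
    )
    def test_matches_brute_force_oracle(self, sets):
        omr, icn, fcn = (
            ConceptSet(lbl, frozenset(s))
            for lbl, s in zip(("C_OMR", "C_ICN", "C_FCN"), sets)
        )
        p = partition_regions(omr, icn, fcn)
        oracle = brute_force_partition(omr, icn, fcn)
        for label in REGION_LABELS:
            assert set(p[label]) == oracle[label]
        # disjoint union covers the three-set union
        union = set().union(*(p[label] for label in REGION_LABELS))
        assert union == set(omr.members | icn.members | fcn.members)
        assert sum(len(p[label]) for label in REGION_LABELS) == len(union)
        # pairwise-intersection identities
        assert p["A"] | p["B"] == omr.members & icn.members
        assert p["A"] | p["C"] == omr.members & fcn.members
        assert p["A"] | p["D"] == icn.members & fcn.members


class TestExactRatio:
    def test_half(self):
        assert exact_intersection_ratio(
            cs("o", "a", "b"), cs("c", "a", "b", "x", "y")
        ) == 0.5

    def test_disjoint_zero(self):
        assert exact_intersection_ratio(cs("o", "a"), cs("c", "x", "y")) == 0.0

    def test_empty_cn_undefined(self):
        with pytest.raises(UndefinedRatioError):
            exact_intersection_ratio(cs("o", "a"), cs("c"))


def chain_graph(*terms):
    """Terminology where consecutive terms are parent/child."""
    g = TerminologyGraph()
    prev = None
    for i, t in enumerate(terms):
        cid = f"C{i}"
        g.add_concept(cid, t)
        if prev is not None:
            g.add_edge(cid, prev)
        prev = cid
    return g


class TestFlexibleMatch:
    def test_exact_term_match_is_identity(self):
        g = chain_graph("heart")
        omr, cn = cs("o", "heart"), cs("c", "heart")
        m = best_flexible_match(omr, cn, g)
        key = next(iter(omr.members))
        assert m.matches[key] == (key, 1.0)

    def test_exact_term_match_without_terminology_entry(self):
        # string identity counts as identical concepts even when the toy
        # terminology has never heard of the term
        g = chain_graph("something else")
        omr, cn = cs("o", "tachycardia"), cs("c", "tachycardia")
        m = best_flexible_match(omr, cn, g)
        assert len(m.similar) == 1

    def test_unmapped_term_has_no_match(self):
        g = chain_graph("heart", "aorta")
        m = best_flexible_match(cs("o", "unknown thing"), cs("c", "heart"), g)
        assert m.matches == {}
        assert m.similar == frozenset()

    def test_adjacent_concept_matches_at_half(self):
        g = chain_graph("heart", "aorta")
        m = best_flexible_match(cs("o", "heart"), cs("c", "aorta"), g)
        ((_, (chosen, sim)),) = m.matches.items()
        assert chosen.term == "aorta"
        assert sim == 0.5

    def test_threshold_excludes_weak_matches(self):
        g = chain_graph("heart", "aorta")
        m = best_flexible_match(cs("o", "heart"), cs("c", "aorta"), g, threshold=0.6)
        assert m.matches == {}

    def test_tie_broken_by_lex_smallest_rendered_key(self):
        # "alpha" and "beta" are both adjacent to "heart"
        g = TerminologyGraph()
        g.add_concept("C0", "heart")
        g.add_concept("C1", "alpha")
        g.add_concept("C2", "beta")
        g.add_edge("C1", "C0")
        g.add_edge("C2", "C0")
        m = best_flexible_match(cs("o", "heart"), cs("c", "alpha", "beta"), g)
        ((_, (chosen, sim)),) = m.matches.items()
        assert sim == 0.5
        assert chosen.term == "alpha"

    def test_identical_keys_prefer_themselves_over_lex_order(self):
        # two patients share a term; each OMR key must claim its own CN twin
        g = chain_graph("x")
        omr = ConceptSet(
            "o", frozenset({ConceptKey("ct", "FIND", "p1"), ConceptKey("ct", "FIND", "p2")})
        )
        m = best_flexible_match(omr, omr.relabel("c"), g)
        assert m.similar == omr.members

    def test_bad_threshold_rejected(self):
        g = chain_graph("x")
        with pytest.raises(ValueError):
            best_flexible_match(cs("o"), cs("c", "x"), g, threshold=1.0)

    @given(
        st.sets(st.sampled_from(["heart", "aorta", "valve", "leaflet", "zzz"]), max_size=5),
        st.sets(st.sampled_from(["heart", "aorta", "valve", "leaflet", "qqq"]), min_size=1, max_size=5),
        st.sampled_from([0.0, 0.3, 0.6, 0.99]),
    )
    def test_flexible_never_below_exact(self, omr_terms, cn_terms, threshold):
        g = chain_graph("heart", "aorta", "valve", "leaflet")
        omr = cs("o", *omr_terms)
        cn = cs("c", *cn_terms)
        m = best_flexible_match(omr, cn, g, threshold=threshold)
        r_s = flexible_intersection_ratio(m, cn)
        r_e = exact_intersection_ratio(omr, cn)
        assert r_s >= r_e
        # growing C_OMR never shrinks C_SIMILAR
        bigger = ConceptSet("o2", omr.members | {ConceptKey("valve", "FIND", "p0")})
        m2 = best_flexible_match(bigger, cn, g, threshold=threshold)
        assert len(m2.similar) >= len(m.similar)

    def test_one_near_match_adds_one_over_cn(self):
        g = chain_graph("heart", "aorta")
        omr = cs("o", "shared", "heart")
        cn = cs("c", "shared", "aorta", "other")
        m = best_flexible_match(omr, cn, g)
        r_s = flexible_intersection_ratio(m, cn)
        r_e = exact_intersection_ratio(omr, cn)
        assert r_s == pytest.approx(r_e + 1 / len(cn))


class TestCoverageTable:
    def build_partition(self):
        omr, icn, fcn = set(), set(), set()
        def plant(region, n, group):
            for i in range(n):
                k = ConceptKey(f"{region}{group}{i}", group, "p0")
                if region in ("A", "B"):
                    omr.add(k); icn.add(k)
                if region in ("A", "C"):
                    omr.add(k); fcn.add(k)
        plant("A", 3, "FIND"); plant("B", 5, "FIND"); plant("C", 2, "FIND")
        plant("A", 1, "PROC"); plant("B", 1, "PROC")
        return partition_regions(
            ConceptSet("o", frozenset(omr)),
            ConceptSet("i", frozenset(icn)),
            ConceptSet("f", frozenset(fcn)),
        )

    def test_row_percentages_and_totals(self):
        df = semtype_coverage_table(self.build_partition())
        find = df[df.semantic_group == "FIND"].iloc[0]
        assert (find.A_freq, find.B_freq, find.C_freq, find.total) == (3, 5, 2, 10)
        assert (find.A_pct, find.B_pct, find.C_pct) == (30.0, 50.0, 20.0)
        total = df[df.semantic_group == "Total"].iloc[0]
        assert total.total == 12
        # frequencies in every row sum to the stated total
        assert ((df.A_freq + df.B_freq + df.C_freq) == df.total).all()

    def test_absent_group_has_no_row(self):
        df = semtype_coverage_table(self.build_partition())
        assert "DISO" not in set(df.semantic_group)

    def test_empty_partition_empty_table(self):
        p = partition_regions(cs("o"), cs("i"), cs("f"))
        assert semtype_coverage_table(p).empty


class TestSectionDistribution:
    def test_multi_section_concept_counts_per_section(self):
        recs = [
            make_record(term="tachy brady syndrome", semantic_group="DISO",
                        section="Diagnosis"),
            make_record(term="tachy brady syndrome", semantic_group="DISO",
                        section="Impression/report/plan"),
        ]
        concepts = {r.concept_key for r in recs}
        counts = section_distribution(recs, concepts)
        assert counts == {"Diagnosis": 1, "Impression/report/plan": 1}

    def test_repeat_across_documents_counts_once(self):
        recs = [
            make_record(document_id=f"d{i}", section="Physical Exam")
            for i in range(3)
        ]
        counts = section_distribution(recs, {recs[0].concept_key})
        assert counts == {"Physical Exam": 1}

    def test_empty_concept_set(self):
        assert section_distribution([make_record()], set()) == {}

    def test_unknown_section_folds_into_unknown(self):
        rec = make_record(section="Totally Novel Section")
        counts = section_distribution([rec], {rec.concept_key})
        assert counts == {"UNKNOWN": 1}

    def test_concepts_outside_set_ignored(self):
        rec = make_record()
        other = ConceptKey("nope", "FIND", "p9")
        assert section_distribution([rec], {other}) == {}


class TestRounding:
    @pytest.mark.parametrize(
        "num, den, expected",
        [
            (1, 800, 0.13),       # 0.125 rounds half-up
            (19164, 60161, 31.85),
            (4793, 25909, 18.50),
            (1, 3, 33.33),
        ],
    )
    def test_percent_half_up(self, num, den, expected):
        assert percent(num, den) == expected

    def test_round_half_up_three_decimals(self):
        assert round_half_up(0.0865, 3) == 0.087
        assert round_half_up(0.08649, 3) == 0.086
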