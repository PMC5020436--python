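import pytest

from tissue_enrichment import (
    AnnotationMap,
    EmptyDictionaryError,
    TrimParams,
    annotation_filter,
    build_dictionary,
    ceiling_filter,
    flag_redundant,
    propagate_annotations,
    read_dictionary,
    similarity_scores,
    sister_sets,
    write_dictionary,
)
from tissue_enrichment.fixtures import fig1_term_ids
from tissue_enrichment.trimming import SimilarityRecord

from _oracles import (
    annotation_filter_oracle,
    ceiling_filter_oracle,
    similarity_flag_oracle,
)
from conftest import edge_map, make_ontology


def amap(flavor="inherited", **sets):
    return AnnotationMap(
        gene_sets={t: frozenset(g) for t, g in sets.items()}, flavor=flavor
    )


class TestTrimParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"annotation_cutoff": 0},
            {"similarity_threshold": 0.0},
            {"similarity_threshold": 1.5},
            {"criterion": "max"},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrimParams(**kwargs)


class TestSimilarityScores:
    def test_identical_sister_sets_score_one(self):
        inh = amap(B={"g1", "g2"}, C={"g1", "g2"})
        (rec,) = similarity_scores(inh, [("A", frozenset({"B", "C"}))])
        assert rec.scores == (1.0, 1.0)
        assert rec.union_size == 2

    def test_partial_overlap(self):
        # sisters {a,b,c} and {c,d}: union 4 -> scores 0.75 and 0.5
        inh = amap(B={"a", "b", "c"}, C={"c", "d"})
        (rec,) = similarity_scores(inh, [("A", frozenset({"B", "C"}))])
        assert rec.union_size == 4
        assert sorted(rec.scores) == [0.5, 0.75]

    def test_three_disjoint_sisters(self):
        inh = amap(
            B={"g1", "g2"},
            C={"g3", "g4", "g5"},
            D={"g6", "g7", "g8", "g9", "g10"},
        )
        (rec,) = similarity_scores(inh, [("A", frozenset({"B", "C", "D"}))])
        assert rec.union_size == 10
        assert sorted(rec.scores) == [0.2, 0.3, 0.5]

    def test_empty_union_is_degenerate(self):
        inh = amap(B=set(), C=set())
        (rec,) = similarity_scores(inh, [("A", frozenset({"B", "C"}))])
        assert rec.degenerate
        assert rec.union_size == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_scores_bounded_and_sizes_cover_union(self, random_fixture, seed):
        fx = random_fixture(seed)
        inh = propagate_annotations(fx.ontology, fx.direct)
        for rec in similarity_scores(inh, sister_sets(fx.ontology)):
            assert all(0.0 <= s <= 1.0 for s in rec.scores)
            total = sum(len(inh.genes(t)) for t in rec.sister_ids)
            assert total >= rec.union_size


def record(scores, parent="A"):
    ids = tuple(f"S{i}" for i in range(len(scores)))
    return SimilarityRecord(
        parent_id=parent, sister_ids=ids, scores=tuple(scores), union_size=10
    )


class TestFlagRedundant:
    def test_any_flags_whole_set(self):
        flagged = flag_redundant(
            [record((1.0, 1.0))], TrimParams(similarity_threshold=0.95)
        )
        assert flagged == {"S0", "S1"}

    def test_avg_uses_the_mean(self):
        rec = record((0.96, 0.50))
        avg = TrimParams(similarity_threshold=0.95, criterion="avg")
        any_ = TrimParams(similarity_threshold=0.95, criterion="any")
        assert flag_redundant([rec], avg) == set()  # mean 0.73 <= 0.95
        assert flag_redundant([rec], any_) == {"S0", "S1"}

    def test_threshold_one_disables_trimming(self):
        rec = record((0.9, 0.9))
        for criterion in ("any", "avg"):
            params = TrimParams(similarity_threshold=1.0, criterion=criterion)
            assert flag_redundant([rec], params) == set()
        # even identical sisters score exactly 1, never strictly above it
        assert flag_redundant([record((1.0, 1.0))],
                              TrimParams(similarity_threshold=1.0)) == set()

    def test_node_in_several_sets_flagged_if_any_triggers(self):
        quiet = SimilarityRecord("P1", ("X", "Y"), (0.5, 0.5), 10)
        loud = SimilarityRecord("P2", ("X", "Z"), (0.99, 0.2), 10)
        flagged = flag_redundant(
            [quiet, loud], TrimParams(similarity_threshold=0.95)
        )
        assert flagged == {"X", "Z"}

    def test_degenerate_sets_always_flagged(self):
        rec = SimilarityRecord("P", ("X", "Y"), (0.0, 0.0), 0, degenerate=True)
        assert flag_redundant([rec], TrimParams()) == {"X", "Y"}


class TestAnnotationFilter:
    def test_branch_walk_stops_at_first_passing_node(self):
        ont = make_ontology({"B": ["A"], "C": ["B"]})
        inh = amap(C={f"g{i}" for i in range(3)},
                   B={f"g{i}" for i in range(30)},
                   A={f"g{i}" for i in range(40)})
        assert annotation_filter(ont, inh, cutoff=25) == {"C"}

    def test_removal_exposes_new_terminal(self):
        ont = make_ontology({"B": ["A"], "C": ["B"]})
        inh = amap(C={"g1"}, B={"g1", "g2"}, A={f"g{i}" for i in range(30)})
        assert annotation_filter(ont, inh, cutoff=25) == {"C", "B"}

    def test_excluded_terms_do_not_shield_parents(self):
        ont = make_ontology({"B": ["A"], "C": ["A"]})
        inh = amap(B={"g1"}, C={"g2"}, A={"g1", "g2"})
        removed = annotation_filter(ont, inh, cutoff=25, excluded={"B", "C"})
        assert removed == {"A"}  # A is terminal once B and C are excluded

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_fixed_point_oracle(self, random_fixture, seed):
        fx = random_fixture(seed)
        inh = propagate_annotations(fx.ontology, fx.direct)
        counts = {t: inh.count(t) for t in fx.ontology.graph.nodes}
        got = annotation_filter(fx.ontology, inh, cutoff=25)
        want = annotation_filter_oracle(edge_map(fx.ontology), counts, 25)
        assert got == want


class TestCeilingFilter:
    def test_incomplete_daughter_set_keeps_parent(self):
        ont = make_ontology({"B": ["A"], "C": ["A"]})
        inh = amap(B={f"g{i}" for i in range(30)}, C={"x1", "x2", "x3"},
                   A={f"g{i}" for i in range(30)} | {"x1", "x2", "x3"})
        removed = ceiling_filter(ont, inh, cutoff=25,
                                 survivors={"A", "B", "C"})
        assert removed == set()

    def test_complete_daughter_set_removes_parent(self):
        ont = make_ontology({"B": ["A"], "C": ["A"]})
        big = {f"g{i}" for i in range(30)}
        other = {f"h{i}" for i in range(30)}
        inh = amap(B=big, C=other, A=big | other)
        removed = ceiling_filter(ont, inh, cutoff=25,
                                 survivors={"A", "B", "C"})
        assert removed == {"A"}

    def test_leaf_only_survivors_remove_nothing(self):
        ont = make_ontology({"B": ["A"], "C": ["A"]})
        inh = amap(B={"g1"}, C={"g2"}, A={"g1", "g2"})
        assert ceiling_filter(ont, inh, cutoff=1, survivors={"B", "C"}) == set()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle(self, random_fixture, seed):
        fx = random_fixture(seed)
        inh = propagate_annotations(fx.ontology, fx.direct)
        counts = {t: inh.count(t) for t in fx.ontology.graph.nodes}
        under = annotation_filter(fx.ontology, inh, cutoff=25)
        survivors = set(fx.ontology.graph.nodes) - under
        got = ceiling_filter(fx.ontology, inh, cutoff=25, survivors=survivors)
        want = ceiling_filter_oracle(edge_map(fx.ontology), counts, 25, survivors)
        assert got == want


class TestBuildDictionary:
    def test_worked_example_survivors(self, fig1):
        ont, direct = fig1
        params = TrimParams(annotation_cutoff=25, similarity_threshold=1.0)
        d = build_dictionary(ont, direct, params)
        ids = fig1_term_ids()
        assert set(d.entries) == {ids["gamma"], ids["delta"]}
        assert d.removed_annotation == {ids[n] for n in ("epsilon", "zeta", "eta")}
        assert d.removed_ceiling == {ids[n] for n in ("alpha", "beta")}
        assert d.removed_similarity == set()

    def test_total_annotations_counts_pairs(self, fig1):
        ont, direct = fig1
        d = build_dictionary(
            ont, direct, TrimParams(annotation_cutoff=25, similarity_threshold=1.0)
        )
        assert d.total_annotations == sum(len(g) for g in d.entries.values())
        assert d.total_annotations == 28 + 30  # gamma inherited + delta

    def test_composition_matches_chained_stage_oracles(self, random_fixture):
        fx = random_fixture(7)
        params = TrimParams(annotation_cutoff=25, similarity_threshold=0.95)
        d = build_dictionary(fx.ontology, fx.direct, params)
        inh = propagate_annotations(fx.ontology, fx.direct)
        inherited_sets = {t: set(g) for t, g in inh.gene_sets.items()}
        counts = {t: len(g) for t, g in inherited_sets.items()}
        edges = edge_map(fx.ontology)
        parent_children = [
            (p, set(kids)) for p, kids in sister_sets(fx.ontology)
        ]
        flagged = similarity_flag_oracle(
            parent_children, inherited_sets, 0.95, "any"
        )
        under = annotation_filter_oracle(edges, counts, 25, excluded=flagged)
        survivors = set(edges) - flagged - under
        ceiling = ceiling_filter_oracle(edges, counts, 25, survivors)
        assert set(d.entries) == survivors - ceiling

    def test_cutoff_above_total_gene_count_is_empty_dictionary(self, fig1):
        ont, direct = fig1
        with pytest.raises(EmptyDictionaryError, match="lower annotation cutoff"):
            build_dictionary(
                ont, direct,
                TrimParams(annotation_cutoff=10_000, similarity_threshold=1.0),
            )

    @pytest.mark.parametrize("criterion", ["any", "avg"])
    def test_survivor_count_monotone_in_cutoff(self, random_fixture, criterion):
        fx = random_fixture(11)
        sizes = []
        for cutoff in (10, 25, 33, 50, 100):
            try:
                d = build_dictionary(
                    fx.ontology, fx.direct,
                    TrimParams(cutoff, 0.95, criterion),
                )
                sizes.append(len(d))
            except EmptyDictionaryError:
                sizes.append(0)
        assert sizes == sorted(sizes, reverse=True)

    @pytest.mark.parametrize("threshold", [0.5, 0.9, 0.95])
    def test_any_flags_superset_of_avg(self, random_fixture, threshold):
        for seed in range(5):
            fx = random_fixture(seed)
            inh = propagate_annotations(fx.ontology, fx.direct)
            recs = similarity_scores(inh, sister_sets(fx.ontology))
            any_ = flag_redundant(recs, TrimParams(25, threshold, "any"))
            avg = flag_redundant(recs, TrimParams(25, threshold, "avg"))
            assert any_ >= avg

    def test_every_entry_meets_cutoff(self, random_fixture):
        fx = random_fixture(13)
        d = build_dictionary(fx.ontology, fx.direct, TrimParams(25, 0.95, "any"))
        assert all(len(g) >= 25 for g in d.entries.values())


class TestSerialization:
    def test_round_trip_and_byte_stability(self, fig1, tmp_path):
        ont, direct = fig1
        d = build_dictionary(
            ont, direct, TrimParams(annotation_cutoff=25, similarity_threshold=1.0)
        )
        p1, _ = write_dictionary(d, str(tmp_path / "a"))
        p2, _ = write_dictionary(d, str(tmp_path / "b"))
        assert open(p1, "rb").read() == open(p2, "rb").read()
        loaded = read_dictionary(str(tmp_path / "a"))
        assert loaded.entries == d.entries
        assert loaded.names == d.names
        assert loaded.params == d.params
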