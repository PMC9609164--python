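import itertools
import math

import numpy as np
import pandas as pd
import pytest

from perizygote import phenotype_similarity as ps

OBO_TEXT = """\
format-version: 1.2

[Term]
id: HP:0000001
name: All

[Term]
id: HP:0000002
name: Organ A
is_a: HP:0000001 ! All

[Term]
id: HP:0000003
name: Finding under A
alt_id: HP:0009999
is_a: HP:0000002 ! Organ A

[Term]
id: HP:0000004
name: Multi-parent finding
is_a: HP:0000002 ! Organ A
is_a: HP:0000001 ! All

[Term]
id: HP:0000005
name: Old finding
is_obsolete: true
"""


class TestParseObo:
    @pytest.fixture()
    def obo_path(self, tmp_path):
        path = tmp_path / "toy.obo"
        path.write_text(OBO_TEXT)
        return path

    def test_chain_loaded(self, obo_path):
        onto = ps.parse_obo(obo_path)
        assert len(onto) == 4
        assert onto.root == "HP:0000001"
        assert onto.ancestors("HP:0000003") == {
            "HP:0000003",
            "HP:0000002",
            "HP:0000001",
        }

    def test_multiple_parents_in_closure(self, obo_path):
        onto = ps.parse_obo(obo_path)
        assert {"HP:0000002", "HP:0000001"} <= set(onto.ancestors("HP:0000004"))

    def test_obsolete_terms_skipped(self, obo_path):
        onto = ps.parse_obo(obo_path)
        assert "HP:0000005" not in onto

    def test_alt_id_resolves(self, obo_path):
        onto = ps.parse_obo(obo_path)
        assert onto.resolve("HP:0009999") == "HP:0000003"
        assert "HP:0009999" in onto

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            ps.OntologyGraph({"a": ["b"], "b": ["a"]})

    def test_multiple_roots_rejected(self):
        with pytest.raises(ValueError, match="root"):
            ps.OntologyGraph({"a": [], "b": []})


class TestInformationContent:
    def test_hand_computed_ic(self, toy_corpus):
        _, corpus = toy_corpus
        assert corpus.ic("R") == 0.0
        assert corpus.ic("t1") == pytest.approx(math.log(4 / 3))
        assert corpus.ic("t2") == pytest.approx(math.log(4))
        assert corpus.ic("t3") == pytest.approx(math.log(2))

    def test_monotone_along_is_a(self, toy_corpus):
        _, corpus = toy_corpus
        corpus.check_ic_monotone()

    def test_unannotated_term_has_no_ic(self):
        onto = ps.OntologyGraph({"R": [], "a": ["R"], "b": ["R"]})
        corpus = ps.AnnotationCorpus(onto, {"e": ["a"]})
        assert not corpus.has_ic("b")
        with pytest.raises(KeyError):
            corpus.ic("b")

    def test_unknown_annotation_terms_dropped(self):
        onto = ps.OntologyGraph({"R": [], "a": ["R"]})
        corpus = ps.AnnotationCorpus(onto, {"e": ["a", "nope"]})
        assert corpus.annotations["e"] == frozenset({"a"})
        assert corpus.dropped == {"e": ["nope"]}


def brute_force_lin(t1, t2, onto, corpus):
    common = onto.ancestors(t1) & onto.ancestors(t2)
    mica = max(
        (corpus.ic(a) for a in common if corpus.has_ic(a)), default=0.0
    )
    denom = corpus.ic(t1) + corpus.ic(t2)
    return 0.0 if denom == 0 else 2 * mica / denom


class TestLinSimilarity:
    def test_hand_computed_value(self, toy_corpus):
        _, corpus = toy_corpus
        expected = 2 * math.log(4 / 3) / (math.log(4 / 3) + math.log(2))
        assert ps.lin_similarity("t3", "t1", corpus) == pytest.approx(expected)
        assert expected == pytest.approx(0.587, abs=1e-3)

    def test_self_similarity_is_one(self, toy_corpus):
        _, corpus = toy_corpus
        assert ps.lin_similarity("t3", "t3", corpus) == 1.0

    def test_root_only_overlap_is_zero(self, toy_corpus):
        _, corpus = toy_corpus
        assert ps.lin_similarity("t1", "t2", corpus) == 0.0

    def test_matches_brute_force_on_random_dags(self, rng):
        """Lin similarity equals an all-common-ancestor maximisation
        oracle on random small ontologies."""
        for trial in range(5):
            n = 12
            parents = {"T0": []}
            for i in range(1, n):
                k = int(rng.integers(1, min(i, 2) + 1))
                ps_ = rng.choice(i, size=k, replace=False)
                parents[f"T{i}"] = [f"T{p}" for p in ps_]
            onto = ps.OntologyGraph(parents)
            terms = list(parents)
            ann = {
                f"e{j}": [terms[int(rng.integers(0, n))] for _ in range(2)]
                for j in range(15)
            }
            corpus = ps.AnnotationCorpus(onto, ann)
            annotated = [t for t in terms if corpus.has_ic(t)]
            for t1, t2 in itertools.combinations(annotated, 2):
                assert ps.lin_similarity(t1, t2, corpus) == pytest.approx(
                    brute_force_lin(t1, t2, onto, corpus)
                )


def brute_force_set_similarity(a, b, corpus):
    a = [t for t in a if corpus.has_ic(t)]
    b = [t for t in b if corpus.has_ic(t)]
    ab = sum(max(ps.lin_similarity(x, y, corpus) for y in b) for x in a) / len(a)
    ba = sum(max(ps.lin_similarity(x, y, corpus) for x in a) for y in b) / len(b)
    return (ab + ba) / 2


class TestSetSimilarity:
    def test_identical_sets(self, toy_corpus):
        _, corpus = toy_corpus
        assert ps.set_similarity(["t1", "t3"], ["t1", "t3"], corpus) == 1.0

    def test_root_only_related_sets(self, toy_corpus):
        _, corpus = toy_corpus
        assert ps.set_similarity(["t1"], ["t2"], corpus) == 0.0

    def test_matches_double_loop_oracle(self, toy_corpus):
        _, corpus = toy_corpus
        a, b = ["t1", "t3"], ["t2", "t3"]
        assert ps.set_similarity(a, b, corpus) == pytest.approx(
            brute_force_set_similarity(a, b, corpus)
        )

    def test_symmetry_and_bounds(self, toy_corpus):
        _, corpus = toy_corpus
        for a, b in [(["t1"], ["t2", "t3"]), (["t1", "t2"], ["t3"])]:
            s = ps.set_similarity(a, b, corpus)
            assert s == ps.set_similarity(b, a, corpus)
            assert 0.0 <= s <= 1.0

    def test_empty_effective_set_is_error(self):
        onto = ps.OntologyGraph({"R": [], "a": ["R"], "b": ["R"]})
        corpus = ps.AnnotationCorpus(onto, {"e": ["a"]})
        with pytest.raises(ValueError, match="b"):
            ps.set_similarity(["a"], ["b"], corpus)


@pytest.fixture()
def mpv_fixture():
    """Two phenotype branches: the proband spans both; gene G1 matches
    branch u closely, G2 adds the branch-v match (best pair improves the
    best single score by ~6%), G3 adds a redundant u-branch term (~1.6%)."""
    parents = {
        "R": [],
        "u": ["R"],
        "v": ["R"],
        "p1": ["u"],
        "g1": ["u"],
        "g3": ["u"],
        "p2": ["v"],
        "g2": ["v"],
        "x1": ["v"],
        "x2": ["R"],
    }
    onto = ps.OntologyGraph(parents)
    counts = {"p1": 4, "g1": 4, "g3": 2, "p2": 4, "g2": 4, "x1": 10, "x2": 14}
    ann = {}
    i = 0
    for term, k in counts.items():
        for _ in range(k):
            ann[f"e{i}"] = [term]
            i += 1
    corpus = ps.AnnotationCorpus(onto, ann)
    genes = {"G1": ["g1"], "G2": ["g2"], "G3": ["g3"]}
    return corpus, ["p1", "p2"], genes


class TestMpvSearch:
    def test_matches_combination_oracle(self, mpv_fixture):
        corpus, proband, genes = mpv_fixture
        res = ps.mpv_search(proband, genes, corpus, k_max=3)
        for k in (1, 2, 3):
            best = max(
                brute_force_set_similarity(
                    proband,
                    set().union(*(genes[g] for g in combo)),
                    corpus,
                )
                for combo in itertools.combinations(sorted(genes), k)
            )
            assert res.per_k.loc[k - 1, "score"] == pytest.approx(best)

    def test_flag_fires_above_five_percent_not_at_one(self, mpv_fixture):
        """A dual-gene model improving the best single-gene score by ~6%
        relative is flagged as multilocus; a third gene adding ~1.6% is
        not."""
        corpus, proband, genes = mpv_fixture
        res = ps.mpv_search(proband, genes, corpus, k_max=3)
        i2 = res.per_k.loc[1, "improvement"]
        i3 = res.per_k.loc[2, "improvement"]
        assert 0.05 < i2 < 0.08
        assert 0.0 < i3 < 0.03
        assert list(res.per_k["mpv_flag"]) == [False, True, False]
        assert res.mpv and res.best_k == 2

    def test_flag_follows_relative_improvement_rule(self, mpv_fixture):
        corpus, proband, genes = mpv_fixture
        res = ps.mpv_search(proband, genes, corpus, k_max=3)
        scores = res.per_k["score"].to_numpy()
        for k in range(1, len(scores)):
            expected = scores[k] / scores[k - 1] - 1 > ps.MPV_IMPROVEMENT
            assert bool(res.per_k.loc[k, "mpv_flag"]) == expected

    def test_single_gene_cannot_flag(self, mpv_fixture):
        corpus, proband, genes = mpv_fixture
        res = ps.mpv_search(proband, {"G1": genes["G1"]}, corpus, k_max=1)
        assert not res.mpv

    def test_combination_cap(self, mpv_fixture):
        corpus, proband, genes = mpv_fixture
        with pytest.raises(ValueError, match="prefilter"):
            ps.mpv_search(proband, genes, corpus, k_max=3, max_combinations=2)

    def test_no_genes_is_error(self, mpv_fixture):
        corpus, proband, _ = mpv_fixture
        with pytest.raises(ValueError):
            ps.mpv_search(proband, {}, corpus)


class TestClusterCases:
    @pytest.fixture()
    def grouped_cases(self, mpv_fixture):
        corpus, _, _ = mpv_fixture
        cases = {
            "case_u1": ["p1", "g1"],
            "case_u2": ["p1", "g3"],
            "case_v1": ["p2", "g2"],
            "case_v2": ["p2", "x1"],
        }
        return corpus, cases

    def test_matrix_symmetric_unit_diagonal(self, grouped_cases):
        corpus, cases = grouped_cases
        sim, _, labels = ps.cluster_cases(cases, corpus)
        assert np.allclose(np.diag(sim), 1.0)
        assert np.allclose(sim.to_numpy(), sim.to_numpy().T)
        assert labels == sorted(cases)

    def test_identical_cases_merge_first(self, mpv_fixture):
        corpus, _, _ = mpv_fixture
        cases = {"a": ["p1", "g1"], "b": ["p1", "g1"], "c": ["p2"]}
        _, z, labels = ps.cluster_cases(cases, corpus)
        first = sorted(labels[int(i)] for i in z[0, :2])
        assert first == ["a", "b"]
        assert z[0, 2] == pytest.approx(0.0)

    def test_two_groups_recovered_at_two_cluster_cut(self, grouped_cases):
        from scipy.cluster.hierarchy import fcluster

        corpus, cases = grouped_cases
        _, z, labels = ps.cluster_cases(cases, corpus)
        assign = fcluster(z, t=2, criterion="maxclust")
        groups = {}
        for label, cl in zip(labels, assign):
            groups.setdefault(cl, set()).add(label)
        assert {frozenset(g) for g in groups.values()} == {
            frozenset({"case_u1", "case_u2"}),
            frozenset({"case_v1", "case_v2"}),
        }
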