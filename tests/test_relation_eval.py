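"""Relation term retrieval metrics: hit, RR, WRR and their invariants."""

import numpy as np
import pytest

from semrel import (
    EmbeddingMatrix,
    EvalTermSet,
    PlantedSpec,
    evaluate_all,
    evaluate_relation,
    hit,
    make_relation_fixture,
)
from semrel.embeddings import NeighborSet, nearest_neighbors_of_term

from conftest import brute_force_neighbors


def ns(*terms):
    return NeighborSet("q", [(t, 1.0 - 0.01 * i) for i, t in enumerate(terms)], len(terms))


def make_evals(gold_by_term):
    return EvalTermSet(
        terms=list(gold_by_term),
        gold={t: {"rel": set(g)} for t, g in gold_by_term.items()},
    )


class TestHit:
    def test_one_element_intersection(self):
        assert hit({"y", "z"}, ns("x", "y")) == (1, 1)

    def test_empty_intersection(self):
        assert hit({"z"}, ns("x", "y")) == (0, 0)

    def test_multiple_matches_counted(self):
        assert hit({"x", "y", "z"}, ns("x", "y", "w")) == (1, 2)

    def test_empty_gold_set_rejected(self):
        with pytest.raises(ValueError):
            hit(set(), ns("x"))

    def test_matches_set_intersection_oracle_on_toy_embedding(self):
        rng = np.random.default_rng(17)
        E = EmbeddingMatrix([f"w{i}" for i in range(30)], rng.standard_normal((30, 8)))
        for term in E.terms[:10]:
            gold = set(rng.choice(E.terms, size=4, replace=False)) - {term}
            nbrs = nearest_neighbors_of_term(E, term, 5)
            h, m = hit(gold, nbrs)
            oracle_terms = {t for t, _ in brute_force_neighbors(E, E.vector(term), 5, {term})}
            assert m == len(oracle_terms & gold)
            assert h == (1 if oracle_terms & gold else 0)


class TestRetrievedRatio:
    def test_direct_substitution(self):
        # 4 eval terms, hits {1,0,1,1} -> RR 0.75; engineered geometrically
        vecs = {
            "e1": [1, 0, 0], "e1g": [0.99, 0.14, 0],
            "e2": [0, 1, 0], "e2far": [1, 0, 0.5],
            "e3": [0, 0, 1], "e3g": [0.1, 0, 0.99],
            "e4": [1, 1, 0], "e4g": [0.9, 1.1, 0],
        }
        E = EmbeddingMatrix(list(vecs), np.array(list(vecs.values()), dtype=float))
        evals = make_evals({"e1": {"e1g"}, "e2": {"e2g_oovless"}, "e3": {"e3g"}, "e4": {"e4g"}})
        m = evaluate_relation(evals, "rel", E, k=1)
        assert m.rr == pytest.approx(0.75)
        assert m.n_eval == 4

    def test_rr_is_one_when_k_covers_vocabulary(self):
        rng = np.random.default_rng(2)
        E = EmbeddingMatrix([f"w{i}" for i in range(10)], rng.standard_normal((10, 4)))
        evals = make_evals({f"w{i}": {f"w{(i + 1) % 10}"} for i in range(5)})
        m = evaluate_relation(evals, "rel", E, k=9)
        assert m.rr == 1.0

    def test_planted_fixture_rr_one_at_every_k(self, default_spec):
        E, kb, evals = make_relation_fixture(default_spec)
        for k in (1, 2, 3, 4, 5):
            tab = evaluate_all(evals, E, (k,))
            assert (tab[tab.relation != "average"].rr == 1.0).all()

    def test_zero_denominator_reports_absent(self):
        E = EmbeddingMatrix(["a", "b"], np.array([[1.0, 0], [0, 1.0]]))
        evals = make_evals({"zz_oov": {"a"}})
        assert evaluate_relation(evals, "rel", E, k=1) is None


class TestWeightedRetrievedRatio:
    def test_weight_formula_partial_retrieval(self):
        # |e.rel| = 10, k = 5, 2 gold retrieved -> weight 2/min(5,10) = 0.4
        rng = np.random.default_rng(0)
        e = np.zeros(12); e[0] = 1.0
        rows, names = [e], ["e"]
        # two gold terms adjacent to e, eight gold far in other axes
        rows += [np.array([0.99] + [0.14 if i == j else 0 for i in range(11)]) for j in range(2)]
        names += ["g0", "g1"]
        for j in range(2, 10):
            v = np.zeros(12); v[j] = 1.0
            rows.append(v); names.append(f"g{j}")
        # distractors fill the remaining top-5 slots
        for j in range(3):
            v = np.zeros(12); v[0] = 0.5; v[11 - j % 2] = 1.0
            rows.append(v); names.append(f"d{j}")
        E = EmbeddingMatrix(names, np.vstack(rows))
        evals = make_evals({"e": {f"g{j}" for j in range(10)}})
        m = evaluate_relation(evals, "rel", E, k=5)
        top5 = {t for t, _ in nearest_neighbors_of_term(E, "e", 5).entries}
        assert len(top5 & {f"g{j}" for j in range(10)}) == 2  # construction check
        assert m.wrr == pytest.approx(2 / 5)

    def test_wrr_equals_rr_when_single_relation_term(self):
        spec = PlantedSpec(terms_per_relation=1, seed=5)
        E, kb, evals = make_relation_fixture(spec)
        for k in (1, 3, 10):
            tab = evaluate_all(evals, E, (k,))
            assert np.allclose(tab.rr, tab.wrr)

    def test_indicator_mode_uses_hit_not_count(self, default_spec):
        E, kb, evals = make_relation_fixture(default_spec)
        k = 5  # > terms_per_relation=3, so count mode: 3/3=1, indicator: 1/3
        count = evaluate_all(evals, E, (k,), wrr_mode="count")
        ind = evaluate_all(evals, E, (k,), wrr_mode="indicator")
        assert (count[count.relation != "average"].wrr == 1.0).all()
        assert ind[ind.relation != "average"].wrr.unique() == pytest.approx(1 / 3)

    def test_hand_enumerated_oracle_on_random_fixture(self):
        rng = np.random.default_rng(23)
        E = EmbeddingMatrix([f"w{i}" for i in range(20)], rng.standard_normal((20, 6)))
        gold = {}
        for t in E.terms[:8]:
            pool = [x for x in E.terms if x != t]
            gold[t] = set(rng.choice(pool, size=rng.integers(1, 6), replace=False))
        evals = make_evals(gold)
        k = 3
        m = evaluate_relation(evals, "rel", E, k=k)
        # independent oracle: brute-force neighbors + direct formula substitution
        hits, weights = [], []
        for t, g in gold.items():
            top = {x for x, _ in brute_force_neighbors(E, E.vector(t), k, {t})}
            n = len(top & g)
            hits.append(1 if n else 0)
            weights.append(n / min(k, len(g)))
        assert m.rr == pytest.approx(sum(hits) / 8)
        assert m.wrr == pytest.approx(sum(weights) / 8)


class TestEvaluateAll:
    def test_average_row_is_unweighted_mean(self):
        rng = np.random.default_rng(4)
        E = EmbeddingMatrix([f"w{i}" for i in range(15)], rng.standard_normal((15, 5)))
        evals = EvalTermSet(
            terms=["w0", "w1", "w2"],
            gold={
                "w0": {"r1": {"w3", "w4"}},
                "w1": {"r1": {"w5"}},
                "w2": {"r2": {"w6"}},
            },
        )
        tab = evaluate_all(evals, E, (3,))
        rows = tab[tab.relation != "average"]
        avg = tab[tab.relation == "average"].iloc[0]
        assert avg.rr == pytest.approx(rows.rr.mean())
        assert avg.wrr == pytest.approx(rows.wrr.mean())

    def test_rr_wrr_non_decreasing_in_k_and_wrr_bounded_by_rr(self):
        rng = np.random.default_rng(31)
        E = EmbeddingMatrix([f"w{i}" for i in range(40)], rng.standard_normal((40, 8)))
        gold = {}
        for t in E.terms[:12]:
            pool = [x for x in E.terms if x != t]
            gold[t] = set(rng.choice(pool, size=rng.integers(1, 7), replace=False))
        evals = make_evals(gold)
        tab = evaluate_all(evals, E, (1, 3, 8, 20))
        assert (tab.wrr <= tab.rr + 1e-12).all()
        by_rel = tab[tab.relation == "rel"].sort_values("k")
        assert by_rel.rr.is_monotonic_increasing
        assert by_rel.wrr.is_monotonic_increasing

    def test_invariant_to_term_order_and_vocab_permutation(self):
        rng = np.random.default_rng(8)
        E = EmbeddingMatrix([f"w{i}" for i in range(20)], rng.standard_normal((20, 6)))
        gold = {t: {E.terms[(i + 3) % 20]} for i, t in enumerate(E.terms[:6])}
        evals = make_evals(gold)
        base = evaluate_relation(evals, "rel", E, k=4)
        evals_rev = make_evals(dict(reversed(list(gold.items()))))
        perm = rng.permutation(20)
        E_perm = EmbeddingMatrix([E.terms[i] for i in perm], E.vectors[perm])
        again = evaluate_relation(evals_rev, "rel", E_perm, k=4)
        assert base.rr == pytest.approx(again.rr)
        assert base.wrr == pytest.approx(again.wrr)

    def test_oov_eval_terms_leave_numerator_and_denominator(self, default_spec):
        E, kb, evals = make_relation_fixture(default_spec)
        evals.terms.append("zz_unseen")
        evals.gold["zz_unseen"] = {"rel0": {"r0e0g0"}}
        tab = evaluate_all(evals, E, (1,))
        row = tab[(tab.relation == "rel0") & (tab.k == 1)].iloc[0]
        assert row.n_oov == 1
        assert row.rr == 1.0
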