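"""Relation term retrieval: hit, retrieved ratio (RR), weighted retrieved ratio (WRR).

For an evaluation term *e* with gold relation-term set *e.rel*, let *N_e*
be its top-*k* cosine neighbors (the query term itself excluded).  Then

    hit(e, rel)  = 1 if N_e ∩ e.rel ≠ ∅ else 0
    RR(rel)      = Σ_e hit(e, rel) / |{e : e.rel ≠ ∅}|

RR is the probability that at least one gold relation term occurs among
the nearest neighbors of an evaluation term.  Because relations differ
wildly in how many gold terms they offer (a term may have one antonym but
dozens of siblings), RR is complemented by a weighted variant that scores
the fraction of retrievable gold terms actually found:

    weight(e, rel, n) = n / min(k, |e.rel|)
    WRR(rel)          = Σ_e weight(e, rel, n_e) / |{e : e.rel ≠ ∅}|

Two readings of *n* are supported.  The default ``count`` mode takes
n_e = |N_e ∩ e.rel|, the number of gold terms retrieved, so weight is the
recall against the best achievable at this k; the ``indicator`` mode takes
n_e = hit(e, rel) ∈ {0, 1}.  Both keep WRR ≤ RR, since each summand is at
most the corresponding hit.

Denominator policy: evaluation terms absent from the embedding vocabulary
(or with a zero-norm vector) leave both numerator and denominator and are
counted in the report.  Gold terms absent from the vocabulary still count
in |e.rel| by default; ``in_vocab_gold_only=True`` restricts |e.rel| to
retrievable terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .embeddings import EmbeddingMatrix, NeighborSet, nearest_neighbors_of_term
from .terms import EvalTermSet

__all__ = [
    "RelationMetrics",
    "hit",
    "retrieved_ratio",
    "weighted_retrieved_ratio",
    "evaluate_relation",
    "evaluate_all",
    "DEFAULT_K_LIST",
]

DEFAULT_K_LIST = (1, 5, 20, 100)
WRR_MODES = ("count", "indicator")


@dataclass(frozen=True)
class RelationMetrics:
    """RR/WRR of one relation at one k, with the evaluated-term count."""

    relation: str
    k: int
    n_eval: int
    n_oov: int
    rr: float
    wrr: float

    def __post_init__(self):
        if not (0.0 <= self.wrr <= self.rr <= 1.0):
            raise ValueError(f"invalid metrics: rr={self.rr}, wrr={self.wrr}")


def hit(gold: set[str], neighbors: NeighborSet) -> tuple[int, int]:
    """The 0/1 hit indicator and the retrieved-gold-term count.

    ``hit = 1`` iff at least one gold relation term appears among the
    neighbors; ``matched_count`` is the size of the intersection.
    """
    if not gold:
        raise ValueError("hit() requires a nonempty gold set; filter upstream")
    matched = sum(1 for t, _ in neighbors.entries if t in gold)
    return (1 if matched > 0 else 0), matched


def _sums(
    evals: EvalTermSet,
    relation: str,
    E: EmbeddingMatrix,
    k: int,
    wrr_mode: str,
    in_vocab_gold_only: bool,
) -> tuple[int, int, float, float]:
    if wrr_mode not in WRR_MODES:
        raise ValueError(f"wrr_mode must be one of {WRR_MODES}")
    n_eval = n_oov = 0
    hit_sum = 0
    weight_sum = 0.0
    for term in evals.terms_with(relation):
        gold = evals.gold[term][relation]
        if in_vocab_gold_only:
            gold = {g for g in gold if g in E}
            if not gold:
                continue
        if term not in E or E.norms[E.index[term]] == 0.0:
            n_oov += 1
            continue
        nbrs = nearest_neighbors_of_term(E, term, k)
        h, matched = hit(gold, nbrs)
        n = matched if wrr_mode == "count" else h
        n_eval += 1
        hit_sum += h
        weight_sum += n / min(k, len(gold))
    return n_eval, n_oov, hit_sum, weight_sum


def evaluate_relation(
    evals: EvalTermSet,
    relation: str,
    E: EmbeddingMatrix,
    k: int,
    wrr_mode: str = "count",
    in_vocab_gold_only: bool = False,
) -> RelationMetrics | None:
    """RR and WRR of one relation at one k; ``None`` when no term is evaluable."""
    n_eval, n_oov, hit_sum, weight_sum = _sums(
        evals, relation, E, k, wrr_mode, in_vocab_gold_only
    )
    if n_eval == 0:
        return None
    return RelationMetrics(
        relation=relation,
        k=k,
        n_eval=n_eval,
        n_oov=n_oov,
        rr=hit_sum / n_eval,
        wrr=weight_sum / n_eval,
    )


def retrieved_ratio(evals, relation, E, k, **kw) -> RelationMetrics | None:
    """Alias of :func:`evaluate_relation` emphasizing the RR field."""
    return evaluate_relation(evals, relation, E, k, **kw)


def weighted_retrieved_ratio(evals, relation, E, k, **kw) -> RelationMetrics | None:
    """Alias of :func:`evaluate_relation` emphasizing the WRR field."""
    return evaluate_relation(evals, relation, E, k, **kw)


def evaluate_all(
    evals: EvalTermSet,
    E: EmbeddingMatrix,
    k_list=DEFAULT_K_LIST,
    relations=None,
    wrr_mode: str = "count",
    in_vocab_gold_only: bool = False,
) -> pd.DataFrame:
    """Per-(relation, k) metrics table plus unweighted-mean ``average`` rows.

    The average row at each k is the mean of the per-relation RR (and WRR)
    over the relations that were evaluable at that k — each relation counts
    once, regardless of how many terms it has.
    """
    k_list = tuple(k_list)
    if list(k_list) != sorted(k_list) or k_list[0] < 1:
        raise ValueError("k_list must be ascending positive integers")
    if relations is None:
        relations = evals.relations()
    rows = []
    for k in k_list:
        per_rel = []
        for rel in relations:
            m = evaluate_relation(evals, rel, E, k, wrr_mode, in_vocab_gold_only)
            if m is None:
                continue
            per_rel.append(m)
            rows.append(
                {"relation": m.relation, "k": k, "n_eval": m.n_eval, "n_oov": m.n_oov,
                 "rr": m.rr, "wrr": m.wrr}
            )
        if per_rel:
            rows.append(
                {
                    "relation": "average",
                    "k": k,
                    "n_eval": sum(m.n_eval for m in per_rel),
                    "n_oov": sum(m.n_oov for m in per_rel),
                    "rr": sum(m.rr for m in per_rel) / len(per_rel),
                    "wrr": sum(m.wrr for m in per_rel) / len(per_rel),
                }
            )
    return pd.DataFrame(rows, columns=["relation", "k", "n_eval", "n_oov", "rr", "wrr"])
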