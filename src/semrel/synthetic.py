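"""Planted-structure fixtures with analytically known metric values.

Two generators, both driven by :class:`PlantedSpec` and a seed:

* :func:`make_analogy_fixture` plants parallelogram structure: each group
  g has a shared offset vector o_g and word pairs (s_i, t_i) with
  t_i = s_i + o_g + noise.  At ``noise_sd = 0`` the analogy prediction
  c - a + b lands exactly on the answer vector, so top-1 accuracy is 1.0
  by construction; as noise grows the closure degrades toward chance.

* :func:`make_relation_fixture` plants retrieval structure: every
  evaluation term's retrievable gold relation terms sit at cosine exactly
  ``neighbor_cosine`` to it while everything else (other evaluation terms,
  foreign gold terms, distractors) is kept below ``neighbor_cosine - 0.3``
  by rejection sampling.  Consequently the top-m neighbors of every
  evaluation term, where m is its number of planted gold terms, are
  exactly those gold terms, giving closed-form metrics in count mode:

      matched(e, k) = min(k, m)
      RR            = 1                          for every k >= 1
      WRR           = min(k, m) / min(k, |e.rel|)

  With the whole gold set planted (``retrievable_fraction = 1``, the
  default) WRR is 1 at every k.  Setting ``retrievable_fraction < 1``
  leaves the remaining gold terms out of the embedding vocabulary
  entirely -- they can never be retrieved but still count in |e.rel| --
  so the weight's discount is exact, e.g. |e.rel| = 10 with 5 retrievable
  at k = 20 gives WRR = 5/10 = 0.5.

Rejection sampling failures (too much structure for too few dimensions)
raise :class:`GeometricInfeasibilityError` naming the violated constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .analogy import AnalogyQuestion, build_questions_from_pairs
from .embeddings import EmbeddingMatrix
from .kb import RelationKB, RelationTriple, build_kb
from .terms import EvalTermSet

__all__ = [
    "PlantedSpec",
    "GeometricInfeasibilityError",
    "make_analogy_fixture",
    "make_relation_fixture",
]


class GeometricInfeasibilityError(RuntimeError):
    """Raised when the requested planted geometry cannot be sampled."""


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of the planted fixtures.

    dim
        Embedding dimension; >= 2 (moderate dimensions, 16-64, give the
        rejection sampler near-orthogonal random directions cheaply).
    n_groups, pairs_per_group
        Analogy fixture: number of relation groups and word pairs per group.
    offset_norm
        Euclidean norm of each group's shared offset vector.
    noise_sd
        Per-coordinate Gaussian noise added to every answer vector t_i.
    n_relations, eval_terms_per_relation, terms_per_relation
        Relation fixture: relations, evaluation terms per relation, and
        gold relation terms planted per evaluation term.
    neighbor_cosine
        Cosine between an evaluation term and each of its planted gold
        terms; everything else stays below ``neighbor_cosine - 0.3``.
    n_distractors
        Background vocabulary terms with no planted relation.
    retrievable_fraction
        Fraction of each gold set actually planted near its term (the rest
        is placed at distractor level); 1.0 plants everything.
    """

    dim: int = 32
    n_groups: int = 4
    pairs_per_group: int = 10
    offset_norm: float = 4.0
    noise_sd: float = 0.0
    n_relations: int = 3
    eval_terms_per_relation: int = 4
    terms_per_relation: int = 3
    neighbor_cosine: float = 0.95
    n_distractors: int = 50
    retrievable_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if not (0.0 < self.neighbor_cosine <= 1.0):
            raise ValueError("neighbor_cosine must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.retrievable_fraction <= 1.0):
            raise ValueError("retrievable_fraction must be in [0, 1]")

    def with_(self, **kw) -> "PlantedSpec":
        return replace(self, **kw)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_analogy_fixture(spec: PlantedSpec) -> tuple[EmbeddingMatrix, list[AnalogyQuestion]]:
    """Embedding plus questions with planted parallelogram structure.

    Terms are named ``g{g}s{i}`` (sources) and ``g{g}t{i}`` (answers), with
    ``d{j}`` distractors.  Questions enumerate unordered pairs-of-pairs per
    group.  Deterministic given ``spec.seed``.
    """
    if spec.pairs_per_group < 2:
        raise ValueError("pairs_per_group must be >= 2 to form questions")
    rng = np.random.default_rng(spec.seed)
    terms: list[str] = []
    rows: list[np.ndarray] = []
    questions: list[AnalogyQuestion] = []
    for g in range(spec.n_groups):
        offset = _unit(rng.standard_normal(spec.dim)) * spec.offset_norm
        pairs = []
        for i in range(spec.pairs_per_group):
            s = _unit(rng.standard_normal(spec.dim))
            t = s + offset + rng.standard_normal(spec.dim) * spec.noise_sd
            s_name, t_name = f"g{g}s{i}", f"g{g}t{i}"
            terms += [s_name, t_name]
            rows += [s, t]
            pairs.append((s_name, t_name))
        questions.extend(
            build_questions_from_pairs(pairs, group=f"group{g}", seed=spec.seed)
        )
    for j in range(spec.n_distractors):
        terms.append(f"d{j}")
        rows.append(_unit(rng.standard_normal(spec.dim)))
    E = EmbeddingMatrix(terms, np.vstack(rows))
    return E, questions


def _sample_separated(rng, dim, existing, sep, what, attempts=500):
    """A random unit vector with |cos| <= sep against every row of ``existing``."""
    for _ in range(attempts):
        v = _unit(rng.standard_normal(dim))
        if not existing or max(abs(float(v @ u)) for u in existing) <= sep:
            return v
    raise GeometricInfeasibilityError(
        f"could not place {what}: |cos| <= {sep:.3f} against {len(existing)} "
        f"existing vectors in {dim} dimensions after {attempts} attempts"
    )


def make_relation_fixture(
    spec: PlantedSpec,
) -> tuple[EmbeddingMatrix, RelationKB, EvalTermSet]:
    """Embedding, KB and evaluation-term set with planted gold neighborhoods.

    Every evaluation term ``r{r}e{i}`` has ``terms_per_relation`` gold terms
    under relation ``rel{r}``; the planted (retrievable) ones sit at cosine
    exactly ``neighbor_cosine``, the rest of the vocabulary below
    ``neighbor_cosine - 0.3``.  Guarantee: for every evaluation term the
    top-min(k, n_planted) neighbors are precisely its planted gold terms.
    """
    nc = spec.neighbor_cosine
    if nc < 0.5:
        raise GeometricInfeasibilityError(
            f"neighbor_cosine={nc} < 0.5: planted gold terms could not dominate "
            "the distractor ceiling neighbor_cosine - 0.3"
        )
    sep = min(0.2, (nc - 0.3) / 2.0)
    rng = np.random.default_rng(spec.seed)
    s = float(np.sqrt(1.0 - nc * nc))

    eval_names: list[str] = []
    eval_vecs: list[np.ndarray] = []
    entries: list[tuple[str, np.ndarray]] = []
    triples: list[RelationTriple] = []
    gold_map: dict[str, dict[str, set[str]]] = {}

    for r in range(spec.n_relations):
        rel = f"rel{r}"
        for i in range(spec.eval_terms_per_relation):
            e_name = f"r{r}e{i}"
            e_vec = _sample_separated(rng, spec.dim, eval_vecs, sep, f"evaluation term {e_name}")
            eval_names.append(e_name)
            eval_vecs.append(e_vec)
            entries.append((e_name, e_vec))
            n_near = int(round(spec.terms_per_relation * spec.retrievable_fraction))
            gold_here: set[str] = set()
            for j in range(spec.terms_per_relation):
                g_name = f"r{r}e{i}g{j}"
                if j < n_near:
                    others = [u for u in eval_vecs if u is not e_vec]
                    raw = _sample_separated(
                        rng, spec.dim, others, sep, f"gold direction for {g_name}"
                    )
                    orth = _unit(raw - float(raw @ e_vec) * e_vec)
                    g_vec = nc * e_vec + s * orth
                    entries.append((g_name, g_vec))
                # unretrievable gold terms stay out of the vocabulary but
                # remain in the KB, so they count in |e.rel| only
                triples.append(RelationTriple(e_name, rel, g_name))
                gold_here.add(g_name)
            gold_map.setdefault(e_name, {})[rel] = gold_here

    for j in range(spec.n_distractors):
        v = _sample_separated(rng, spec.dim, eval_vecs, nc - 0.3, f"distractor d{j}")
        entries.append((f"d{j}", v))

    terms = [t for t, _ in entries]
    E = EmbeddingMatrix(terms, np.vstack([v for _, v in entries]))
    kb = build_kb(triples)
    evals = EvalTermSet(
        terms=eval_names,
        gold=gold_map,
        provenance={"candidates": len(eval_names), "matched": len(eval_names)},
    )
    return E, kb, evals
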