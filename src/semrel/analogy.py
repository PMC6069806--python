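"""Analogy term retrieval: question construction and top-k accuracy.

An analogy question is a quadruple *(a, b, c, d)*: from the embedding
vectors of the first three words the answer vector is predicted as

    d' = c - a + b

and the question counts as correct at *k* when the true *d* is among the
*k* cosine-nearest neighbors of *d'*.  Questions come either from the
standard text layout (``: group`` section headers followed by 4-token
lines) or are generated from pairs of terms sharing one relation, e.g.
(atropine, uveitis) and (rifampin, tuberculosis) under *may treat* give
(atropine, uveitis :: rifampin, ?) with answer tuberculosis.

By default the input terms {a, b, c} are excluded from the candidate
neighbors — without the exclusion d' is frequently nearest to b or c and
top-1 accuracy is meaningless; ``exclude_inputs=False`` restores the raw
search.  Questions with any out-of-vocabulary term are skipped and counted,
never failed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embeddings import EmbeddingMatrix, nearest_neighbors

logger = logging.getLogger(__name__)

__all__ = [
    "AnalogyQuestion",
    "AccuracyReport",
    "build_questions_from_pairs",
    "predict_vector",
    "accuracy_at_k",
    "read_questions",
    "write_questions",
]

DEFAULT_K_LIST = (1, 5, 20, 100)


@dataclass(frozen=True)
class AnalogyQuestion:
    a: str
    b: str
    c: str
    d_true: str
    group: str

    def __post_init__(self):
        if (self.a, self.b) == (self.c, self.d_true):
            raise ValueError("question pairs (a,b) and (c,d) must differ")
        if not self.group:
            raise ValueError("group must be nonempty")


@dataclass
class GroupAccuracy:
    n_questions: int
    n_skipped_oov: int
    accuracy: dict[int, float | None]

    @property
    def n_answered(self) -> int:
        return self.n_questions - self.n_skipped_oov


@dataclass
class AccuracyReport:
    """Per-group and pooled top-k accuracies.

    ``overall`` pools correct counts over answered questions (the
    question-weighted accuracy, not the mean of group accuracies).  A group
    with no answerable question reports ``None`` accuracies.
    """

    per_group: dict[str, GroupAccuracy]
    overall: GroupAccuracy
    k_list: tuple[int, ...] = field(default=DEFAULT_K_LIST)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, ga in list(self.per_group.items()) + [("overall", self.overall)]:
            for k in self.k_list:
                rows.append(
                    {
                        "group": group,
                        "k": k,
                        "n_questions": ga.n_questions,
                        "n_skipped_oov": ga.n_skipped_oov,
                        "accuracy": ga.accuracy[k],
                    }
                )
        return pd.DataFrame(rows)


def build_questions_from_pairs(
    pairs,
    group: str,
    cap: int | None = None,
    seed: int = 0,
    ordered: bool = False,
) -> list[AnalogyQuestion]:
    """Questions from all pairs-of-pairs sharing one relation.

    With ``ordered=False`` (default) each unordered pair of distinct pairs
    {p, q} yields one question (p.source, p.target :: q.source, ?), giving
    n(n-1)/2 questions from n pairs; ``ordered=True`` enumerates both
    directions, n(n-1).  When the enumeration exceeds ``cap`` a uniform
    sample of size ``cap`` is drawn without replacement with ``seed``.
    """
    pairs = list(dict.fromkeys(tuple(p) for p in pairs))
    n = len(pairs)
    if n < 2:
        warnings.warn(f"group {group!r}: fewer than 2 distinct pairs, no questions", stacklevel=2)
        return []
    if ordered:
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        mask = ii != jj
        left, right = ii[mask], jj[mask]
    else:
        left, right = np.triu_indices(n, k=1)
    total = left.size
    if cap is not None and total > cap:
        rng = np.random.default_rng(seed)
        pick = rng.choice(total, size=cap, replace=False)
        pick.sort()
        left, right = left[pick], right[pick]
    out = []
    for i, j in zip(left, right):
        p, q = pairs[i], pairs[j]
        out.append(AnalogyQuestion(p[0], p[1], q[0], q[1], group))
    return out


def predict_vector(E: EmbeddingMatrix, a: str, b: str, c: str) -> np.ndarray:
    """The analogy prediction ``c - a + b`` on raw (un-normalized) vectors."""
    return E.vector(c) - E.vector(a) + E.vector(b)


def accuracy_at_k(
    questions,
    E: EmbeddingMatrix,
    k_list=DEFAULT_K_LIST,
    exclude_inputs: bool = True,
) -> AccuracyReport:
    """Top-k accuracy of analogy questions against an embedding.

    For each answerable question the rank of the true answer among the
    neighbors of the predicted vector is computed once at ``max(k_list)``;
    the question is correct at every k >= rank.  Questions with any of the
    four terms out of vocabulary are skipped and counted; they leave the
    denominator.
    """
    k_list = tuple(k_list)
    if list(k_list) != sorted(k_list) or len(set(k_list)) != len(k_list) or k_list[0] < 1:
        raise ValueError("k_list must be ascending positive integers")
    kmax = k_list[-1]
    groups: dict[str, dict] = {}
    total = {"n": 0, "skip": 0, "correct": {k: 0 for k in k_list}}
    for q in questions:
        g = groups.setdefault(q.group, {"n": 0, "skip": 0, "correct": {k: 0 for k in k_list}})
        g["n"] += 1
        total["n"] += 1
        if any(t not in E for t in (q.a, q.b, q.c, q.d_true)):
            g["skip"] += 1
            total["skip"] += 1
            continue
        pred = predict_vector(E, q.a, q.b, q.c)
        exclude = {q.a, q.b, q.c} if exclude_inputs else frozenset()
        if np.linalg.norm(pred) == 0.0:
            # degenerate prediction (e.g. b is the zero vector); unanswerable
            g["skip"] += 1
            total["skip"] += 1
            continue
        nbrs = nearest_neighbors(E, pred, kmax, exclude=exclude)
        rank = None
        for pos, (term, _) in enumerate(nbrs.entries, start=1):
            if term == q.d_true:
                rank = pos
                break
        for k in k_list:
            if rank is not None and rank <= k:
                g["correct"][k] += 1
                total["correct"][k] += 1

    def finish(d) -> GroupAccuracy:
        answered = d["n"] - d["skip"]
        acc = {k: (d["correct"][k] / answered if answered > 0 else None) for k in k_list}
        return GroupAccuracy(d["n"], d["skip"], acc)

    per_group = {g: finish(d) for g, d in groups.items()}
    report = AccuracyReport(per_group, finish(total), k_list)
    if total["n"] > 0 and total["n"] == total["skip"]:
        logger.warning("all %d questions were out-of-vocabulary; accuracy undefined", total["n"])
    return report


def read_questions(path) -> list[AnalogyQuestion]:
    """Read the standard analogy question layout.

    Lines beginning with ``:`` start a new group (the rest of the line,
    stripped, is the group name); other nonempty lines hold exactly four
    whitespace-separated tokens a b c d.
    """
    out: list[AnalogyQuestion] = []
    group = "default"
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(":"):
                group = stripped[1:].strip() or "default"
                continue
            tokens = stripped.split()
            if len(tokens) != 4:
                raise ValueError(f"{path} line {lineno}: expected 4 tokens, got {len(tokens)}")
            out.append(AnalogyQuestion(*tokens, group=group))
    return out


def write_questions(questions, path) -> None:
    """Write questions in the standard layout (inverse of :func:`read_questions`)."""
    with open(path, "w", encoding="utf-8") as fh:
        current = None
        for q in questions:
            if q.group != current:
                fh.write(f": {q.group}\n")
                current = q.group
            fh.write(f"{q.a} {q.b} {q.c} {q.d_true}\n")
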