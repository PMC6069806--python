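"""Embedding matrices and exact cosine nearest-neighbor search.

Reads the two de-facto standard text serializations of word vectors —
word2vec text (a ``<vocab> <dim>`` header line followed by one
``token v1 ... vd`` line per word) and GloVe text (the same payload without
the header) — into an :class:`EmbeddingMatrix`, and answers top-*k* cosine
queries against it by exhaustive scan.  Every retrieval task in this package
(analogy prediction, relation-term retrieval, neighborhood visualization)
goes through :func:`nearest_neighbors`, so its contract is strict: results
equal a full-precision brute-force scan, ties at equal cosine are broken by
ascending vocabulary index, and zero-norm rows are never returned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingMatrix",
    "NeighborSet",
    "read_embedding",
    "write_embedding",
    "nearest_neighbors",
]


class EmbeddingParseError(ValueError):
    """Raised when an embedding file violates its dialect's line grammar."""


@dataclass
class NeighborSet:
    """Ranked cosine neighbors of a query vector.

    ``entries`` is sorted by non-increasing cosine score; ties share a score
    but keep ascending vocabulary-index order, so the ranking is total and
    deterministic.  ``k`` records the requested count (``len(entries)`` may
    be smaller when the admissible vocabulary is exhausted).
    """

    query_label: str
    entries: list[tuple[str, float]]
    k: int

    @property
    def terms(self) -> list[str]:
        return [t for t, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass
class EmbeddingMatrix:
    """A vocabulary with one dense real vector per term.

    Rows keep file order.  Per-row Euclidean norms and the unit-normalized
    matrix are cached at construction; rows of exactly zero norm are
    recorded in ``zero_norm_terms`` and excluded from neighbor search (a
    zero vector has no direction, hence no cosine).
    """

    terms: list[str]
    vectors: np.ndarray
    norms: np.ndarray = field(init=False, repr=False)
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.terms):
            raise ValueError("vectors must be (n_terms, dim)")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding contains non-finite entries")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("terms must be unique")
        self.index = {t: i for i, t in enumerate(self.terms)}
        self.norms = np.linalg.norm(self.vectors, axis=1)
        self._admissible = self.norms > 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            self._unit = np.where(
                self._admissible[:, None], self.vectors / np.where(self.norms == 0, 1.0, self.norms)[:, None], 0.0
            )

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def zero_norm_terms(self) -> list[str]:
        return [t for t, ok in zip(self.terms, self._admissible) if not ok]

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def vector(self, term: str) -> np.ndarray:
        """The stored (un-normalized) vector of ``term``."""
        return self.vectors[self.index[term]]

    def unit_matrix(self) -> np.ndarray:
        """Row-normalized matrix used for cosine scoring (zero rows stay zero)."""
        return self._unit


def _parse_row(line: str, lineno: int, dim: int | None) -> tuple[str, list[float]]:
    parts = line.rstrip("\n").split(" ")
    # trailing spaces produce empty fields; word2vec.c emits one
    parts = [p for p in parts if p != ""]
    if len(parts) < 2:
        raise EmbeddingParseError(f"line {lineno}: expected a token and vector components")
    token, rest = parts[0], parts[1:]
    try:
        values = [float(x) for x in rest]
    except ValueError as exc:
        raise EmbeddingParseError(f"line {lineno}: non-numeric vector component") from exc
    if dim is not None and len(values) != dim:
        raise EmbeddingParseError(
            f"line {lineno}: expected {dim} components, found {len(values)}"
        )
    return token, values


def read_embedding(path, dialect: str = "word2vec_text") -> EmbeddingMatrix:
    """Read a text-format embedding file.

    Parameters
    ----------
    path : str or Path
        File to read.
    dialect : {"word2vec_text", "glove_text"}
        ``word2vec_text`` expects a ``<vocab_size> <dim>`` header line;
        ``glove_text`` is headerless and the dimension is inferred from the
        first data line.

    Tokens are taken as-is (no case folding; knowledge-base matching handles
    casing).  A duplicate token keeps its first occurrence and logs a
    warning.
    """
    if dialect not in ("word2vec_text", "glove_text"):
        raise ValueError(f"unknown dialect {dialect!r}")
    terms: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    dim: int | None = None
    declared: int | None = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first == "":
            raise EmbeddingParseError(f"{path}: empty embedding file")
        start_lineno = 1
        if dialect == "word2vec_text":
            header = first.split()
            if len(header) != 2:
                raise EmbeddingParseError("line 1: header must be '<vocab_size> <dim>'")
            try:
                declared, dim = int(header[0]), int(header[1])
            except ValueError as exc:
                raise EmbeddingParseError("line 1: header must be two integers") from exc
            if declared <= 0 or dim <= 0:
                raise EmbeddingParseError("line 1: header integers must be positive")
        else:
            token, values = _parse_row(first, 1, None)
            dim = len(values)
            terms.append(token)
            rows.append(values)
            seen.add(token)
        for lineno, line in enumerate(fh, start=start_lineno + 1):
            if line.strip() == "":
                continue
            token, values = _parse_row(line, lineno, dim)
            if token in seen:
                logger.warning("duplicate token %r at line %d: keeping first occurrence", token, lineno)
                continue
            terms.append(token)
            rows.append(values)
            seen.add(token)
    if not rows:
        raise EmbeddingParseError(f"{path}: no vector rows")
    if declared is not None and declared != len(rows):
        logger.warning(
            "header declares %d rows but %d were read (duplicates or truncation)", declared, len(rows)
        )
    return EmbeddingMatrix(terms, np.asarray(rows, dtype=np.float64))


def write_embedding(E: EmbeddingMatrix, path, dialect: str = "word2vec_text", fmt: str = "%.8g") -> None:
    """Write ``E`` in the requested text dialect (inverse of :func:`read_embedding`)."""
    if dialect not in ("word2vec_text", "glove_text"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w", encoding="utf-8") as fh:
        if dialect == "word2vec_text":
            fh.write(f"{len(E.terms)} {E.dim}\n")
        for term, row in zip(E.terms, E.vectors):
            fh.write(term + " " + " ".join(fmt % v for v in row) + "\n")


def nearest_neighbors(
    E: EmbeddingMatrix,
    query: np.ndarray,
    k: int,
    exclude: set[str] | frozenset[str] = frozenset(),
    query_label: str = "vector",
) -> NeighborSet:
    """Top-``k`` cosine neighbors of ``query`` over the admissible vocabulary.

    Exhaustive scan: score every non-zero-norm row, drop ``exclude``,
    sort by descending cosine with ascending-vocabulary-index tie-break,
    truncate to ``k``.  If fewer than ``k`` terms are admissible all of them
    are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    q = np.asarray(query, dtype=np.float64).ravel()
    if q.shape[0] != E.dim:
        raise ValueError(f"query has dim {q.shape[0]}, embedding has dim {E.dim}")
    qn = np.linalg.norm(q)
    if qn == 0.0:
        raise ValueError("zero-norm query has no cosine neighbors")
    scores = E.unit_matrix() @ (q / qn)
    admissible = E._admissible.copy()
    for t in exclude:
        i = E.index.get(t)
        if i is not None:
            admissible[i] = False
    idx = np.nonzero(admissible)[0]
    if idx.size == 0:
        return NeighborSet(query_label, [], k)
    if idx.size < k:
        warnings.warn(
            f"k={k} exceeds admissible vocabulary ({idx.size}); returning all terms",
            stacklevel=2,
        )
    kk = min(k, idx.size)
    sub = scores[idx]
    # stable sort on negated scores keeps ascending vocab index among ties
    order = np.argsort(-sub, kind="stable")[:kk]
    chosen = idx[order]
    entries = [(E.terms[i], float(scores[i])) for i in chosen]
    return NeighborSet(query_label, entries, k)


def nearest_neighbors_of_term(E: EmbeddingMatrix, term: str, k: int, extra_exclude: set[str] = frozenset()) -> NeighborSet:
    """Neighbors of a vocabulary term, excluding the term itself."""
    if term not in E:
        raise KeyError(f"term {term!r} not in vocabulary")
    exclude = {term} | set(extra_exclude)
    return nearest_neighbors(E, E.vector(term), k, exclude=exclude, query_label=term)
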