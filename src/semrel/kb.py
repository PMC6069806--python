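"""Gold-standard semantic-relation knowledge base.

Builds a term -> relation -> set-of-relation-terms index from flat TSV
exports of UMLS-style relation triples (``source<TAB>relation<TAB>target``)
and concept-synonym groups (``concept_id<TAB>term``, CUI-style: terms
sharing a concept id are synonyms of each other).

Cleaning follows the construction rules of the evaluation dataset: terms
are lowercased, ASCII punctuation is stripped, and anything that is not a
single word afterwards is rejected.  WordNet-style inverse relations
(hypernym/hyponym, holonym/meronym) are populated in both directions from
either triple; synonym-like relations are stored symmetrically.
"""

from __future__ import annotations

import logging
import string
from collections import defaultdict
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

__all__ = [
    "clean_term",
    "RelationTriple",
    "SynonymGroups",
    "RelationKB",
    "build_kb",
    "read_relation_tsv",
    "read_synonym_tsv",
    "write_relation_tsv",
    "SYMMETRIC_RELATIONS",
    "INVERSE_RELATIONS",
]

#: Relations whose edges are undirected: b in kb[a][rel] <=> a in kb[b][rel].
SYMMETRIC_RELATIONS = frozenset({"synonym", "umls_synonym", "antonym", "sibling", "derivation"})

#: Directed relation pairs that are inverses of each other; a triple in one
#: direction also yields the inverse triple.
INVERSE_RELATIONS = {
    "hypernym": "hyponym",
    "hyponym": "hypernym",
    "holonym": "meronym",
    "meronym": "holonym",
}

_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


def clean_term(raw: str) -> str | None:
    """Normalize a knowledge-base term; return ``None`` (REJECT) if unusable.

    Lowercase, strip ASCII punctuation (removal, not space substitution),
    trim surrounding whitespace.  Rejects empty results and anything still
    containing internal whitespace (the evaluation uses unigrams only).
    """
    cleaned = raw.lower().translate(_PUNCT_TABLE).strip()
    if not cleaned or any(ch.isspace() for ch in cleaned):
        return None
    return cleaned


@dataclass(frozen=True)
class RelationTriple:
    """A directed gold relation edge ``source --relation--> target``."""

    source: str
    relation: str
    target: str


@dataclass
class SynonymGroups:
    """CUI-style synonym groups: concept_id -> set of (cleaned) terms."""

    groups: dict[str, set[str]] = field(default_factory=dict)

    def pairs(self):
        """All unordered within-group term pairs; groups of <2 terms yield none."""
        for terms in self.groups.values():
            members = sorted(terms)
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    yield a, b


class RelationKB:
    """Index of gold relation terms: ``kb[term][relation] -> set of terms``.

    The relation vocabulary is open: unknown relation names are admitted
    verbatim.  Invariant: a term is never its own relation term.
    """

    def __init__(self) -> None:
        self._index: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
        self.relation_names: list[str] = []

    def _note_relation(self, rel: str) -> None:
        if rel not in self.relation_names:
            self.relation_names.append(rel)

    def add(self, source: str, relation: str, target: str) -> None:
        """Add one directed edge; symmetric/inverse companions are added too."""
        if source == target:
            return
        self._index[source][relation].add(target)
        self._note_relation(relation)
        if relation in SYMMETRIC_RELATIONS:
            self._index[target][relation].add(source)
        inv = INVERSE_RELATIONS.get(relation)
        if inv is not None:
            self._index[target][inv].add(source)
            self._note_relation(inv)

    def relation_terms(self, term: str, relation: str) -> set[str]:
        """Gold relation terms of ``term`` under ``relation`` (empty set if none)."""
        return set(self._index.get(term, {}).get(relation, set()))

    def relations_of(self, term: str) -> dict[str, set[str]]:
        return {rel: set(ts) for rel, ts in self._index.get(term, {}).items() if ts}

    def __contains__(self, term: str) -> bool:
        return any(ts for ts in self._index.get(term, {}).values())

    def __getitem__(self, term: str) -> dict[str, set[str]]:
        return self.relations_of(term)

    @property
    def terms(self) -> list[str]:
        return sorted(t for t in self._index if t in self)

    def triples(self) -> list[RelationTriple]:
        out = []
        for s in sorted(self._index):
            for rel in sorted(self._index[s]):
                for t in sorted(self._index[s][rel]):
                    out.append(RelationTriple(s, rel, t))
        return out


def build_kb(
    triples,
    syn_groups: SynonymGroups | None = None,
    bidirectional: bool = False,
) -> RelationKB:
    """Build the relation index from cleaned triples and synonym groups.

    Synonym groups expand to all unordered within-group pairs under the
    relation name ``umls_synonym``.  With ``bidirectional=True`` every
    directed triple is additionally indexed target -> source under the same
    relation name (for relations with no declared inverse).
    """
    kb = RelationKB()
    for tr in triples:
        kb.add(tr.source, tr.relation, tr.target)
        if (
            bidirectional
            and tr.relation not in SYMMETRIC_RELATIONS
            and tr.relation not in INVERSE_RELATIONS
        ):
            kb.add(tr.target, tr.relation, tr.source)
    if syn_groups is not None:
        for a, b in syn_groups.pairs():
            kb.add(a, "umls_synonym", b)
    return kb


def read_relation_tsv(path) -> tuple[list[RelationTriple], dict[str, int]]:
    """Read ``source<TAB>relation<TAB>target`` rows, cleaning both endpoints.

    Returns the deduplicated triples plus a load report with ``kept`` /
    ``dropped_cleaning`` / ``dropped_malformed`` counts.  Rows whose source
    or target fails :func:`clean_term` are dropped; duplicates collapse.
    """
    triples: list[RelationTriple] = []
    seen: set[RelationTriple] = set()
    report = {"kept": 0, "dropped_cleaning": 0, "dropped_malformed": 0}
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            n_rows += 1
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                logger.warning("%s line %d: expected 3 columns, got %d", path, lineno, len(parts))
                report["dropped_malformed"] += 1
                continue
            s, rel, t = clean_term(parts[0]), parts[1].strip(), clean_term(parts[2])
            if s is None or t is None or not rel:
                report["dropped_cleaning"] += 1
                continue
            tr = RelationTriple(s, rel, t)
            if tr in seen:
                continue
            seen.add(tr)
            triples.append(tr)
            report["kept"] += 1
    if n_rows == 0:
        raise ValueError(f"{path}: empty relation file")
    logger.info("%s: kept %d triples, dropped %d", path, report["kept"], n_rows - report["kept"])
    return triples, report


def read_synonym_tsv(path) -> tuple[SynonymGroups, dict[str, int]]:
    """Read ``concept_id<TAB>term`` rows into :class:`SynonymGroups`."""
    groups: dict[str, set[str]] = defaultdict(set)
    report = {"kept": 0, "dropped_cleaning": 0, "dropped_malformed": 0}
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            n_rows += 1
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                logger.warning("%s line %d: expected 2 columns, got %d", path, lineno, len(parts))
                report["dropped_malformed"] += 1
                continue
            cui, term = parts[0].strip(), clean_term(parts[1])
            if not cui or term is None:
                report["dropped_cleaning"] += 1
                continue
            groups[cui].add(term)
            report["kept"] += 1
    if n_rows == 0:
        raise ValueError(f"{path}: empty synonym file")
    return SynonymGroups(dict(groups)), report


def write_relation_tsv(kb: RelationKB, path) -> None:
    """Serialize a KB as a triple TSV (round-trips through read + build)."""
    with open(path, "w", encoding="utf-8") as fh:
        for tr in kb.triples():
            fh.write(f"{tr.source}\t{tr.relation}\t{tr.target}\n")
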