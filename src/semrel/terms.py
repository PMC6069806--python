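"""Evaluation-term construction: candidate filtering and KB matching.

Candidate terms (n-grams with corpus frequencies and per-word POS labels)
are filtered by five rules — at most four words, corpus frequency >= 100,
no leading/trailing stop word, unigrams must be a noun/adjective/gerund,
multi-grams must end in a noun or gerund — and the survivors are kept only
if the knowledge base holds at least one nonempty relation set for them.
POS is consumed as an input annotation with the coarse labels ``noun``,
``adjective``, ``gerund``, ``other`` (a tagger's VBG maps to ``gerund``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .kb import RelationKB
from .stopwords import DEFAULT_STOPWORDS

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateTerm",
    "EvalTermSet",
    "filter_candidates",
    "match_to_kb",
    "read_candidate_tsv",
    "POS_LABELS",
    "UNIGRAM_POS",
    "TAIL_POS",
]

POS_LABELS = frozenset({"noun", "adjective", "gerund", "other"})
UNIGRAM_POS = frozenset({"noun", "adjective", "gerund"})
TAIL_POS = frozenset({"noun", "gerund"})

#: Filter-stage names, in reporting order.
FILTER_STAGES = (
    "too_many_words",
    "low_frequency",
    "stopword_boundary",
    "unigram_pos",
    "multigram_tail_pos",
    "missing_pos",
)


@dataclass(frozen=True)
class CandidateTerm:
    """An n-gram candidate with its corpus frequency and per-word POS labels."""

    text: str
    frequency: int
    pos_tags: tuple[str, ...]

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(self.text.split())

    @property
    def word_count(self) -> int:
        return len(self.words)


@dataclass
class EvalTermSet:
    """Filtered evaluation terms with their gold relation sets.

    ``gold[term][relation]`` is the set of gold relation terms; every kept
    term has at least one nonempty relation set.  ``provenance`` carries the
    non-increasing survivor counts of the construction stages.
    """

    terms: list[str]
    gold: dict[str, dict[str, set[str]]]
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def relations(self) -> list[str]:
        rels: set[str] = set()
        for by_rel in self.gold.values():
            rels.update(r for r, ts in by_rel.items() if ts)
        return sorted(rels)

    def terms_with(self, relation: str) -> list[str]:
        return [t for t in self.terms if self.gold.get(t, {}).get(relation)]


def filter_candidates(
    cands: list[CandidateTerm],
    stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
    min_freq: int = 100,
    max_words: int = 4,
) -> tuple[list[CandidateTerm], dict[str, int]]:
    """Apply the five noise filters; return survivors and a per-rule report.

    The rules are a conjunction, so the outcome is order-independent; the
    report attributes each rejected term to the first failing rule in the
    stated order.  A candidate whose POS annotation does not cover every
    word is rejected under the distinct ``missing_pos`` category.
    """
    report = {stage: 0 for stage in FILTER_STAGES}
    kept: list[CandidateTerm] = []
    stops = {s.lower() for s in stopwords}
    for c in cands:
        words = c.words
        if len(words) != len(c.pos_tags):
            report["missing_pos"] += 1
            continue
        if c.word_count > max_words:
            report["too_many_words"] += 1
            continue
        if c.frequency < min_freq:
            report["low_frequency"] += 1
            continue
        if words[0].lower() in stops or words[-1].lower() in stops:
            report["stopword_boundary"] += 1
            continue
        if c.word_count == 1:
            if c.pos_tags[0] not in UNIGRAM_POS:
                report["unigram_pos"] += 1
                continue
        else:
            if c.pos_tags[-1] not in TAIL_POS:
                report["multigram_tail_pos"] += 1
                continue
        kept.append(c)
    return kept, report


def match_to_kb(
    cands: list[CandidateTerm],
    kb: RelationKB,
    join: str = "_",
) -> EvalTermSet:
    """Keep candidates with at least one nonempty KB relation set.

    Multi-word candidates are looked up by their words joined with ``join``
    (the convention under which phrases enter embedding vocabularies).
    Gold sets are attached as a restricted view of the KB.
    """
    terms: list[str] = []
    gold: dict[str, dict[str, set[str]]] = {}
    for c in cands:
        key = join.join(c.words) if c.word_count > 1 else c.text
        by_rel = kb.relations_of(key)
        if not by_rel:
            continue
        if key not in gold:
            terms.append(key)
            gold[key] = by_rel
    if not terms:
        logger.warning("no candidate matched the knowledge base")
    return EvalTermSet(
        terms=terms,
        gold=gold,
        provenance={"candidates": len(cands), "matched": len(terms)},
    )


def read_candidate_tsv(path) -> list[CandidateTerm]:
    """Read ``term<TAB>frequency<TAB>pos1,pos2,...`` rows."""
    out: list[CandidateTerm] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                logger.warning("%s line %d: expected 3 columns", path, lineno)
                continue
            text, freq_s, pos_s = parts
            try:
                freq = int(freq_s)
            except ValueError:
                logger.warning("%s line %d: non-integer frequency", path, lineno)
                continue
            pos = tuple(p.strip() for p in pos_s.split(",") if p.strip())
            out.append(CandidateTerm(text.strip(), freq, pos))
    return out
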