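# semrel

**semrel** quantifies how semantic relations — general lexical relations
(synonym, antonym, hypernym/hyponym, holonym/meronym, sibling,
derivationally related form, pertainym) and biomedical relations
(*may treat*, *has finding site*, *has ingredient*, ...) — are represented
in word-embedding vector spaces. It is aimed at text-mining and medical
informatics practitioners who want to know, before wiring an embedding
into a downstream model, whether the neighbors of a term in that embedding
actually carry the relations their application depends on.

The package evaluates an embedding against knowledge-base gold standards
(UMLS-style relation triples and CUI synonym groups, WordNet-style relation
exports) on two retrieval tasks, and ships a synthetic generator that
plants both kinds of structure with analytically known answers, so every
metric can be validated end to end without any external data.

## The two tasks

**Analogy term retrieval.** A question (a, b :: c, ?) with answer d is
scored by predicting

    d' = c − a + b

in vector space and asking whether d is among the top-k cosine neighbors
of d' (k ∈ {1, 5, 20, 100} by default; the inputs a, b, c are excluded
from the candidates). Accuracy is reported per question group and pooled.
Medical analogy questions are generated from pairs of terms sharing one
UMLS relation — (atropine, uveitis) and (rifampin, tuberculosis) both
carry *may treat*, giving (atropine, uveitis :: rifampin, ?) — capped at
10,000 questions per relation by seeded uniform sampling.

**Relation term retrieval.** For an evaluation term e with gold relation
terms e.rel, let N_e be its top-k cosine neighbors (e itself excluded):

    hit(e, rel) = 1  iff  N_e ∩ e.rel ≠ ∅
    RR(rel)     = Σ_e hit(e, rel) / |{e : e.rel ≠ ∅}|

    weight(e, rel, n) = n / min(k, |e.rel|)
    WRR(rel)          = Σ_e weight(e, rel, n_e) / |{e : e.rel ≠ ∅}|

The retrieved ratio RR is the probability that at least one gold relation
term occurs among a term's nearest neighbors; the weighted retrieved ratio
WRR discounts relations with many gold terms by scoring, per term, the
retrieved count n_e against the best achievable at this k. WRR ≤ RR
always, and both are non-decreasing in k.

Evaluation terms are built the way the gold standard prescribes: n-gram
candidates are filtered (≤ 4 words, corpus frequency ≥ 100, no
leading/trailing stop word, unigrams must be noun/adjective/gerund,
multi-grams must end in a noun or gerund) and kept only if the knowledge
base holds at least one nonempty relation set for them.

## Worked example

Plant noisy analogy structure and partially-retrievable relation
structure, then evaluate both:

```python
from semrel import (PlantedSpec, make_analogy_fixture, make_relation_fixture,
                    accuracy_at_k, evaluate_all)

spec = PlantedSpec(noise_sd=0.8, seed=42)
E, questions = make_analogy_fixture(spec)
print(accuracy_at_k(questions, E, (1, 5, 20)).to_frame().to_string(index=False))

half = spec.with_(terms_per_relation=10, retrievable_fraction=0.5, dim=48)
E2, kb, evals = make_relation_fixture(half)
print(evaluate_all(evals, E2, (1, 5, 20)).to_string(index=False))
```

The analogy table ends with:

```
overall  1          180              0  0.155556
overall  5          180              0  0.594444
overall 20          180              0  0.972222
```

Per-coordinate noise of 0.8 on the planted offsets breaks exact
parallelogram closure, so top-1 accuracy drops to 0.16 — but the true
answer is almost always *near* the predicted vector, so accuracy recovers
to 0.97 by k = 20. The relation table at k = 20 reads:

```
    rel0 20       4      0 1.0  0.5
    rel1 20       4      0 1.0  0.5
    rel2 20       4      0 1.0  0.5
 average 20      12      0 1.0  0.5
```

Each evaluation term has 10 gold relation terms of which 5 are in the
vocabulary, all planted nearest: some gold term is always retrieved
(RR = 1.0), and the weight n/min(k, |e.rel|) = 5/10 makes WRR exactly 0.5
— the metric sees that half of each gold set is unreachable.

The same workflows are available from the shell:

```bash
semrel simulate --out-dir fixtures --seed 42
semrel eval-analogy --emb fixtures/analogy_embedding.w2v.txt \
    --questions fixtures/questions.txt -k 1,5,20 --out accuracy.tsv
semrel eval-relations --emb fixtures/relation_embedding.w2v.txt \
    --kb fixtures/relations.tsv --terms fixtures/eval_terms.txt -k 1,5,20
semrel neighbors --emb fixtures/relation_embedding.w2v.txt --term r0e0 -k 5
semrel viz --emb fixtures/relation_embedding.w2v.txt --term r0e0 -k 10 \
    --kb fixtures/relations.tsv --coords coords.tsv --out plot.svg
```

Embeddings are read in word2vec text format (`<vocab> <dim>` header) or
GloVe text format (headerless); relation KBs from
`source<TAB>relation<TAB>target` TSVs plus `concept_id<TAB>term` synonym
TSVs.

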