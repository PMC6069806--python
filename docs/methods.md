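# Methods

## The evaluation model

semrel treats a trained word embedding as a retrieval system over its own
vocabulary and asks how well cosine neighborhoods reproduce known semantic
relations. Two probes are implemented.

The **analogy probe** assumes the classic vector-offset model of relational
structure: if pairs (a, b) and (c, d) instantiate the same relation, then
b − a ≈ d − c, so d can be predicted as d' = c − a + b and retrieved by
cosine nearest-neighbor search around d'. A question is correct at k when
the true d is among the top-k neighbors of d'. The input terms {a, b, c}
are excluded from the candidate set by default: d' = c − a + b is
frequently nearest to b or c themselves, and without the exclusion top-1
accuracy measures mostly that artifact. A flag restores the unexcluded
search for comparison with protocols that do not state an exclusion.
Accuracy is reported per question group and pooled over answered
questions (the pooled figure is question-weighted, not a mean of group
accuracies). Questions with any out-of-vocabulary term are skipped and
counted; they leave the denominator rather than scoring as wrong, since
they measure vocabulary coverage, not geometry.

The **relation-term probe** scores, for each evaluation term e with a
nonempty gold set e.rel under relation rel, whether gold terms appear in
its top-k cosine neighborhood N_e (e itself excluded — retrieving the
query is vacuous):

    hit(e, rel) = [N_e ∩ e.rel ≠ ∅]
    RR(rel)     = mean of hit over evaluable terms
    weight(e, rel, n) = n / min(k, |e.rel|)
    WRR(rel)    = mean of weight over evaluable terms

The weight's denominator min(k, |e.rel|) is the number of gold terms that
could possibly be retrieved at this k, so in the default `count` mode
(n = |N_e ∩ e.rel|) the weight is the recall against the best achievable.
An `indicator` mode (n = hit ∈ {0, 1}) is selectable; both keep every
summand ≤ the corresponding hit, hence WRR ≤ RR identically. Per-relation
rows are complemented by an `average` row, the unweighted mean over
evaluable relations, so relations with few terms are not swamped.

Denominator policy: evaluation terms missing from the vocabulary (or with
a zero-norm vector) leave both numerator and denominator and are reported
as `n_oov`. Gold terms missing from the vocabulary still count in |e.rel|
by default — an embedding is legitimately penalized for not containing
retrievable synonyms only when k exceeds what it holds; a
`in_vocab_gold_only` flag restricts |e.rel| to in-vocabulary terms.

## Nearest-neighbor search

Search is an exact exhaustive cosine scan over unit-normalized cached
rows. Zero-norm rows have no direction and are excluded from search (and
recorded). Ties at equal cosine break by ascending vocabulary index, which
makes rankings total, reproducible, and prefix-stable in k. The numerical
contract — agreement with a full-precision brute-force scan to 1e-6 — is
enforced by oracle tests over repeated random fixtures.

## Knowledge-base construction

Gold relations are consumed as flat TSV exports: triples
(source, relation, target) and CUI-style synonym groups. Terms are
lowercased, stripped of ASCII punctuation (removal, not
space-substitution — multi-word results are rejected next anyway), and
discarded unless a single nonempty word remains; rows failing cleaning are
dropped and counted. Synonym groups expand to all unordered within-group
pairs under `umls_synonym`. Relations declared symmetric (synonym,
umls_synonym, antonym, sibling, derivation) are stored in both directions;
hypernym/hyponym and holonym/meronym are inverse-paired, so a triple in
either direction populates both. Other relation names are open-vocabulary
and directed; a `bidirectional` option additionally indexes
target → source for them, since relation exports do not always fix a
direction convention. No term is ever its own relation term.

## Evaluation-term selection

Candidates arrive as n-grams with corpus frequencies and coarse per-word
POS labels (`noun`, `adjective`, `gerund`, `other`; a tagger's VBG maps to
gerund — POS is an input annotation, produced by whatever tagger the user
trusts). Five conjunctive filters apply: word count ≤ 4; frequency ≥ 100
(the threshold applies to the joined multi-gram); first and last word not
a stop word (a standard ~150-word English list is bundled and
replaceable); unigrams must be noun/adjective/gerund; multi-grams must end
in a noun or gerund. The stage report attributes each rejection to the
first failing rule in that order, but the outcome is order-independent.
Survivors are kept as evaluation terms iff the KB has a nonempty relation
set for them; multi-word survivors are looked up with underscores joining
their words, the convention under which phrases enter embedding
vocabularies, and only terms present in the embedding vocabulary reach
retrieval.

## Synthetic fixtures

The generator plants the exact structure each probe assumes, so metric
values are known in closed form and every pipeline stage can be verified
without external data.

*Analogy fixture*: each group g draws a shared offset o_g with norm
`offset_norm` (default 4, dominating the unit-norm base vectors); pairs
(s_i, t_i = s_i + o_g + ε), ε ~ N(0, noise_sd²·I) per coordinate.
At noise_sd = 0 the parallelogram closes exactly and top-1 accuracy is
1.0; at noise_sd ≫ offset_norm accuracy is statistically at the chance
level 1/(V−3), which the tests check over 20 pooled seeds with a binomial
bound. Defaults (dim 32, 4 groups × 10 pairs, 50 distractors) keep each
run well under a second.

*Relation fixture*: each evaluation term's retrievable gold terms are
placed at cosine exactly `neighbor_cosine` (default 0.95) via a random
orthogonal component; evaluation terms, foreign gold directions and
distractors are rejection-sampled under pairwise-cosine ceilings (0.2
between planted directions, `neighbor_cosine − 0.3` for distractors), so
everything non-gold stays strictly below the gold ring and the top-m
neighbors of each term are exactly its m planted gold terms. Closed forms
follow: RR = 1 at every k; WRR = min(k, m)/min(k, |e.rel|) in count mode.
`retrievable_fraction < 1` leaves the remaining gold terms out of the
vocabulary — they count in |e.rel| but can never be retrieved, making the
weight's discount exact (5 of 10 retrievable at k ≥ 10 gives WRR = 0.5).
Rejection sampling is bounded (500 attempts per vector); exhaustion raises
an error naming the violated cosine constraint, which is how geometrically
infeasible requests (e.g. many mutually-separated directions in 2
dimensions, or `neighbor_cosine < 0.5`, where planted gold could not
dominate the distractor ceiling) surface.

What the fixtures do **not** emulate: Zipfian token frequencies, the
anisotropy and hubness of trained embedding spaces, polysemy, phrase
composition, and correlated noise between related terms. Passing planted
tests therefore validates the correctness of the metrics and search — not
any claim about how real corpora distribute relations in real embeddings.

## Published-composition arithmetic

The module `semrel.datasets` carries the published composition counts of
the study datasets (corpus size, analogy groups, medical relation pair
counts, evaluation-term coverage per relation) and recomputes every
derived column — totals, percentages, words per article, and the capped
medical question counts, the last by actually generating the question
sets. Recomputed values are compared against the published ones and
inconsistencies are flagged rather than reproduced: the capital-common
percentage prints as 5.24% upstream but 506/9331 = 5.42%, and the medical
question rows sum to 33,580 against a printed grand total of 33,585. The
published per-relation "average relation terms" column and the relation-
term grand total do not reproduce from their own printed rows and are
therefore not asserted anywhere.

The medical analogy enumeration is over unordered pairs of gold pairs —
n(n−1)/2 questions from n pairs, which is what the published per-relation
question counts (903 from 43, 1,596 from 57, 1,081 from 47) correspond to;
an ordered n(n−1) enumeration is available as an option. Capping is
uniform sampling without replacement at 10,000 questions per relation,
seeded.

## Visualization

A term's neighborhood is projected by PCA fitted on the k+1 selected
vectors only (the local view; a global-fit option exists), with component
signs fixed by making each component's largest-magnitude loading positive
so coordinates are bit-for-bit reproducible. Original-space rank is
encoded as marker size and KB relation types as marker symbols; a
coordinates TSV is always produced so nothing downstream parses images.
t-SNE is deliberately not offered: it is non-deterministic and does not
preserve the linear offset structure the analogy probe is about.

## Numerical and reporting choices

All vectors are float64; cosine scores match brute force to 1e-6.
Duplicate embedding tokens keep the first occurrence with a warning.
CLI reports are TSV with `#` header lines carrying the tool version, seed
and a configuration hash (input paths reduced to basenames), so identical
configurations re-run byte-identically. Every stochastic step — question
capping, fixture generation — flows from a single integer seed.

## Limitations

Exact search is O(V·d) per query and intended for evaluation-scale
vocabularies (up to a few hundred thousand terms), not for serving.
Only unigram retrieval is supported; multi-word evaluation terms
participate solely via their joined form. The binary word2vec format is
not read — text dialects only. RR/WRR compare embeddings descriptively;
no significance test between embeddings is provided.
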