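# Methods

## The statistic

The analysis conditions everything on *seed sentences*: sentences
containing at least one seed lemma after lowercasing, Unicode-NFC
normalization, lemmatization and surface-form pooling.  For a lemma ℓ
the reported quantity is the conditional sentence frequency

    freq(ℓ) = |{seed sentences containing ℓ}| / |{seed sentences}|,

a value in (0, 1].  The denominator is the number of seed-containing
sentences — not all sentences and not documents — because that is the
only reading under which the upper bound 1.0 is attainable (a lemma
present in every seed sentence) and under which the statistic is a
probability of co-mention given a mention.  Within a sentence, lemma
multiplicity is collapsed to presence/absence: the unit of counting is
the sentence, not the token pair.  Counts are integers divided only at
presentation time, so equal counts compare exactly equal and row
ordering is stable.

Pairwise counts `pair_counts[(a,b)]` — the number of seed sentences
containing both `a` and `b` — are computed over seed sentences only,
including pairs involving the seed lemmas themselves.  A
whole-corpus (unconditioned) variant was considered and rejected as a
default: the object of study is the neighbourhood of the seed terms,
not the corpus-wide collocation structure.

Lemmas never observed in a seed sentence are stored nowhere.  An
exporter rendering a fixed row list (a figure-style table) represents
them as crossed cells; the in-memory table simply omits them, which
keeps the invariant 0 < freq ≤ 1 for every stored entry.

## Preprocessing

**Descriptor filter.**  A document is retained iff it contains at
least one of the 15 pandemic descriptor terms as a case-insensitive
*whole token*.  Tokens are maximal runs of word characters with
internal hyphens kept, so `covid-19` is one token that matches the
descriptor `covid-19`, while the compound `Pandemiebekämpfung` does
not match `pandemie`.  Whole-token semantics is deliberate: the
descriptor list contains both `corona` and `coronavirus`, which would
be redundant under substring matching.

**Sentence segmentation.**  Terminators `.`, `!`, `?` followed by
whitespace split; a per-run abbreviation list (`Dr.`, `z.B.`, `Mme.`,
...) suppresses false splits; newlines always split because social
posts frequently separate statements by line breaks without terminal
punctuation.  The segmenter never drops non-whitespace characters.

**Lemmatization.**  The backend interface demands determinism and
non-empty lemmas; the shipped `RuleLemmatizer` combines an exact
dictionary with regular German noun-plural suffix reductions
(`-ionen→-ion`, `-ungen→-ung`, `-heiten→-heit`, `-keiten→-keit`,
`-schaften→-schaft`, `-täten→-tät`, `-ien→-ie`), guarded by a minimum
stem length of 3.  Every replacement is a fixed point of the rule
table, so the backend is idempotent — a property the tests assert.
This rule backend is the default because it makes every run (and the
test suite) reproducible with no model downloads; a statistical NLP
backend can be plugged in by subclassing `LemmatizerBackend` where
higher recall on irregular morphology matters more than bit-level
reproducibility.  Hyphenated compounds are kept as single lemmas
(`corona-impfung`), matching how such compounds function as single
content terms.

**Stopwords.**  Default policy `builtin` removes small per-language
function-word lists (articles, pronouns, auxiliaries); the published
frequency tables of this kind of analysis show content lemmas only.
Seed lemmas are never removed regardless of policy.

## Network and clustering

Nodes are the observed seed lemmas (size fixed at 1.0 — a seed is in
every seed sentence by construction) plus every lemma with
freq ≥ `min_node_freq`; edges are pairs with
pair count ≥ `min_edge_count` (default 1).  Non-seed nodes left
isolated are dropped; a network with no surviving edge is an error
rather than an empty result.

Cluster quality is the resolution-scaled Newman–Girvan modularity

    Q_γ = Σ_c [ W_c / W − γ (S_c / 2W)² ]

with W the total edge weight, W_c the intra-community weight, S_c the
summed weighted degree of community c, and γ the resolution parameter
(default **0.5**, favouring broad thematic groupings).  Edge weights
enter as weights, not binarized, because edge strength (number of
shared sentences) is meaningful; an unweighted mode exists behind a
flag for sensitivity analysis.  One community gives Q = 1 − γ; γ → 0
merges any connected graph into one community; both are asserted.

The optimizer is a from-scratch two-phase Louvain: greedy local moves
in a seeded-shuffled node order until no move improves Q_γ, then
aggregation of communities into super-nodes with self-loops, repeated
until stable.  Because single-run greedy Louvain is order-dependent
and can stall in a local optimum (a 6-node path at γ = 0.5 is a
minimal example), the optimizer is **multi-start**: 10 restarts whose
visiting orders are drawn sequentially from one generator seeded with
`rng_seed`, keeping the highest-Q_γ partition (first found wins
ties).  The run therefore remains a pure function of the seed.  On
every battery graph with ≤ 8 nodes the returned Q_γ equals the global
optimum found by enumerating all set partitions (≤ 4,140 for n = 8).

Numerical choices: move gains are compared on the scale
ΔQ · 2m² = 2m·k_{i,c} − γ·S_c·k_i, which is exact for integer edge
weights, so tie-breaking (keep the current community on a tie,
otherwise lowest community id) never depends on float round-off.
Final community ids are densified in order of first appearance over
lexicographically sorted node names.  Test comparisons against the
independent networkx modularity oracle use absolute tolerance 1e-12.

Cluster prominence is operationalized as node count (descending), with
ties broken by total node size then by smallest member lemma — "largest
first" made total and deterministic.

## Export

GEXF 1.3, undirected, weighted, with node attributes `size` (double)
and `modularity_class` (long).  The writer is canonical — sorted
nodes and edges, shortest round-trip number formatting, no
timestamps — so identical inputs yield byte-identical files, and
`read_gexf` reproduces nodes, edges, weights and attributes exactly.
Layout is delegated to external visualization tools.  CSV exports
(frequency table, pair counts, cluster report) are likewise fully
ordered.

## Synthetic corpora

The generator emulates the statistical skeleton assumed of a
keyword-retrieved discourse corpus: documents of 3–8 sentences; one
hard topic per document drawn uniformly from k = 3 topics; each
sentence a seed sentence with p = 0.3; a seed sentence carries one
seed lemma (alternating deterministically between the two seeds, which
exercises the pooled-seed logic), each of the 10 active-topic lemmas
independently with p = 0.8, and each of 50 background lemmas with
p = 0.02; non-seed sentences draw background lemmas only; a document
carries the descriptor token `covid` with p = 0.9.  Defaults
(n_docs = 500) describe a well-separated regime in which topic lemmas
form near-cliques through their shared seed sentences while
cross-topic lemma pairs co-occur only through background noise.  The
per-topic expected frequency of a topic lemma is p_topic_lemma times
its topic's realized share of seed sentences; the generator reports
exactly this as ground truth, making the frequency-consistency checks
pure binomial statements.

What the generator does **not** emulate: natural-language syntax and
morphology (lemmas are pre-generated tokens; an `inflect` mode appends
a regular plural suffix to exercise the rule lemmatizer), word
burstiness and document-length heavy tails, code-switching, soft or
mixed topic membership, and any platform metadata beyond the required
fields.  Passing recovery tests therefore show that the pipeline
recovers planted sentence-level co-occurrence structure; they do not
certify performance on real multilingual text, where segmentation and
lemmatization noise dominate.

Recovery is scored by the adjusted Rand index between planted lemma
topics and recovered modularity classes, restricted to planted lemmas
present in the network; with the defaults above, ARI ≥ 0.9 in at
least 4 of 5 seeded runs (observed: 5 of 5 with ARI 1.0).

## Problem sizes

The shipped checks use 100 random corpora of ≤ 50 sentences over ≤ 20
lemmas for oracle equivalence, graph batteries of ≤ 8 nodes for
exhaustive optimality, and five n_docs = 500 pipeline runs for planted
recovery — sizes at which the naive oracles (double loops, Bell-number
enumeration, pair-counting ARI) are exact and fast, which is what
makes them trustworthy as references.

## Known limitations

- The rule lemmatizer only handles regular suffix patterns; irregular
  German plurals and all French/Italian morphology pass through
  unchanged unless added to the dictionary.
- Sentence segmentation is rule-based; creative punctuation (ellipses,
  emoji terminators) may merge or split sentences unexpectedly.
- Language handling of mixed corpora is left to `language_filter`
  policy; no machine translation is attempted, so per-language lemma
  spaces do not merge except through the explicit seed surface-form
  map.
- Louvain with a resolution parameter has the usual resolution-limit
  caveats; the multi-start optimizer is exact only on graphs small
  enough to verify exhaustively.
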