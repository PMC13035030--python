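# seednet

Seed-term sentence co-occurrence networks for discourse corpora.

`seednet` answers a recurring question in infodemiology and
computational health-communication research: **when a public discourse
corpus mentions a focal concept — here the German lemmas
*Fehlinformation* ("misinformation") and *Desinformation*
("disinformation") — which terms surround it, and how do those terms
organize into themes?**  It is aimed at researchers analyzing exports
of news databases or social-media monitoring tools (one row per
article or post), in German, French, Italian or English.

## Method

The pipeline implements, as tested reusable code, a standard
keyword-conditioned co-occurrence analysis:

1. **Descriptor filtering.** Documents not containing at least one of
   15 pandemic descriptor tokens (`covid`, `corona`, `virus`,
   `covid-19`, `coronavirus`, `pandemic`, `epidemic`, `outbreak`,
   `pandémie`, `épidémie`, `pandemie`, `epidemie`, `seuche`,
   `pandemia`, `epidemia`) are removed.  Matching is whole-token and
   case-insensitive; hyphenated tokens stay whole, so `Corona-Kurs`
   does **not** match `corona`.
2. **Sentence segmentation and lemmatization.**  The co-occurrence
   window is the sentence.  A pluggable lemmatizer reduces tokens to
   base forms; the shipped backend is a deterministic dictionary +
   suffix-rule reducer.  Foreign surface forms (`misinformation`,
   `désinformation`, `disinformazione`, ...) are pooled onto the seed
   lemmas.
3. **Conditional co-occurrence frequency.**  For each lemma ℓ,

   freq(ℓ) = #(seed sentences containing ℓ) / #(seed sentences) ∈ (0, 1],

   where a *seed sentence* contains at least one seed lemma.  Lemmas
   that never share a sentence with a seed are absent ("crossed
   cells").  Pairwise sentence co-occurrence counts over the seed
   sentences become edge weights.
4. **Semantic network and modularity classes.**  Nodes are lemmas
   (size = frequency; seeds have size 1), edges are co-occurrence
   counts.  Thematic clusters maximize the resolution-scaled
   Newman–Girvan modularity

   Q_γ = Σ_c [ W_c / W − γ (S_c / 2W)² ],

   optimized by a from-scratch, seeded, multi-start Louvain algorithm
   (default resolution γ = 0.5 for coarse thematic groupings).  The
   network is exported as GEXF 1.3 for external visualization.

A synthetic-corpus generator with planted topics and known ground
truth (`seednet.synthetic`) makes every stage verifiable end-to-end:
recovered modularity classes can be scored against planted topics by
adjusted Rand index.

## Worked example

```bash
seednet simulate --seed 11 --n-docs 200 --out-corpus demo.csv
seednet analyze demo.csv --outdir demo_out --seed 11
```

The second command prints the top co-occurring lemmas to stdout (stage
counts go to stderr):

```
t0wort6ung	0.3110
t0wort4ung	0.3074
t0wort7ung	0.3004
...
```

Each line is a lemma and its conditional frequency: `t0wort6ung`
(a planted topic-0 lemma) appeared in 31.1% of the 283 seed sentences.
Because the generator assigns each document one of 3 topics uniformly
and plants topic lemmas in seed sentences with probability 0.8, the
expected frequency per topic lemma is ≈ 0.8/3 ≈ 0.27 — the printed
values scatter around that.  `demo_out/` then contains
`frequencies.csv`, `pairs.csv`, `network.gexf`, `clusters.csv` and
`run_metadata.json`.  The cluster report recovers the three planted
topics exactly:

```
cluster_id,rank,n_nodes,total_size,members
0,1,36,5.607...,desinformation;fehlinformation;t0wort6ung;...
1,2,24,2.780...,t1wort4ung;t1wort9ung;...
2,3,23,2.579...,t2wort0ung;t2wort2ung;...
```

Re-running either command with the same `--seed` reproduces every
output byte for byte.

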