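# termscout

Colloquial search-term discovery and precision-controlled retrieval
evaluation for social-media health content.

Health-content retrieval that relies only on technical medical queries
("colonoscopy") misses user-generated videos phrased in layperson or brand
vocabulary ("suprep", "miralax"). `termscout` implements the full
evaluation pipeline around that problem:

1. **Normalize** video titles + descriptions (lowercase, ASCII fold,
   emoji/punctuation stripping, stopword removal).
2. **Embed**: train word2vec (CBOW or skip-gram with negative sampling,
   implemented in-house on numpy, fully deterministic under a single seed)
   on the normalized corpus and rank nearest-neighbor terms to a focal
   term by cosine similarity.
3. **Recall evaluation**: per-neighbor-term retrieval statistics — how
   many coded expansion videos are relevant, and how many relevant ones
   omit the focal term (the recall improvement).
4. **Corpus comparison**: grouped document-feature matrices, Euclidean
   set-distance matrices, Yates-corrected chi-square keyness, and
   complete-linkage hierarchical clustering (Newick output).
5. **Precision evaluation**: exclusion filtering (non-English,
   duplicate-of-core, missing metadata), in/out/total degree of each
   expansion video against the core set in the relatedness graph, and the
   cumulative precision / recall / F1 curve over descending total-degree
   thresholds.
6. **Synthetic corpora**: a seeded generator of platform-like corpora
   (topic-mixture text, relatedness edges, relevance labels, planted
   duplicates/non-English/missing-metadata videos) so every stage is
   testable offline.

## CLI

One top-level command with per-stage subcommands; every stage writes a
JSON run manifest (config snapshot, seed, input digests, outputs).

```sh
# generate a synthetic corpus + edge list
termscout simulate --seed 42 --n-core 60 --n-per-term 30 --out-dir run/

# train embeddings and rank neighbor terms
termscout embed run/corpus.jsonl --focal-term colonoscopy --seed 42 --out-dir run/
termscout neighbors run/embeddings.txt --focal-term colonoscopy --k 6 --out-dir run/

# recall-improvement report over the coded expansion sample
termscout recall run/corpus.jsonl --focal-term colonoscopy --out-dir run/

# set distances, keyness table, dendrogram
termscout compare run/corpus.jsonl --focal-term colonoscopy --out-dir run/

# degree-threshold precision/recall/F1 curve
termscout network run/corpus.jsonl run/edges.tsv --focal-term colonoscopy \
    --min-degree 1 --out-dir run/

# batch summary across several focal terms
termscout report --corpus colonoscopy run/corpus.jsonl run/edges.tsv --out-dir run/
```

Corpora are JSON Lines (one video per line; CSV also supported), edge
lists are two-column TSV/CSV, embeddings persist in the word2vec text
format, dendrograms in Newick.

## Package layout

| Module | Role |
| --- | --- |
| `termscout.corpus_model` | domain types, JSONL/CSV corpus and edge I/O, run config |
| `termscout.text_normalize` | normalization recipe and token docs |
| `termscout.embed_neighbors` | word2vec training, cosine, neighbor ranking |
| `termscout.expansion_eval` | mention detection, recall report, core dedup |
| `termscout.corpus_compare` | DFM, set distances, keyness, complete-linkage clustering |
| `termscout.network_eval` | exclusion filter, degree metrics, threshold curve, batch summary |
| `termscout.synthetic_corpus` | seeded corpus/graph generator with ground truth |
| `termscout.cli` | pipeline subcommands + run manifests |
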