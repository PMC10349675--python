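# swarmrec

Swarm-intelligence wrapper feature selection and top-N recommendation,
built as one tested library plus CLI:

- **`swarmrec.mining`** — frequent-itemset mining on a software-emulated
  systolic prefix tree of processing-element nodes (WRITE builds the tree,
  SCAN/COUNT answer candidate support queries), plus a brute-force
  level-wise oracle used only for equivalence testing.
- **`swarmrec.text`** — tokenize / lowercase / stopword-filter / Porter-stem
  pipeline (self-contained stemmer, stopword list shipped as package data)
  and TF-IDF weighting `w = tf * log10(N / df)`.
- **`swarmrec.rfd`** — River Formation Dynamics on weighted digraphs:
  gradient-proportional drop transitions, erosion along traversed paths,
  uniform sediment deposit, and a best-path driver with patience stopping.
- **`swarmrec.pso`** — global-best PSO with an inertia weight (constant or
  linear 0.9 → 0.4 schedule), velocity clamping and box clipping.
- **`swarmrec.hybrid`** — the hybrid RFD-PSO wrapper feature selector.
  Subsets are simultaneously source→sink paths in an index-ordered feature
  graph (RFD view) and points in `[0,1]^D` re-binarized at 0.5 (PSO view);
  the two phases alternate, with wrapper fitness driving extra erosion and
  the global best reinforced by a small constant erosion bonus. Wrapper
  evaluators: held-out 3-NN accuracy or held-out precision@10 of the CF
  recommender.
- **`swarmrec.recommend`** — user-based collaborative filtering (cosine /
  Pearson over co-rated items) and the precision/recall@N evaluation grid
  (N = 2..18), macro-averaged per user.
- **`swarmrec.synthetic`** — seed-deterministic generators for all input
  kinds (latent-factor ratings, transactions with planted itemsets,
  labelled bag-of-words corpora, diurnal actigraphy bundles, labelled
  feature tables) with recorded ground truth.
- **`swarmrec.io`** — plain-text readers/writers (ratings CSV, transaction
  lines, actigraphy directories, feature tables, corpora, edge lists,
  MatrixMarket term weights) with round-trip guarantees.

## CLI

```sh
swarmrec --seed 1 simulate --kind ratings --out ratings.csv
swarmrec --seed 1 simulate --kind transactions --out tx.txt
swarmrec mine --transactions tx.txt --min-support 3 --out frequent.tsv
swarmrec --seed 1 simulate --kind features --out features.csv
swarmrec --seed 1 select --features features.csv --method rfd-pso --out report.json
swarmrec --seed 1 recommend --ratings ratings.csv --top-n 10 --out recs.tsv
swarmrec --seed 1 evaluate --ratings ratings.csv --out grid.tsv
swarmrec --seed 1 evaluate --ratings ratings.csv --variants --out variants.tsv
```

Global flags: `--seed`, `--config <yaml>` (parameter overlay),
`--log-level`. Every run logs its parameters under a deterministic run id.

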