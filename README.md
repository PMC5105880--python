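# ctxhub — contextual hub analysis for molecular interaction networks

Highly connected nodes (hubs) in protein–protein interaction networks are
topologically important, but raw degree is a blunt instrument: networks built
by expanding a gene list through an interaction database are biased toward
promiscuous, ubiquitous or simply well-studied proteins, which enter the
network by chance alone. What an experimentalist usually wants is the node
that interacts with the *relevant* genes — the differentially expressed ones,
say — more often than chance predicts. `ctxhub` identifies these **contextual
hubs** and contrasts them with conventional degree-based hubs.

## The statistic

Given an interaction database (PSI-MITAB 2.5/2.7 or a two-column edge list),
the user's gene list with numeric/categorical attributes, and a predicate
defining which genes are *contextual* (e.g. `logFC gt 2.0`), the tool:

1. filters and deduplicates the database into an undirected graph
   (self-interactions disregarded; both interactors must match any species /
   interaction-type filter);
2. expands the gene list to its **first-neighbor network**: all uploaded genes
   found in the database plus every direct interactor. Edges between first
   neighbors are kept for the analysis but partitioned out of the display set;
3. scores every network node with the hypergeometric upper tail

   ```
   p(X ≥ k) = Σ_{x=k}^{min(n,K)} C(K,x) · C(N−K, n−x) / C(N,n)
   ```

   where *N* is the number of genes with at least one interaction in the
   database, *K* the number of contextual genes among them, *n* the node's
   distinct database interactors, and *k* how many of those are contextual;
4. corrects the p-values across the network node family with the
   Benjamini–Hochberg step-up procedure; and
5. ranks nodes two ways — ascending adjusted p-value (**contextual hubs**) and
   descending database degree (**degree hubs**) — and reports the overlap of
   the two top lists (top 20 by default).

Note that *K* is counted database-wide (every contextual gene with at least
one database interaction), not within the constructed network, and *n* is the
node's degree in the full filtered database; both choices keep the background
of the test and the degree ranking on the same universe.

## Worked example

```
printf 'A\tB\nA\tC\nA\tD\nB\tC\nC\tE\nD\tE\nE\tF\n' > edges.tsv
printf 'gene\tlogFC\nB\t3.0\nC\t2.5\nE\t4.1\n' > context.tsv
chat run --db edges.tsv --db-format edgelist --context context.tsv \
     --id-column gene --where "logFC gt 2.0" --top 3 --out out
```

prints

```
N=6 K=3 network=6 nodes m=6 tests; top-3 overlap: 2 shared, jaccard=0.5000; outputs in out
```

and `out/scores.tsv` holds one row per network node:

```
node  role      contextual  n  k  p_raw               p_adj               rank_contextual  rank_degree
F     neighbor  false       1  1  0.5000000000000002  0.9500000000000011  1                6
A     neighbor  false       3  2  0.5000000000000006  0.9500000000000011  2                1
C     seed      true        3  2  0.5000000000000006  0.9500000000000011  3                2
...
```

Reading node A: of its *n* = 3 database interactors, *k* = 2 are contextual;
drawing 3 interactors from a universe of *N* = 6 genes containing *K* = 3
contextual ones yields 2 or more contextual hits with probability 0.5, which
the BH correction (over the m = 6 tested nodes) lifts to 0.95 — nothing is
enriched in a 6-node toy, as it should be. On a realistic database the
contextual ranking and the degree ranking typically diverge sharply; the
`comparison.tsv` report and the `jaccard` line quantify that divergence.

Other outputs: `network.sif` (display edges: seed–seed and seed–neighbor),
`network.graphml` (full network with `role`, `contextual` and `displayed`
attributes), `run.json` (N, K, network size, warnings — including one when
the database holds fewer than 10,000 interactions and background frequencies
become unreliable).

The `chat simulate` subcommand generates synthetic databases with known
ground truth (null, or with planted contextual/promiscuous hubs), `chat
score` prints the statistics table alone, and `chat report --node X` gives
the node-analyzer view of a single node's interactors.

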