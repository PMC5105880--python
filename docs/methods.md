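# Methods

## Model and procedure

`ctxhub` tests, for every node of a first-neighbor interaction network,
whether the node's interactors are enriched for *contextual* genes beyond
what random drawing from the database would produce. The null model is
sampling without replacement: if the filtered database contains *N* genes
with at least one interaction, of which *K* are contextual, and a node has
*n* distinct interactors of which *k* are contextual, then under the null the
count of contextual interactors is hypergeometric and the reported raw
p-value is the upper tail p(X ≥ k). The test is one-sided by design: the
question is over-representation; depletion is not tested.

Assumptions worth keeping in mind:

- **Background universe.** Over-representation analysis depends heavily on
  the background. Here both *N* and *K* are counted database-wide, and a
  node's draw count *n* is its degree in the full filtered database (not its
  degree inside the constructed network). This keeps the test's background,
  the contextual count and the degree ranking on one consistent universe, and
  makes `db_degree ≡ n`. The alternative — counting K only inside the
  network — would condition on network membership and shift every p-value;
  the database-wide reading follows from defining K as the contextual genes
  with at least one interaction in the database queried.
- **Independence across evidence lines is forced by deduplication.** Multiple
  interaction records for the same pair (different detection methods,
  publications) collapse to a single undirected edge, because the statistic
  counts interactors, not evidence.
- **Self-interactions are disregarded** everywhere: a node never counts among
  its own interactors, and its own contextual status does not enter its *k*.

### Multiple testing

Raw p-values are corrected with the Benjamini–Hochberg step-up procedure
(`statsmodels.stats.multitest.multipletests`, method `fdr_bh`). The family is
the set of nodes actually tested — the constructed network, so m equals the
network size — not all database nodes. Bonferroni-style familywise control is
deliberately not offered; it is too strict for this screening use.

### Rankings and tie-breaks

Contextual ranking: ascending adjusted p-value, ties broken by raw p-value,
then larger *k*, then larger degree, then node ID. Degree ranking: descending
database degree, ties by adjusted p-value, then node ID. The chains are fixed
purely so that identical inputs give byte-identical outputs on any platform;
no scientific meaning attaches to them. The default top-list size is 20.

## Numerical choices

The upper tail is summed in log-space: each term
`exp(lnC(K,x) + lnC(N−K,n−x) − lnC(N,n))` via `lgamma`, factored by the
largest term, accumulated with compensated summation from the largest
contribution downward, and capped at 1.0 to absorb rounding. Tests show
agreement with exact rational enumeration to better than 12 significant
digits for all parameter tuples with N ≤ 12 and relative error below 1e−9 at
interactome scale (N = 20,000), and cross-check against
`scipy.stats.hypergeom.sf` as an independent implementation. When
k ≤ max(0, n+K−N) the event is certain and 1.0 is returned without
summation.

Degenerate inputs are errors, not silent results: an empty database (before
or after filtering), a contextual set with no database member (K = 0 leaves
the statistic undefined), a gene list with no seed in the database, p-values
outside (0, 1], and inconsistent hypergeometric bounds each raise a typed
error that the CLI maps to a nonzero exit with a single-line message.

## Input handling

- Identifier normalization is deliberately conservative: strip a `db:` prefix
  (text up to the first colon), whitespace and parenthetical annotations,
  then upper-case. No cross-namespace mapping service is consulted — the ID
  type is the user's choice, and records in a different namespace than the
  selected one are dropped and counted in a log line rather than guessed at.
- Species and interaction-type filters require BOTH interactors to match;
  records with an empty organism field fail a set species filter. Type
  criteria of the form `MI:dddd` match the controlled-vocabulary identifier
  exactly; anything else is a case-insensitive substring match on the label,
  since MITAB column 12 mixes both forms in the wild.
- The 10,000-interaction minimum database size is implemented as a warning,
  not a hard error: the rule governs which public databases are sensible
  backgrounds, not a mathematical requirement, and small fixtures must run.
- All uploaded genes found in the database seed the network; the predicate
  controls contextual *status* only. Uploaded genes absent from the database
  are excluded from network and analysis (reported in a `missing` list) —
  they have no measurable neighborhood, so every analyzed node stays
  testable. Seed–seed edges are display edges; only neighbor–neighbor edges
  are partitioned into the hidden set.

## Synthetic data generator

The generator emulates the two situations the analysis must handle:

- **null** — an Erdős–Rényi background (or a heavy-tailed degree-sequence
  background via the configuration model, reflecting the power-law
  connectivity of real interactomes) with contextual labels assigned to a
  uniformly random K-subset of interacting nodes. No node is truly enriched,
  so raw p-values must be super-uniform; the calibration experiment (200
  databases of 200 nodes, density 0.05, K = 40) checks
  Pr(p_raw ≤ α) ≤ α + 3 SE at α ∈ {0.01, 0.05, 0.1}. The pooled fraction is
  computed over *all database nodes*: restricting to network nodes would
  condition on having ≥ 1 contextual interactor, which inflates small
  p-values by construction and is exactly the selection effect the
  database-wide background corrects for.
- **planted** — the background plus ten *contextual hubs* wired to 30
  distinct partners of which 60 % are contextual (non-integer allocations are
  resolved by stochastic rounding, so fixed seeds give stable fixtures), and
  ten *promiscuous hubs* wired to 60 partners drawn uniformly (expected
  contextual fraction = the background rate K/N). Hub nodes are drawn
  disjoint from the contextual set and from each other so the two hub kinds
  are cleanly dissociated. Defaults (500 nodes, density 0.01 → mean degree
  ≈ 5, K = 50) are the study conditions used by the recovery experiment and
  were chosen once as a small but realistic regime: contextual genes are 10 %
  of the universe, planted hubs sit well above the background degree but
  below the promiscuous hubs, mirroring the situation where degree ranking
  and enrichment ranking disagree.

At these conditions the recovery experiment (20 seeds) requires the
contextual ranking's top-10 recall of planted contextual hubs to strictly
exceed the degree ranking's recall in every seed, and the top-10
contextual/degree Jaccard to stay below 0.10 — a bound calibrated once by
simulation at the frozen conditions (observed 0.0 in every seed) and then
frozen. This is the synthetic analogue of the empirical observation that top
contextual-hub and top degree-hub lists share no members on real data.

What passing these tests does *not* show: the generator draws edges
(conditionally) independently, has no sociological ascertainment bias (well-
studied proteins accumulating evidence), no false-positive interactions, and
its contextual labels are noiseless. Real databases violate all four, so
results on real data inherit those biases through N, K and n; the synthetic
experiments validate the statistic and the machinery, not the biology.

## Problem sizes

The test suite and the acceptance script run the calibration at 200 null
databases of 200 nodes and the recovery experiment at 20 replicates of the
500-node planted spec — sizes chosen so the full suite completes in seconds
while the binomial error bars on the calibration (≈ 40,000 pooled nodes) stay
tight.

## Known limitations

- No second-or-higher-neighbor expansion, no betweenness/bottleneck
  statistics, no depletion test, no live database queries (files only), and
  no ID mapping across namespaces.
- The hypergeometric model treats the database as a fixed truth; interaction
  confidence scores are ignored.
- With very small backgrounds (toy fixtures) the discrete test is extremely
  conservative — adjusted p-values saturate quickly, as the worked example
  shows.
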