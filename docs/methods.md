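# Methods

## Pipeline

Given three interaction datasets — two multi-herb formulas (XZD, GXBD) and
one set of approved CAD drugs, each a mapping `source → set of target gene
symbols` — the pipeline runs:

1. **Normalization.** Gene symbols are uppercased with all whitespace
   removed; nothing else. No alias or HGNC resolution is attempted: the
   input tables give no mapping procedure and the pipeline must be
   deterministic without external resources. Rows whose symbol normalizes
   to the empty string are rejected with a logged warning; duplicate
   (source, target) rows collapse silently to one link, so the bipartite
   networks are simple graphs.
2. **Bipartite construction and projection.** One edge per distinct link.
   The target-side projection connects two targets iff ≥ 1 common source
   acts on both; the weight is the number of shared sources. Isolated
   targets are retained — the vertex counts of a projection must equal the
   dataset's target-universe size, or the module arithmetic downstream
   would be corrupted. The handshake identity Σ weights = Σ_source C(k, 2)
   holds by construction and is property-tested.
3. **Master integration.** The two formula projections are merged into
   three disjoint layers (XZD-specific, GXBD-specific, overlap); an overlap
   edge's weight is the *sum* of the two formulas' weights, the only merge
   that preserves the handshake identity. The drug projection is stored as
   a fourth, separate layer — a pair may appear both in a formula layer and
   the drug layer, mirroring how the two edge populations are kept
   distinguishable. Summary edge counts are unique unordered pairs, never
   weight sums.
4. **Partition and similarity.** Each target in the union is labeled by its
   membership triple; seven labels exist even though one
   (GXBD-specific-and-drug-targeted) is empty in the study-sized scenario —
   the general implementation must support it. Jaccard similarity is
   computed over source ids, over canonical compound ids when both formulas
   share a declared compound namespace (otherwise reported n/a), and over
   the full / drug-targeted / non-drug-targeted target sets.
   `J(∅, ∅) := 0` as the conservative convention.
5. **Centrality.** Computed on the combined formula TP network (union of
   the three formula layers over the formula targets); a flag optionally
   merges in the drug layer. All shortest-path work ignores projection
   weights — the unweighted convention matches the integer degrees and
   small closeness values the analysis expects. Degree is the neighbor
   count in the projection, not the number of associated ingredients; the
   ingredient count per target is exposed as an auxiliary column of the
   centrality CSV. Betweenness is unnormalized Brandes accumulation,
   endpoints excluded, each unordered pair counted once. Closeness is the
   mean geodesic distance to reachable vertices (lower = more central);
   for a vertex with no reachable counterpart it is undefined and recorded
   as missing — assigning 0 would invert the ordering.
6. **Ranking.** Top-k lists by descending degree, descending betweenness
   and ascending closeness, ties broken by ascending symbol text. The
   consensus is ascending rank-sum over the three full rankings; a vertex
   with undefined closeness takes the worst closeness rank
   (n_defined + 1), so it can never outrank a vertex the metric is defined
   for.
7. **Validation battery.** Ten tests per run: one Pearson χ² on the 3×2
   module × drug-status contingency table (formula targets only), three
   two-sample t-tests (each centrality vs the drug-target dummy), three
   one-way ANOVAs (each centrality across the formula modules present;
   empty modules skipped with a log line), three Pearson correlations among
   the centralities. Sub-test failures (degenerate inputs) are recorded per
   test; the battery continues.

## Statistical conventions

- χ²: uncorrected Pearson statistic, `E = row_total × col_total / N`,
  df = (r−1)(c−1), asymptotic upper-tail p. On the study-sized contingency
  table `[[14, 0], [38, 12], [114, 50]]` this yields χ² = 6.386, p = 0.041,
  minimum expected count 3.8, one of six cells below 5 — the uncorrected
  statistic is the convention that makes these numbers exact. A zero row or
  column total is a hard error (expected counts undefined). The low-expected-
  cell warning (count, percentage, minimum) is always attached.
- t-tests: pooled-variance Student t by default (df = nA + nB − 2); Welch
  with Satterthwaite df behind `--t-variant welch`. The choice cannot be
  adjudicated from summary data, so both are offered. Two constant groups
  with equal means give t = 0, p = 1; with unequal means the test is
  flagged degenerate rather than reporting an infinite statistic.
- ANOVA: F = MS_between / MS_within, df = (k−1, N−k); with two groups
  F = t² of the pooled t-test to 1e−9 relative tolerance (tested).
- Pearson r with the two-sided t-based p on n − 2 df; pairs containing an
  undefined closeness are dropped listwise — imputing a value would
  fabricate centrality for unreachable vertices. Zero variance is an error.
- Tail probabilities come from scipy's chi-squared, t and F distributions
  (regularized incomplete gamma/beta functions).
- One known inconsistency in the published summary this analysis emulates:
  the overlapping-module drug-targeted share is quoted there as 43.8%,
  while the underlying counts give 50/164 = 30.5%. The pipeline reports
  50/164 and makes no attempt to reproduce the 43.8% figure.

## Synthetic data generator

The generator emulates the *structure* of curated interaction tables:
three overlapping target universes with many-to-many source→target links
and heterogeneous source out-degrees. Its defaults are the study-sized
scenario: module cardinalities (114, 50, 38, 12, 14, 0, 178) — giving
target sets of 214 (XZD), 178 (GXBD) and 240 (drugs) with a 164-symbol
formula overlap — 787 and 179 formula ingredients, and 60 drug entities.
The number of drugs is a free parameter (only their 240 targets are fixed
by the scenario); 60 is a plausible order of magnitude for approved CAD
drugs. Out-degrees are uniform on an integer range (formulas 1–40, drugs
1–10): the real out-degree distribution is unknown, and uniform is the
minimal-assumption, configurable choice spanning "one to dozens" of targets
per ingredient.

Sampling: each source draws its out-degree and then samples that many
targets uniformly without replacement from its dataset's allowed set;
targets left untouched are afterwards attached to a uniformly chosen source
(*coverage repair*), which guarantees exact module cardinalities in bounded
time where rejection sampling would not. A single integer seed drives one
NumPy generator for the whole call; identical config + seed reproduces
identical link sets. An infeasible configuration
(`n_sources × kmax < set size`) is rejected before sampling.

What the generator does **not** emulate: the real data's ingredient
out-degree distribution, chemical-class composition, correlated targeting
of biologically related proteins, or the real edge counts of the published
projections (7664/6374/1418 edges — these depend on edge-level data that is
not machine-readable). Passing tests therefore demonstrate correctness of
the pipeline's set arithmetic, graph algorithms and statistics under known
ground truth — not that real formulas have these centrality or correlation
values. t/F/r statistics on synthetic runs differ from the published ones
for the same reason and are not acceptance-checked.

## Numerical and design choices

- All tabular outputs are sorted (symbols lexicographically, edges by
  vertex pair) and written with fixed float formatting, so a fixed
  config + seed yields byte-identical CSV/TSV/JSON outputs; the manifest
  stores SHA-256 checksums so downstream tooling can verify a bundle
  cheaply.
- Ties in every ranking break on ascending symbol text — deterministic and
  label-stable under re-runs.
- Graph sizes in the default test and acceptance runs (≤ 15-vertex oracle
  graphs, ~400-vertex pipeline networks) keep the exhaustive brute-force
  comparisons exact and the full suite fast; the brute-force oracles
  (Floyd–Warshall distances, explicit shortest-path enumeration, all-pairs
  shared-source loops) are independent of the implementation's algorithms.
- The interaction-table dialect is TSV with a required header; the original
  supplementary DOCX tables are not machine-readable and a converter is out
  of scope.

## Limitations

- Gene-symbol normalization is typographic only; two databases naming the
  same protein differently produce two vertices.
- The drug-entity count and out-degree ranges of the synthetic scenario are
  assumptions, not measurements; conclusions about edge-level quantities
  (counts, weights, centrality magnitudes) do not transfer to real data.
- Multiple-testing correction is deliberately absent from the battery, which
  mirrors the validation-battery design it implements; users comparing many
  scenarios should correct externally.
- Closeness on disconnected graphs is per-component by construction;
  comparing closeness across components of very different sizes is not
  meaningful.
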