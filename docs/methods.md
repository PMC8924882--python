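# Methods

## Model and assumptions

The pipeline treats co-expression as closeness in correlation distance,

d(p, q) = 1 − |corr(p, q)|,

with corr the Pearson coefficient between two transcript TPM profiles
across samples. Two assumptions are baked in:

- **Anti-correlation counts as co-expression.** The absolute value makes
  d(p, q) = 0 for perfectly anti-correlated profiles. For
  tissue-panel data this is usually what one wants (a repressor and its
  target belong in the same regulatory story), but it means modules are
  not guaranteed to be sign-coherent.
- **Raw TPM by default.** Correlation is computed on the values as
  given. Pearson correlation of raw TPM is dominated by the
  highest-magnitude tissues; for strongly tissue-specific genes this is
  exactly the signal of interest, which is why raw is the default, but a
  `log_transform` switch (log2(TPM + 1)) is provided for profiles whose
  dynamic range would otherwise swamp shape information.

Pairs with d ≤ threshold form the co-expression graph. The graph is then
reduced with Kruskal's algorithm to a minimum spanning forest (the
thresholded graph is almost always disconnected, so "minimum spanning
tree" generalizes to one tree per connected component), and the Louvain
method partitions the forest into modules. The spanning-forest step is a
deliberate sparsification: it keeps, per component, only the strongest
skeleton of relationships, which makes the community step cheap at the
10⁴–10⁵-transcript scale where the dense graph would have 10⁸+ edge
candidates.

Zero-variance (constant) profiles have undefined correlation. They are
excluded from the graph — never silently assigned a distance — and
re-appended after partitioning as singleton modules, so the final
assignment is total: every transcript of the input matrix gets exactly
one module ID.

## Parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `threshold` | 0.1 | maximum correlation distance for an edge, i.e. \|corr\| ≥ 0.9; the working cutoff for multi-tissue TPM panels. Comparison is inclusive (d ≤ t); at a continuous-data boundary the choice is measure-zero. |
| `weighting` | `similarity` | edge weights for Louvain: w = 1 − d (= \|corr\|). Modularity semantics require affinity, not distance, hence the default; `unweighted` (w = 1) is provided for sensitivity analysis. |
| `resolution` | 1.0 | standard Newman–Girvan modularity; no rescaling of the null-model term. |
| `block_size` | 2048 rows | rows per block in the pairwise-correlation sweep; peak memory is O(block_size × n), so the 5 × 10⁴-transcript scale fits in ordinary memory. |
| `random_state` / `seed` | 1 | seeds the Louvain node-visit order; identical seeds give identical partitions. |
| `log_transform` | off | correlate log2(TPM + 1) instead of raw TPM. |
| `replicate_average` | off | average replicate columns per tissue before correlation; kept off so the correlation sees replicate-level variation, matching the run-level input convention. |

## Numerical choices

- Correlations are computed in double precision as inner products of
  standardized rows (mean 0, unit norm); |corr| is clamped to [0, 1]
  after round-off before forming d, so distances always lie in [0, 1].
- A row counts as zero-variance when the norm of its deviations is below
  1e−12 relative to its magnitude — i.e. constant up to float
  representation.
- Kruskal ties are broken by (weight, u_id, v_id) lexicographic order on
  transcript IDs, so the forest is unique and platform-independent even
  with duplicated weights.
- Louvain: greedy single-node moves with strictly-positive gain
  (ties resolve to the smallest community label), node order shuffled
  from the seed, aggregation between levels, stop when a full level
  gains less than 1e−7 modularity (hard cap of 100 levels, never
  approached on forests). Isolated vertices stay singletons. An
  edgeless graph has modularity 0 by convention.
- Degenerate inputs are hard errors with coordinates: duplicate IDs,
  negative/non-finite/non-numeric expression values, fewer than 3
  samples, an all-constant matrix, negative edge weights, an empty
  TF-domain list.

## Screening

Target modules are the modules containing ≥ 1 isoform of a target gene;
genes with several isoforms may hit several modules. TF candidates are
member transcripts whose annotated domains intersect the TF-domain
list. What counts as a "TF-diagnostic motif" is a curation decision, so
the list is an explicit input; the packaged default seeds the
DNA-binding families relevant to silk-gland regulators (Forkhead
PF00250, TALE-homeobox PF05920, bZIP PF00170, LIM PF00412, HSF PF00447,
NF-Y PF00808, MBF2 PF15868, C2H2 zinc fingers, …) plus the standard
insect TF families. Candidates that are themselves target isoforms
(e.g. a known regulator inside a silk-gene module) are flagged, not
removed. Per-gene transcript totals are reported both as the union over
the gene's modules and as the per-module sum; the two agree because a
partition's modules are disjoint, and both are emitted so either
counting convention of a reference table can be checked.

## Synthetic data

The generator emulates a tissue-panel TPM table: samples are tissues ×
replicates; each planted module owns a tissue signature (high
`expression_scale` in a small tissue subset — a distinct primary tissue
per module, optionally plus one extra — and a 1% baseline elsewhere);
member transcripts are the signature times a per-transcript log-normal
gain times i.i.d. multiplicative log-normal noise (σ = `noise_sd` on the
log scale). Multiplicative noise is the right first-order model for TPM:
values stay non-negative and variance grows with the mean. Background
transcripts are independent log-normal noise and exercise the
excluded/singleton and below-threshold paths. One member per module is
flagged as a target gene and a random ~10% of members receive a TF
domain, so the whole screening path is testable without any download.
All randomness flows from the single spec seed through one generator
stream; identical specs give byte-identical fixture files.

What the generator does **not** emulate: read counting and library-size
effects, isoform structure (members are independent transcripts, not
isoforms of shared loci), correlated noise between samples, and the
long-tailed module-size distribution of real transcriptomes. Passing the
planted-module tests therefore shows the pipeline recovers block
structure under multiplicative noise — not that real-data module counts
will match any particular reference.

## Known limitations

- **Modularity resolution limit on forests.** On a spanning forest with
  near-uniform edge weights, the modularity optimum splits any
  component whose internal weight exceeds roughly √(2W w̄) (W the total
  forest weight): merging two sub-communities with degree-product above
  2W w̄ always lowers Q. Large planted blocks are therefore split into
  several sub-modules — this is a property of the objective on trees,
  not a search failure, and it caps recovery of large blocks well below
  perfect agreement (the benchmark script reports the measured ARI and
  module counts; with 10 planted 50-transcript blocks the forest's
  optimum prefers ~2 communities per block, and the split partition has
  strictly higher modularity than the planted one). Where planted
  modules are small relative to that scale, whole modules are recovered
  exactly. Practically this means module IDs delimit *fine-grained*
  co-expression neighbourhoods; a gene of interest with many isoforms
  will legitimately hit several modules.
- **Count reproduction across implementations.** Louvain output depends
  on node order and seed, and the forest-weighting convention
  (similarity vs. unweighted) changes the partition; published counts
  from other implementations can be approximated but not guaranteed.
  The `reproduce` report exists for exactly this comparison and emits
  both weighting modes and both singleton-counting conventions.
- **Screening is annotation-bound.** TF candidacy is read from the
  annotation table; transcripts missing from it are invisible to the
  screen, and no motif scanning or domain prediction is performed.

## Problem sizes

Tests and the benchmark script run at deliberately modest scale — the
exhaustive oracles (all spanning forests of ≤ 7-vertex graphs, all
partitions of ≤ 8-vertex graphs) pin correctness where enumeration is
exact, and the planted benchmarks (500 transcripts × 30 samples)
exercise every pipeline path in seconds. The blocked correlation sweep
is the only stage whose cost grows quadratically; at the deposited
dataset's 51,926 × 45 scale it completes in tens of minutes on one CPU
with the default block size.
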