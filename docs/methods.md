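# Methods

## Problem and pipeline

`degchar` characterizes the proteins encoded by differentially expressed
genes (DEGs) along three axes and contrasts them with a length-matched
sample of the reference proteome:

1. **Evolutionary conservation** — mean per-residue relative entropy of an
   alignment profile against a background amino-acid distribution.
2. **Intrinsic disorder** — disorder content (fraction of residues labelled
   disordered) under a majority-vote consensus of five per-residue binary
   predictor tracks.
3. **Interconnectedness** — node degree in an undirected protein-protein
   interaction (PPI) network.

The pipeline runs: gene-list merging and gene→protein mapping → background
sampling → feature computation → distributional comparisons → GO
overrepresentation with filtering and path-based redundancy reduction.

## Models and statistics

### Conservation

For a profile row `p` (a probability vector over the 20 amino acids) and
background `q`, the per-residue score is the Kullback–Leibler divergence

    D(p ‖ q) = Σ_a p_a · ln(p_a / q_a),

with the convention `0 · ln 0 = 0`. A protein's conservation is the
arithmetic mean over its rows. Units are nats by default (`unit="bits"`
rescales by `ln 2`); only relative comparisons between groups are
interpreted, so the base is a presentation choice. The default background is
uniform (`q_a = 1/20`); any strictly positive 20-vector may be supplied
(e.g. database composition). Profile zeros are taken at face value — no
pseudocounts; smoothing is the profile producer's responsibility. Rows read
from TSV (probabilities printed to 6 decimals) are validated to sum to 1
within 1e-4 and renormalized exactly; in-memory rows must sum to 1 within
1e-6.

### Disorder consensus

A residue is disordered iff at least 3 of the 5 predictor tracks label it
disordered. The threshold is fixed — it is the strict majority of five
predictors — and disorder content is the mean of the consensus track.

### Interconnectedness

Degree in a simple undirected graph. A protein absent from the network is
reported as "no PPI information" (a `None` sentinel, not degree 0) and is
excluded from interconnectedness statistics; exclusion counts are logged
and reported.

### Length-matched background

Disorder content depends on chain length, so the control sample must match
the focal length distribution. The sampler visits focal proteins in seeded
random order and takes, without replacement, a proteome protein of
identical length when available, otherwise the nearest available length
(ties toward the shorter length; the pick within a length bucket is by
seeded RNG). With dense length coverage (guaranteed by the generator, below)
matching is exact, the two length samples are identical as multisets, and
the two-sample K-S p-value equals 1.

### Hypothesis tests

* **Kolmogorov–Smirnov (two-sample)**: D = sup |ECDF₁ − ECDF₂|; p exact
  when `n·m ≤ 10,000`, else the asymptotic Kolmogorov distribution with
  effective size `nm/(n+m)`. Spot checks show the asymptotic p tracks the
  exact p within ~0.05 at n = m = 100 and within 0.02 in the p < 0.1 region
  where decisions are made. With heavily tied data in the exact regime the
  underlying routine may itself fall back to the asymptotic form.
* **Mann–Whitney U**: two-sided; exact when `n·m ≤ 200` and tie-free, else
  the normal approximation with tie and continuity corrections.
* Significance is α = 0.05 on raw p-values — no multiple-testing
  correction, matching the single-comparison-at-a-time reporting style of
  the analysis this package operationalizes.
* Box summaries report Q1/median/Q3 with 10th/90th centile whiskers;
  quantiles use linear interpolation between order statistics (the numpy
  default), stated here because conventions differ.
* Groups smaller than 5 after exclusions report "not performed due to the
  low sample size" instead of a test result.

### GO overrepresentation

After true-path propagation (every protein annotated to all is_a ancestors
of its direct terms), each term gets

    expected = |focal| · proteome_count / |proteome|,
    fold     = observed / expected,

and a one-sided Fisher exact p (over-representation), computed as the
hypergeometric upper tail — the two are identical for a 2×2 table. The
focal set is a subset of the reference proteome. Filters: observed ≥ 5,
fold > 1.5 (strict), p < 0.05. Each namespace is analyzed separately.

**Path reduction.** Among passing terms, a sub-DAG links each term to its
nearest passing ancestors (non-passing terms are skipped over). For every
maximal root-to-leaf path of this sub-DAG the single term with the highest
focal count is retained (ties: smaller p, then lexicographic id); the
retained set is the union of per-path winners. "Most frequent" is read as
frequency in the focal set — the quantity the count filter also acts on;
this reading is a design choice, and the operator is deliberately a small,
separately testable function so another reading can be swapped in.

## Synthetic data generator

The generator emulates the study's inputs with planted, recoverable
effects. Defaults are the emulated study conditions:

| knob | default | emulates |
|---|---|---|
| `n_focal` | 103 | proteins encoded by the mapped DEGs |
| `deg_list_sizes` | (55, 55, 6, 5) | two 55-gene lists, 6 shared, 5 unmappable |
| `n_proteome` | 5000 | reference proteome (scaled down from ~50k) |
| `length_log_mean`, `length_log_sd` | ln 412, 0.6 | median chain length ≈ 412 |
| `disorder_content_focal/background` | 0.09 / 0.18 | planted disorder medians |
| `conservation_alpha_focal/background` | 1.0 / 0.5 | focal less conserved |
| `predictor_flip_rates` | 0.05×3, 0.08×2 | five predictors, two designs |
| `mean_degree` | 6.0 | PPI mean degree ≈ 6 |
| `ppi_absent_fraction` | 0.1 | proteins without PPI information |
| `go_n_terms`, `go_depth` | 60, 5 | three-namespace GO slice |
| planted term | GO:0000010, 0.24 vs 0.08 | a broad, 3×-enriched term |

Design notes, in generation order:

* **Lengths** are log-normal draws snapped to a quantile grid of ~n/50
  support values, with a repair pass guaranteeing ≥ 20 proteins at every
  grid value in the central 5th–95th percentile band. The grid is what makes
  exact-length matching feasible at desk scale: at n ≈ 5000 the central band
  spans ~900 distinct integer lengths, so a per-integer guarantee is
  impossible without quantization. The log-normal family itself is a
  modeling choice; the emulated study does not state its proteome's length
  distribution.
* **Sequences** are uniform over the 20 amino acids: composition enters no
  downstream statistic — only length and the auxiliary tracks matter.
* **Profiles** draw each row from a symmetric Dirichlet; lower
  concentration α gives sharper columns and higher relative entropy
  (E[RE] ≈ 0.68 nats at α = 0.5, ≈ 0.40 at α = 1). A `conservation_uniform`
  flag produces exactly uniform rows (zero-conservation limit).
* **Disorder truth** is a two-state Markov chain, simulated by alternating
  geometric run lengths, with stationary disordered fraction equal to the
  group target and mean disordered segment length 15 residues — disorder
  occurs in runs, which stresses the consensus caller more realistically
  than i.i.d. residues. Each predictor track flips the truth independently
  per residue at its own rate; rates must be < 0.5 (better than chance).
  Predictor errors are independent — real predictors are correlated, so
  real consensus gains are smaller than the synthetic ones.
* **PPI**: configuration model on a discretized Pareto degree sequence
  (exponent 2.5, rescaled to the target mean), simplified to a simple
  graph, then repaired by adding/removing uniform random edges to hit the
  target edge count exactly. A configurable fraction of proteins is absent
  from the network entirely.
* **GO**: per-namespace rooted is_a DAGs built level by level (depth
  capped), annotations drawn per (term, group) Bernoulli rates. Planted
  terms are generated as **leaf** terms: if a planted term acquires random
  descendants, their base-rate annotations propagate up through it and
  dilute its fold enrichment toward 1, destroying the planted effect. The
  default planting (focal 0.24 vs background 0.08) keeps the 3× enrichment
  ratio while representing a broad, strongly annotated term — the regime in
  which a 3× enrichment at n = 103 is reliably detectable by Fisher's test;
  at rarer rates (e.g. 0.06 vs 0.02) the same ratio has only ~60% power at
  this sample size.
* **Gene lists**: mappable genes are the focal proteins' genes (extra focal
  proteins beyond the gene count are isoforms of randomly chosen genes);
  unmappable ids exist only on the lists. Directions are consistent across
  lists. The synthetic mapping table contains no fragment-flagged rows;
  the mapping stage handles the flag when present in real tables.
* **Reproducibility**: each generator uses an RNG stream seeded by
  `(seed, stream offset)`; per-protein artifacts key their substream by
  `crc32(accession)`, so profiles/tracks generated for a subset of records
  are identical to the corresponding subset of a full run. This is why the
  pipeline can generate profiles only for the ~206 proteins it analyzes
  (focal + matched background) instead of writing ~5000 profile files.

### What passing tests do and do not show

The generator plants clean, independent effects: uniform composition,
independent predictor errors, Bernoulli annotations, no correlation between
disorder, conservation, degree and annotation status. Passing the planted
recovery tests demonstrates that the pipeline's statistics detect effects of
the stated size at the stated sample sizes and control their type-I error —
not that real proteomes satisfy these independence assumptions, and not
that any specific real term list would be recovered.

## Numerical and scale choices

Problem sizes in the test suite are chosen for seconds-scale runs: the
proteome is generated at 5000 + 103 where length coverage matters (matching,
enrichment), at ~100–400 background proteins where it does not (unit tests,
end-to-end determinism), and power/type-I checks use 100 seeds per
condition. Tie-breaks everywhere are deterministic (documented per
operation); all file outputs are byte-stable under a fixed seed, with
floats printed at fixed precision.

## Known limitations

* The relative-entropy background `q` and log base of the emulated analysis
  are not pinned down; both are configurable and the defaults (uniform,
  nats) only affect absolute scores, not group contrasts.
* The enrichment p-value is one-sided Fisher; the emulated analysis used a
  tool whose statistic has varied across releases, so the test is kept as a
  small pluggable function.
* Path reduction semantics ("most frequent term per path") admit other
  readings; see above.
* The pipeline's `--threads` flag is reserved; computation is
  single-threaded.
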