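# Methods

## Statistical model

The pipeline partitions pairwise community turnover into five
ecological processes with two sequential null models.

**Phylogenetic null (βMNTD / βNTI).** βMNTD measures how far each
taxon in one community is from its nearest relative in the other,
abundance-weighted by default (an unweighted 1/richness variant is
exposed via `weighted=False`). The null shuffles taxon labels across
all tips of the patristic distance matrix of the analyzed table — the
canonical "taxa.labels" randomization — and recomputes βMNTD; βNTI is
the z-score over `n_null` (default 999, minimum 99) randomizations.
Because shared taxa remain shared under a consistent permutation, a
pair whose two communities occupy the same taxon set has zero null
variance; such pairs are flagged `degenerate`, reported in QC, and
excluded from process fractions rather than coerced to 0 — silent
exclusion would bias sparse early-timepoint groups.

**Assembly null (RC_Bray).** For pairs with |βNTI| ≤ 2, each null
replicate assembles both communities from a metacommunity pool: the
observed richness is drawn without replacement with probability
proportional to occupancy (implemented as exponential first-arrival
keys, equivalent to sequential weighted sampling), each drawn taxon is
seeded with one individual, and the remaining individuals are placed
multinomially with probability proportional to pooled mean relative
abundance renormalized over the drawn set. Bray–Curtis values of 999
such pairs locate the observed value; ties are half-weighted and the
rank is rescaled to RC ∈ [−1, 1]. RC is computed for every pair but
only consulted when |βNTI| ≤ 2.

**Decision rule.** βNTI > 2 → variable selection; βNTI < −2 →
homogenizing selection; else RC > 0.95 → dispersal limitation (+
drift); RC < −0.95 → homogenizing dispersal; else drift. All four
thresholds are strict: a value exactly at ±2 or ±0.95 falls on the
stochastic side. This convention matters only on a measure-zero
boundary for continuous data.

## Pipeline order and preprocessing

Counts are rarefied first (without replacement, exact
`multivariate_hypergeometric` subsampling; default depth 4,000 reads;
samples below depth are dropped and logged), then taxa occurring in
fewer than 3 samples are removed — the order is deliberate and the two
orders are not interchangeable. Optional quantitative profiling
divides counts by per-taxon 16S copy numbers (default 1 with a warning
when missing), renormalizes rows, and multiplies by per-sample qPCR
loads, so output row sums equal the loads exactly. Whether null models
run on rarefied counts or absolute abundances is a config switch
defaulting to rarefied counts; in absolute mode the RC null rounds
totals to integers because it is an individual-based draw.

## Pair constraints and pools

Comparisons are restricted to the designs the questions require:
different patients, same or different ward, same calendar week, or a
founder timepoint against later timepoints. `calendar_week` must be
supplied in the metadata; the pipeline never derives it from dates, to
avoid hidden binning. The RC pool defaults to the samples of each
comparison group ("group" scope) and can be widened to the whole
analyzed table ("cohort" scope); pool choice is the framework's main
free parameter, so it is explicit in config and recorded in the log.

## Determinism

Every stochastic routine derives its generator from the global seed
plus string tokens (e.g. the sorted sample ids of a pair) via a
blake2b-keyed `SeedSequence`. Per-pair results are therefore
independent of batch order and parallel scheduling, and a rerun with
the same seed writes byte-identical TSVs.

## The simulator

The generator is a positive-control factory: it creates data in which
a single known process dominates, at sizes a desk machine handles
(defaults: 100 taxa, 20 samples, 2,000 reads per sample, lognormal
σ = 1 species-abundance distribution, 4 calendar weeks, one sample per
synthetic patient).

* Trees are pure-birth (Yule, rate 1) with a final exponential
  increment so all branches are positive; traits evolve by Brownian
  motion (σ = 1).
* Local communities follow a zero-sum island model: a multinomial
  founding draw of N = reads individuals, then whole-community
  multinomial replacement each generation from
  (1−m)·local + m·immigration weights. Replacing the entire community
  per round (non-overlapping generations) keeps the process
  individual-based and zero-sum while remaining vectorizable; drift
  strength per round scales as 1/N.
* Selection filters immigration by exp(−(trait − env)²/(2·fw²)).

Regime wiring, with the reasoning that fixed each choice:

* **neutral_drift** — m = 0.7, 50 generations, no selection.
  High migration keeps communities near the pool so observed turnover
  sits inside the assembly null's spread.
* **variable_selection** — two environments ±1.5 (≈ ±0.75 trait SD),
  fw = 0.5, m = 0.3, one environment per ward. Cross-ward pairs face
  opposite filters; βNTI far exceeds +2.
* **homogenizing_selection** — one environment selecting a single
  phylogenetically coherent extreme guild. Guild candidates are
  Gaussian bands at the 5th/95th trait quantiles over several width
  factors and several independent Brownian realizations, ranked by
  mean nearest-neighbour distance relative to size-matched random
  subsets; a quick generator-internal βNTI probe on chain pairs
  accepts the first candidate that clearly carries the signal. This
  conditioning exists because a single Brownian draw can leave the
  trait tails phylogenetically scattered (lineages near the ancestral
  value occur in every clade), in which case no selection filter on
  that realization could produce clustering — the positive control
  must contain the structure it claims to test. Each community is
  founded by a uniform colonization lottery of ~half the guild, so
  samples hold different but closely related taxa.
* **dispersal_limitation** — founder bottleneck of 4 colonists per
  sample (priority effects fix different dominants), m = 0.004
  immigration from the full pool for 60 generations maintaining a
  shared rare background. The mixture of disjoint dominants and
  common rares pushes observed Bray–Curtis above ~95% of null
  assemblies while keeping the null tight; pure drift without the
  founder stage converges to monodominance, where both observed and
  null dissimilarities saturate at 1 and RC collapses to 0.
* **homogenizing_dispersal** — one regional pool per calendar week,
  drifted 300 generations from the metacommunity, with each sample a
  150-colonist draw from its week's pool. Same-week pairs are nearly
  identical while the cohort-wide pool is heterogeneous, driving
  RC below −0.95. The finite colonist draw keeps sample supports
  slightly different; identical supports would make βNTI degenerate.

Recovery of all five regimes was verified across seeds 0–11 (60/60
modal labels correct at the default sizes).

## What the simulator does not emulate

Real cohort features outside its scope: longitudinal within-patient
sampling (each synthetic patient contributes one sample; the
within-patient turnover metrics are exercised on hand-built tables),
clinical covariates that actually drive selection (the driver
regression's positive control is constructed directly), sequencing
noise beyond multinomial sampling, chimeras/contamination, copy-number
variation, and realistic taxonomies. Passing recovery therefore shows
the inference chain is mathematically sound and well calibrated, not
that any particular biological dataset satisfies the nulls'
assumptions.

## Numerical choices

* βNTI requires n_null ≥ 99; z-scores use the sample SD (ddof = 1).
* RC tie detection uses an absolute tolerance of 1e-12 on Bray–Curtis
  values, which are exact ratios of small integers in rarefied mode.
* Bray–Curtis of two all-zero vectors is an error, not 0 or 1.
* Degenerate βNTI pairs carry `bnti = NaN`; downstream code must treat
  them explicitly (classify_pair refuses NaN).
* Rarefaction at exactly the sample's total keeps the sample unchanged.
* Acceptance calibrations use 200 pairs and 999 nulls — large enough
  that the binomial Monte-Carlo error is well inside the stated bands,
  small enough to run in about a minute on one CPU.

## Known limitations

βNTI loses power when communities occupy most of the taxon pool
(supports overlap; nearest-taxon distances vanish) — with only ~100
taxa the informative regime is sample richness well below pool size,
which the simulator respects and real ASV tables (thousands of taxa)
satisfy naturally. The RC null inherits the usual sensitivity to pool
definition; group- versus cohort-scoped pools can shift borderline
pairs across the ±0.95 thresholds. The five-way rule attributes each
pair to exactly one process; mixtures within a pair are not resolved.
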