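# Methods

This note documents the models, conventions and numerical choices behind
cfhydroxy, what the synthetic-data generator does and does not emulate,
and the known limitations of the differential statistic.

## Coordinates and interval algebra

All coordinates are 0-based half-open (`[start, end)`, the BED convention),
internally and on disk; BED12 gene models are converted on read. Book-ended
intervals (one ending where the next starts) merge at `min_gap = 0`,
matching the common `bedtools merge` default. Strand is carried but ignored
by overlap operations; only metagene orientation uses it. Chromosome names
are compared by exact string match — no "chr"-prefix harmonisation — so
mismatched inputs fail loudly (empty overlaps) rather than silently.

Overlap counting follows multicov semantics: a fragment overlapping k
regions is counted in all k. The default ≥ 1 bp overlap threshold runs as a
searchsorted sweep per chromosome, O((n+m) log m); larger thresholds fall
back to an interval tree.

## Region universes

Two region definitions are first-class, because differential regions can
reasonably be defined on either:

* **Consensus / merged hMRs** — per group, a base belongs to the
  high-confidence set iff it is covered by peaks in ≥ `min_replicates`
  (default 2) distinct replicates. "Present in at least two replicates" is
  resolved *base-wise* because peak-wise presence is ill-defined under
  partial overlaps; a peak-wise mode (whole union peak kept on ≥ 1 bp
  support) exists behind a flag. Group consensus sets are then union-merged
  into the total universe.
* **1-kb tiles** — fixed half-open tiles, last tile truncated at the
  chromosome end.

## Quantification and normalisation

Counts are fragments overlapping a region by ≥ 1 bp; the library size is
the sample's *total* fragment count, including fragments outside the
universe. RPKM is `count / ((region_length/1000) · (library_size/10^6))`.
Replicates are merged by summing raw counts and library sizes — not by
averaging RPKM — because summation preserves the Poisson additivity the
differential test relies on; group RPKM is computed on the summed
quantities (identical to the mean of replicate RPKMs when libraries are
equal).

## The differential test

For region r and focal group g, with group-summed counts k and group
library sizes L:

* null mean: `λ_rg = mean over others o of (k_ro · L_g / L_o)`;
* tail: upper `P(X ≥ k)` if `k > λ`, else lower `P(X ≤ k)` (a two-sided
  doubling option exists behind a flag);
* fold change: `(RPKM_g + c) / (mean other RPKM + c)` with pseudocount
  `c = 0.5` RPKM units — the pseudocount never enters the Poisson test;
* adjustment: Bonferroni over the full region × group family (per-group
  family by flag), or none;
* call: adjusted p < α **and** FC ≥ `fc_min` or ≤ `1/fc_min` (the FC
  threshold is read symmetrically).

The test runs on integer counts; a Poisson likelihood on RPKM values would
be ill-defined, so RPKM informs only the fold change. This count-scale
reading of the rescaled null mean is an interpretation — the alternative
(treating RPKM means as Poisson parameters directly) cannot be ruled out
from the published description — and it is the package's documented choice.

Two threshold presets ship: `methods` (Bonferroni-adjusted p < 0.05,
|FC| > 2, intended for merged-hMR universes) and `results` (raw p < 0.01,
|FC| > 2, intended for 1-kb tiles). Healthy controls participate as an
ordinary sixth group when present; they can be excluded by configuration.

Pooled contrasts (e.g. immune-privileged sites — testicular + CNS — versus
the rest) sum the focal and reference sides into two pseudo-groups and run
the same machinery once per region; k-stratum designs iterate each stratum
against the rest.

### Calibration: a known property of the plug-in λ

λ is an *estimate* (the mean of 5 other group counts), so `k − λ` has
variance `≈ 1.2·μ` while the Poisson tail assumes `μ`. Raw p-values are
therefore mildly anti-conservative: simulation of the exact statistic at
the default design gives `P(p < 0.01) ≈ 0.014–0.031` across group-mean
counts 1–150 (for either tail convention) instead of ≤ 0.01. A
known-λ Poisson tail *is* conservative (verified in the unit suite); the
plug-in version is not. In practice the fold-change gate, not the raw
p-value, controls false calls: in 100 no-effect simulations of the 6×3
design over 2,000 regions, zero Bonferroni-plus-FC significant calls
occurred. Users relying on raw p-value thresholds (the `results` preset)
should treat them as ranking scores, not calibrated error rates.

## QC

* **Conversion filter** — "contains a C-to-T conversion signal" is
  operationalised as ≥ 1 converted cytosine per read (threshold exposed);
  the filter is idempotent and order-preserving.
* **Spike-in detection rate** — converted true sites / total true sites
  over spike-in reads (site-level); a read-level rate (fraction of modified
  reads with ≥ 1 conversion) is also reported, since the published "~97 %"
  could be either.
* **Spike-in enrichment** — odds ratio of observed vs input modified-read
  fractions; all-modified libraries report +∞ with a warning.
* **Fragment lengths** — histogram plus modal length (ties resolve to the
  smallest length). Nucleosomal periodicity is reported descriptively; no
  spectral statistic is asserted.

## Genomic-context profiles

* **Class assignment** uses the region midpoint with priority
  promoter > exon > intron > TTS > intergenic (configurable); exclusive
  assignment makes the fractions a partition.
* **Enrichment scores** are `log2((observed + ε)/(expected + ε))`, ε = 0.5,
  with expected counts computed analytically from merged class genome
  fractions; a permutation mode exists for validation but the analytic
  expectation is deterministic and exact under the generator's disjoint
  classes.
* **Metagene profiles** rescale each gene body to 100 bins with 2-kb
  flanks in 20 fixed bins; the signal is fragment-*midpoint* density per bp
  per million fragments (the published y-axis normalisation is not stated;
  this choice makes groups of different depth comparable). Minus-strand
  genes are reversed so bin 0 is always upstream of the TSS; genes shorter
  than the bin count are skipped with a warning.
* **Centred profiles** average the fraction of each bin covered by the
  (merged) mark set over query-region midpoints, ±5 kb in 100-bp bins;
  "distal" regions default to > 10 kb from any TSS.
* **Separability** is the mean silhouette of per-sample `log2(RPKM+1)`
  vectors (restricted to significant regions) under Euclidean distance.
  Any 2-D embedding (t-SNE etc.) is presentation only. Note that for a
  matrix with genuine cluster structure, *permuted* labels score
  systematically negative (≈ −0.2), not ≈ 0: random labels place samples
  across clusters, so the nearest-other-label distance falls below the
  own-label distance. A near-zero permutation null indicates absent
  structure, not a healthy one.

## The synthetic-data generator

Defaults encode the emulated study design: 6 groups — five DLBCL primary
sites (lymph node, gastric, intestinal, testicular, CNS) plus healthy
controls — with 3 replicates each (the smallest real group size), 10,000
hMRs of 500–1500 bp over a 60-Mb toy genome, 200 planted differential
regions per group at fold change 4 (gain/loss mix 0.5), baseline 50
fragments per region per sample. Where the emulated study reports no
quantitative value, defaults follow the generic cfDNA literature and are
configuration-exposed, not asserted as measured values: fragment lengths
167 ± 10 bp (mono-nucleosomal mode, mixture-extensible), per-sample
library factors log-uniform in [0.8, 1.25], region intensities log-normal
(σ = 0.5, mean-preserving), 10 % genome-uniform background fragments,
conversion rates 0.97 (true sites) and 0.005 (false), spike-ins with 10
known sites per read.

Counts are Poisson by default — the distributional assumption of the
test under evaluation — with a gamma-mixing overdispersion knob for
robustness studies. Synthetic "peak calls" are regions whose per-sample
count reaches a threshold (default 10), standing in for upstream peak
calling, which is out of scope. Gene placement leaves ≥ promoter+TTS+500 bp
between genes so the derived feature classes are genuinely disjoint and
partition the genome, making analytic enrichment expectations exact.

All randomness flows from one seed through named substreams (CRC32-keyed
`SeedSequence` spawn keys), so any stage reproduces in isolation and the
fixture bundle is byte-identical across runs.

What the generator does **not** emulate: base-level sequence, GC and
mappability bias, aligner artefacts, copy-number structure, fragment-end
motifs, inter-patient biological heterogeneity beyond the planted effects,
or negative-binomial overdispersion unless enabled. Tests passing under
the generator therefore demonstrate correctness of the computations and
power under the test's own model assumptions — not performance on real
plasma libraries.

## Problem sizes used in the test and acceptance runs

Unit and acceptance runs use the full default design for the recovery and
separability studies (10,000 regions, 18 samples, fragments materialised),
a 2,000-region count-level design for the 100-simulation null study, and
scaled-down designs (300–1,000 regions, 3–6-Mb genomes) for end-to-end and
API tests. The metagene flatness study uses 220 genes on a 10-Mb genome
with 1.5 M uniform fragments, sized so per-bin sampling noise sits well
below the 10 % flatness bound being tested.

## Known limitations

* The plug-in-λ miscalibration above is intrinsic to the published test;
  a conditional binomial test (k given the region total) would be exactly
  calibrated but is deliberately not substituted for it.
* Replicate merging before testing discards within-group dispersion; a
  region driven by one aberrant replicate can be called.
* Midpoint-based class assignment and metagene binning are insensitive to
  fragments straddling class boundaries.
* The consensus operation assumes replicate peak sets are trustworthy as
  given; it does not model peak-caller uncertainty.
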