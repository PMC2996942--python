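# Methods

This note documents the models, defaults and numerical choices behind
`chiptile`, and what the synthetic benchmark does and does not establish
about real arrays.

## Signal model

A two-color scan yields per-probe foreground/background intensities for the
IP and reference channels. Processing follows the standard path for this
array type: per-channel background subtraction (probes with net ≤ 0 in
either channel are removed outright, not zero-filled — a zero net has no
defined ratio, so the boundary case is treated as below threshold);
`log2(IP_net / ref_net)`; normalization to the array-wide average, taken as
the mean of log2 ratios (equivalently the geometric mean of ratios), which
keeps the normalized track symmetric around zero and makes the whole chain
invariant to rescaling either channel; and per-probe arithmetic averaging of
duplicate arrays. Replicate merging intersects the retained probe sets:
a probe filtered out in any replicate is absent from the merged track.
Probe exclusion (non-unique screening) happens before merging. Scanner dye
normalization is an instrument-level step outside this package; the
simulator emits dye-unbiased intensities, so no LOWESS/linear dye correction
is implemented (a documented limitation for real raw scans that have not
passed through feature-extraction software).

## Probe screening

Probes are matched exactly (no mismatch tolerance — cross-hybridization
modeling is out of scope) against both strands of the circular genome; a
position matching on both strands counts once. A probe with ≥ 2 matches is
excluded together with every probe whose middle lies within a configurable
flank (default 1000 bp, inclusive, circular distance) of its middle. The
1000-bp default mirrors the convention of assigning a probe's locus as
1000 bp up- and downstream of its middle. Exclusion is idempotent and
monotone in the flank. For probe sets of uniform length the implementation
counts all k-mer starts in one pass over the doubled genome; this is
algebraically identical to the per-probe scan and is cross-checked against
it and against a naive rotation oracle in the tests.

## GATC context

GATC is its own reverse complement, so single-strand counting over a
centered window (default 500 bp, half-open, start positions only) is
complete. Signal-vs-GATC summaries are five-number boxplot statistics per
GATC count; whiskers use the Tukey 1.5×IQR convention (the plotting
convention is not otherwise constrained).

## Detection rules

* **Neighbor rule** (replicated tracks): a probe qualifies when its log2
  ratio exceeds 0.5 in every replicate; maximal runs of ≥ 2 qualifying
  probes form one target. "Neighboring" means genomically adjacent retained
  probes with centers ≤ `max_gap_bp` apart (default 500 bp ≈ 3× the 150-bp
  spacing), so holes left by excluded probes break runs. Runs may wrap the
  circular origin. The anchor is the probe with the maximal mean signal,
  leftmost (lowest unwrapped coordinate) on ties; target positions are
  reported as the anchor middle, 1-based.
* **Summit rule** (single merged track): a probe above 1.0 whose immediate
  circular neighbors both exceed 0.5; qualifying summits ≤ `max_gap_bp`
  apart merge, anchored at the maximal summit. The thresholds are applied to
  the merged track (the per-replicate reading is also defensible; merged is
  the more parsimonious choice and is exposed via config).
* **Control filter**: a target survives when the neighbor rule — same
  threshold, same minimum run — still holds within its span on replicate-wise
  condition-subtracted tracks (index-matched replicate pairing). The
  subtraction threshold is deliberately the neighbor threshold itself; no
  separate constant is introduced. Survivors keep their spans, scores are
  recomputed on subtracted values. The output is provably a subset of the
  input.
* **Classification**: a call matches a reference entry when the circular
  distance between its anchor and the reference position is ≤ 2000 bp.
  Assignment is nearest-first, each reference entry consumes at most one
  call, and previously described sites take precedence over sites from the
  earlier ChIP-chip-only list; the remainder are novel. Reference tables for
  the σ³² reinvestigation ship in `chiptile/data/`.

Both callers are verified against exhaustive brute-force enumerators on
hundreds of random circular tracks, including wrap-around runs.

## Whole-chromosome summaries

The moving-window track sums positive log2 ratios in windows (default
60,000 bp — the hemimethylated-tract length, see below) stepped every
1000 bp; values are anchored at window centers (center vs start anchoring is
a free choice). With step = window the windows partition the chromosome and
conserve the genome-wide positive signal, which the tests assert. Top-N
cutoffs take the value of the n-th ranked probe and include all ties, so
selections are "~n"; overlap between two selections is counted by shared
probe id (both data sets are assumed to be on the same platform). Extracted
loci are probe middles ± 1000 bp, merged when overlapping, exported as BED
(0-based half-open, wrap intervals split at the origin); tabular reports are
1-based inclusive.

## The simulator

The simulator's purpose is truth-grounded validation of the analysis: it
generates the data-generating processes the analysis is meant to untangle,
not scanner physics (no image model, no dye bias, no fragment-length
distribution, no per-cell replication simulation).

**Genome.** Uniform random circular sequence; GATC planted at a target
per-bp density (default 0.0043 ≈ 20,000 GATCs per 4.64 Mb chromosome; the
background is scrubbed of spontaneous GATCs first so density 0 means zero
sites); `n_duplications` segments (default length 3 kb) copied verbatim to a
second locus to create non-unique probes.

**Binding.** SeqA-like occupancy lives on GATC start positions. Replication
forks leave each locus hemimethylated for `hemimeth_time_s` (60 s) at
`fork_speed_bp_s` (1000 bp/s), giving a 60,000-bp tract behind the fork.
For an unsynchronized population with phases uniform over one replication
cycle (fork transit time plus the dwell), each locus is hemimethylated in a
`tau / (T_fork + tau)` fraction of cells. Loci within `sequestration_bp`
(5 kb) of the origin get a dwell prolonged by `sequestration_factor` (10×,
capped at a full cycle), standing in for origin sequestration — the reason
the origin is the strongest binding region and the window track peaks there.
Probe-level binding enrichment is `1 + beta * (summed occupancy weight in
500 bp)` with `beta` (default 1.0) the effect-size knob; no field-established
value exists for it. `planted_features` instead lays down discrete uniform
occupancy tracts (default 1200 bp) scaled to an exact expected log2 effect,
for truth-recovery benchmarks.

**Artifacts.** The expected linear ratio at a locus is

    binding × (reversal_ip / reversal_input)^[transcribed]
            × spin_column_factor^[transcribed]
            × (1 + rna_background_scale × activity × exp(−rnase_minutes / 30))

Transcribed regions (default: ten non-overlapping 2-kb intervals with
activity uniform in [0.5, 2.0]; no per-gene activity scale is established,
so a modest range around 1 is used) are the protein-rich regions where the
crosslink-reversal and spin-column mechanisms act — deliberately the same
region set, since the two effects plausibly share a cause. The RNA residue
decays exponentially with RNase digestion time with a 30-minute e-folding
time, calibrated so a 30-min digestion retains e⁻¹ of the background while
≥ 90 min is near-complete (the two experimentally contrasted regimes); any
monotone decay would do. `rna_background_scale` defaults to 0 because no
magnitude is established for real arrays. A probe whose footprint lies
entirely inside a duplicated segment maps to both loci and receives the
arithmetic mean of the loci's linear-scale ratios (a "medium enrichment at
both positions"); boundary-straddling probes keep their single locus, as
exact matching would also fail for them. Observed log2 = expected log2 +
N(0, `noise_sd`), drawn per replicate from sub-seeded independent streams
(default 0.3, the scale at which the truth-recovery benchmarks run).
Intensities are emitted at a fixed reference net of 1000 with additive
background 100 — scanner gain is biologically meaningless; the values only
keep background subtraction non-degenerate.

**Truth.** `true_bound` marks probes with binding enrichment ≥ 2 (log2 ≥ 1),
i.e. probes a caller ought to find; weaker GATC-driven enrichment exists at
most probes and labeling it "bound" would make the label vacuous. Artifact
classes follow the precedence non-unique > crosslink > spin-column > RNA
when several mechanisms touch one probe.

**What passing tests do not show.** The simulator has no dye bias, no
spatial artifacts, no intensity-dependent variance, Gaussian log-scale noise
only, and rectangular transcription units; recovery rates measured here are
upper bounds on what identical settings achieve on real scans.

## qPCR

Relative template quantity is `2^(−mean Ct)` per region (amplification
efficiency fixed at perfect doubling; no standard-curve efficiencies are
modeled), reported as a ratio to a reference region with first-order error
propagation from the triplicate Ct standard deviations:
`sd = ratio · ln2 · sqrt(sd_s² + sd_r²)`. At least two usable Ct values per
region are required.

## Pipeline and reproducibility

`run_pipeline` executes the stages in a fixed order and records a funnel of
per-stage counts. Configs are YAML with defaults for every key; unknown keys
are rejected and range violations are reported with key paths. Every output
file carries the seed and a SHA-256 hash of the resolved config; no
timestamps are written, so identical configs give byte-identical outputs.
All randomness flows from `numpy.random.default_rng` seeded by the run seed
plus fixed offsets per purpose (replicate noise streams use `(seed, r)`).

## Problem sizes

Unit and property tests run on 5–300 kb genomes; the truth-recovery and
calibration benchmarks use 500-kb genomes (~3,333 probes, duplicate arrays)
over 20 seeds, and the artifact-reproduction benchmark a 200-kb genome with
eight transcribed regions. These sizes give stable rates (tens of thousands
of probe-level draws per estimate) on a laptop-class single core.

## Known limitations

* Headline counts from the original experiments (74/47 targets, 889
  non-unique probes of 40,000, the >80% overlap) depend on the deposited
  GSE19053 arrays and the vendor's proprietary probe sequences; they are not
  recomputable from this repository and instead parameterize the simulator.
  The README documents the manual GEO recipe.
* No FDR estimation or model-based (HMM/window-statistic) peak calling; the
  two rules implemented are deliberately the simple threshold rules under
  study.
* Cross-platform overlap (different probe sets) is out of scope; overlap is
  by probe id.
* The published list of deleted non-unique probe regions was never released,
  so screening output cannot be diffed against a gold list — only against
  the package's own oracles.
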