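# chiptile

Processing and validation toolkit for **two-color ChIP-chip tiling arrays on
circular bacterial genomes**, with a built-in simulator of the four
background mechanisms known to create false-positive binding sites:

1. **non-unique probes** — probes matching several chromosomal loci report a
   mixture of all copies;
2. **differential crosslink reversal** — incomplete formaldehyde-crosslink
   reversal depletes protein-rich (highly transcribed) regions at different
   rates in IP and input DNA; if 60% of a crosslinked site is reversed in the
   IP but only 30% in the input, the locus appears two-fold enriched;
3. **spin-column trapping** — large crosslinked complexes retained in wash
   columns elute with the IP DNA, enriching protein-rich fragments up to
   several fold;
4. **residual RNA** — insufficient RNase digestion leaves transcript-derived
   signal proportional to local transcription activity.

The package is aimed at people analyzing (or re-analyzing) bacterial
ChIP-chip data — e.g. SeqA binding to hemimethylated GATC tracts, or heat
shock sigma-factor (σ³²) targets — and at method developers who want a
ground-truthed synthetic benchmark for probe-level peak callers.

## What it computes

For a probe *i* with IP and reference intensities, the processed signal is

    r_i = log2( (IP_fg − IP_bg) / (ref_fg − ref_bg) ),  normalized so mean(r) = 0,

averaged over duplicate arrays. On these tracks it implements:

* **probe screening** — exact two-strand matching of every probe against the
  circular genome; probes with ≥ 2 matches and all probes within 1000 bp of
  them are excluded;
* **neighbor rule** — targets are maximal runs of ≥ 2 adjacent probes with
  r > 0.5 in *both* replicates (adjacent = centers ≤ 500 bp apart);
* **summit rule** — peaks are probes with r > 1.0 whose immediate neighbors
  both exceed 0.5;
* **control filtering** — a target survives only if the neighbor rule still
  holds on replicate-wise condition-subtracted tracks (e.g. heat-shock minus
  non-heat-shock, or wild type minus knockout);
* **classification** — calls are matched to reference target lists within a
  2000-bp circular distance (the σ³² reference tables ship with the package);
* **GATC context** — GATC counts in a 500-bp window around each probe middle
  with boxplot summaries of signal per GATC count;
* **moving windows** — sum of positive r in 60,000-bp windows every 1000 bp,
  the length scale of the hemimethylated tract trailing a replication fork
  (1000 bp/s × 60 s);
* **top-N overlap** — Venn counts of the ~1000 highest-signal probes between
  two data sets;
* **qPCR** — 2^(−ΔCt) relative quantification with first-order error
  propagation.

The simulator generates circular genomes with planted GATC sites and exact
segmental duplications, tiles them with 60-base probes every 150 bp, and
emits two-channel scans plus a per-probe truth table, so every detection
rule can be validated by truth recovery.

## Worked example

```python
import json, dataclasses
from chiptile import run_pipeline

report = run_pipeline({
    "seed": 11,
    "out_dir": "demo",
    "simulate": {"genome_length": 200000, "planted_targets": 8,
                 "planted_effect_log2": 2.0, "n_duplications": 1,
                 "control": "knockout"},
    "artifacts": {"noise_sd": 0.3},
})
print(json.dumps(dataclasses.asdict(report), indent=2))
```

prints (abridged):

```json
{
  "seed": 11,
  "config_hash": "adaf2811c196",
  "n_probes": 1333,
  "n_excluded": 62,
  "n_retained_after_background": 1271,
  "n_targets_called": 8,
  "n_targets_after_control": 8,
  "outputs": {
    "planted_centers": [12883, 31969, 46108, 69977, 96543, 116382, 179261, 194597]
  }
}
```

Reading the funnel: a 200-kb circular genome is tiled with 1333 probes; one
3-kb duplication makes 62 probes (the multi-mapping ones plus their 1000-bp
neighborhoods) ineligible; all 1271 retained probes survive background
subtraction; the neighbor rule calls 8 targets at noise 0.3 — exactly the 8
planted log2-2.0 binding tracts — and all 8 survive the knockout-style
control comparison. The output directory holds the probe table, per-replicate
and merged ratio tracks, target calls, BED loci, the 60-kb window bedGraph
and `report.json`, each stamped with the seed and config hash.

The same stages are available from the shell:

```bash
chiptile simulate --length 200000 --seed 11 --out-dir demo
chiptile screen-probes --genome demo/genome.fa --probes demo/probes.tsv
chiptile run --config run.yaml --seed 11
chiptile --help
```

## Real arrays

The experimental data this workflow is shaped around (SeqA and σ³²
ChIP-chip on *E. coli*, Oxford Gene Technology whole-genome arrays) are
deposited in GEO under accession **GSE19053**. The probe sequences are
proprietary to the array vendor, so the repository does not redistribute
them; to reanalyze the deposited arrays, download the series matrix and raw
files from GEO, export per-probe `ip_fg/ip_bg/ref_fg/ref_bg` columns to the
scan TSV layout used here (see `chiptile/io.py`), supply the platform's
probe table, and run `chiptile process` / `chiptile call-targets` with the
default thresholds.
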