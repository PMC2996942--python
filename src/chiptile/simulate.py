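"""Synthetic ChIP-chip data: genomes, probe designs, binding features, and
two-channel array scans under configurable background-artifact mechanisms.

The simulator emulates a two-color tiling-array experiment on a circular
bacterial chromosome (60-base probes, ~150-bp start-to-start spacing, an
Oxford-Gene-Technology-style design). True binding follows a hemimethylated-
GATC-tract model of SeqA-like occupancy behind bidirectional replication
forks. Four background mechanisms known to inflate ChIP signal can be
switched on independently:

* **non-unique probes** — duplicated genomic segments make a probe report the
  mean of several loci;
* **differential crosslink reversal** — incomplete reversal depletes
  protein-rich (transcribed) regions differently in IP and input material,
  e.g. 60% reversal in IP vs 30% in input appears as two-fold enrichment;
* **spin-column trapping** — crosslinked protein-rich fragments are retained
  and later eluted from wash-column matrices, enriching them in the IP;
* **residual RNA** — insufficient RNase digestion leaves transcript-derived
  signal proportional to local transcription activity.

Every simulated scan ships with a per-probe truth table so downstream peak
calls can be scored against ground truth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSequence

#: e-folding time of residual RNA under RNase digestion, minutes. Calibrated
#: so a 30-min digestion retains e^-1 of the background while >= 90 min is
#: near-complete, the two regimes contrasted experimentally.
RNASE_TAU_MIN = 30.0

#: window (bp) over which GATC occupancy weights are summed into a probe's
#: binding enrichment; matches the 500-bp GATC-context convention.
BINDING_WINDOW_BP = 500

PROBE_COLUMNS = ["probe_id", "sequence", "chrom", "middle"]
SCAN_COLUMNS = ["probe_id", "ip_fg", "ip_bg", "ref_fg", "ref_bg"]
TRUTH_COLUMNS = ["probe_id", "true_bound", "expected_log2", "artifact_class"]

# fixed intensity scales: reference net intensity and additive background.
# Scanner gain carries no biological meaning; these only keep background
# subtraction non-degenerate.
_REF_NET = 1000.0
_BG = 100.0


def residual_rna(minutes: float) -> float:
    """Fraction of RNA background surviving an RNase digestion of the given
    duration: ``exp(-minutes / 30)``. Monotone non-increasing, -> 0 for long
    digestions."""
    if minutes < 0:
        raise ValueError("rnase_minutes must be non-negative")
    return math.exp(-minutes / RNASE_TAU_MIN)


@dataclass(frozen=True)
class ArtifactConfig:
    """Knobs for the four background mechanisms plus measurement noise.

    The defaults are neutral (no artifact, no RNA background) except for
    ``noise_sd``, which defaults to the 0.3 log2-scale measurement noise used
    throughout the truth-recovery simulations.

    Parameters
    ----------
    reversal_ip, reversal_input
        Fraction of crosslinked sites reversed in IP / input material at
        protein-rich (transcribed) loci, in ``(0, 1]``. Their ratio appears
        directly as apparent enrichment there: 0.6 vs 0.3 gives two-fold.
    spin_column_factor
        Multiplier (>= 1) applied to protein-rich fragments in the IP channel
        when spin-column washing is simulated; 1 disables the mechanism.
    rnase_minutes
        Duration of the RNase digestion; short digestions leave residual RNA
        background at transcribed loci.
    rna_background_scale
        Coefficient coupling transcription activity to residual-RNA signal;
        0 disables the mechanism (no magnitude is established for real
        arrays, so it is off by default).
    noise_sd
        Standard deviation of additive log2-scale noise per replicate.
    binding_beta
        Effect size converting summed GATC occupancy weight into binding
        enrichment ``1 + beta * weight``.
    seed
        Base seed; replicate r uses the independent stream ``(seed, r)``.
    """

    reversal_ip: float = 1.0
    reversal_input: float = 1.0
    spin_column_factor: float = 1.0
    rnase_minutes: float = 90.0
    rna_background_scale: float = 0.0
    noise_sd: float = 0.3
    binding_beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("reversal_ip", "reversal_input"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.spin_column_factor < 1:
            raise ValueError("spin_column_factor must be >= 1")
        if self.rnase_minutes < 0:
            raise ValueError("rnase_minutes must be non-negative")
        if self.rna_background_scale < 0:
            raise ValueError("rna_background_scale must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.binding_beta < 0:
            raise ValueError("binding_beta must be non-negative")


@dataclass
class FeatureAnnotation:
    """Genomic features driving true binding and artifact background.

    ``true_binding`` is a per-position occupancy weight (length = genome
    length): nonzero at GATC start positions, scaled by the fraction of cells
    in which that locus is hemimethylated. ``transcribed_regions`` are
    ``(start, end, activity)`` half-open intervals of high transcription
    activity where the crosslink/spin-column/RNA mechanisms act.
    """

    genome: GenomeSequence
    transcribed_regions: list[tuple[int, int, float]]
    true_binding: np.ndarray
    fork_origin: int
    tract_length_bp: int

    def __post_init__(self) -> None:
        n = len(self.genome)
        self.true_binding = np.asarray(self.true_binding, dtype=float)
        if self.true_binding.shape != (n,):
            raise ValueError("true_binding must have one weight per genome position")
        if not np.all(np.isfinite(self.true_binding)) or np.any(self.true_binding < 0):
            raise ValueError("occupancy weights must be finite and non-negative")
        for start, end, activity in self.transcribed_regions:
            if not (0 <= start < end <= n):
                raise ValueError("transcribed region outside genome")
            if activity < 0:
                raise ValueError("activity level must be non-negative")


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _find_gatc_starts(seq: str, circular: bool = True) -> list[int]:
    n = len(seq)
    text = seq + (seq[:3] if circular else "")
    starts = []
    i = text.find("GATC")
    while i != -1:
        if i < n:
            starts.append(i)
        i = text.find("GATC", i + 1)
    return starts


def _scrub_gatc(seq: bytearray, protected: list[tuple[int, int]], rng) -> None:
    """Mutate bases until the circular sequence contains no GATC, leaving
    positions inside ``protected`` half-open intervals untouched."""
    n = len(seq)

    def is_protected(p: int) -> bool:
        return any(s <= p < e for s, e in protected)

    for _ in range(100):
        starts = _find_gatc_starts(seq.decode("ascii"))
        if not starts:
            return
        for i in starts:
            for off in range(4):
                p = (i + off) % n
                if not is_protected(p):
                    cur = chr(seq[p])
                    choices = [b for b in "ACGT" if b != cur]
                    seq[p] = ord(choices[rng.integers(len(choices))])
                    break
            else:  # pragma: no cover - would require GATC fully inside a copy
                raise RuntimeError("cannot scrub GATC inside protected segment")
    raise RuntimeError("GATC scrubbing did not converge")  # pragma: no cover


def generate_genome(
    length: int,
    gatc_density: float = 0.0043,
    n_duplications: int = 0,
    dup_length: int = 3000,
    seed: int = 0,
    name: str = "synthetic_chr",
) -> GenomeSequence:
    """Generate a random circular genome with planted GATC sites and exact
    segmental duplications.

    ``gatc_density`` is the expected per-bp rate of GATC starts (the
    *E. coli* chromosome carries about 20,000 GATCs in 4.64 Mb, i.e. ~0.0043
    per bp, the default). With density 0 the sequence contains no GATC at
    all. Each of the ``n_duplications`` segments of ``dup_length`` bp occurs
    verbatim at two loci, modelling the non-unique sequences that make array
    probes multi-mapping.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0 <= gatc_density <= 0.25):
        raise ValueError("gatc_density must be in [0, 0.25]")
    if n_duplications < 0 or dup_length <= 0:
        raise ValueError("n_duplications and dup_length must be non-negative/positive")
    if n_duplications > 0:
        if length < 10 * dup_length:
            raise ValueError(
                f"impossible parameters: length ({length}) must be >= 10 * dup_length "
                f"({10 * dup_length}) to place duplications"
            )
        if 2 * n_duplications * dup_length > length // 2:
            raise ValueError(
                "impossible parameters: duplications would cover more than half the "
                f"genome (2 * {n_duplications} * {dup_length} > {length // 2})"
            )

    rng = np.random.default_rng(seed)
    seq = bytearray(_BASES[rng.integers(0, 4, size=length)].tobytes())
    _scrub_gatc(seq, [], rng)

    # plant GATC sites at the requested density (collisions < 4 bp apart are
    # dropped, so the realized count is approximately density * length)
    n_sites = int(round(gatc_density * length))
    if n_sites > 0:
        positions = np.sort(rng.choice(length, size=min(n_sites, length // 4), replace=False))
        kept: list[int] = []
        for p in positions:
            if kept and p - kept[-1] < 4:
                continue
            kept.append(int(p))
        if len(kept) >= 2 and (kept[0] + length) - kept[-1] < 4:
            kept.pop()
        for p in kept:
            for off, base in enumerate(b"GATC"):
                seq[(p + off) % length] = base

    # exact duplications: copy source segments over destination segments
    duplications: list[tuple[int, int, int]] = []
    if n_duplications > 0:
        taken: list[tuple[int, int]] = []

        def overlaps(a: int, b: int) -> bool:
            return any(a < e + 10 and b > s - 10 for s, e in taken)

        for _ in range(n_duplications):
            for _attempt in range(1000):
                src = int(rng.integers(0, length - dup_length))
                dst = int(rng.integers(0, length - dup_length))
                if src == dst:
                    continue
                if overlaps(src, src + dup_length) or overlaps(dst, dst + dup_length):
                    continue
                if src < dst + dup_length and dst < src + dup_length:
                    continue
                break
            else:  # pragma: no cover
                raise ValueError(
                    "impossible parameters: could not place non-overlapping "
                    "duplication segments"
                )
            seq[dst : dst + dup_length] = seq[src : src + dup_length]
            taken.extend([(src, src + dup_length), (dst, dst + dup_length)])
            duplications.append((src, dst, dup_length))

    if gatc_density == 0 and duplications:
        # copying segment boundaries can create GATC across an edge; scrub
        # outside the copied intervals so duplications stay verbatim
        protected: list[tuple[int, int]] = []
        for src, dst, ln in duplications:
            protected.extend([(src, src + ln), (dst, dst + ln)])
        _scrub_gatc(seq, protected, rng)

    return GenomeSequence(
        name=name, sequence=seq.decode("ascii"), circular=True, duplications=duplications
    )


# ---------------------------------------------------------------------------
# feature placement
# ---------------------------------------------------------------------------


def place_features(
    genome: GenomeSequence,
    n_transcribed: int = 10,
    fork_origin: int | None = None,
    fork_speed_bp_s: float = 1000.0,
    hemimeth_time_s: float = 60.0,
    seed: int = 0,
    transcribed_length_bp: int = 2000,
    activity_range: tuple[float, float] = (0.5, 2.0),
    sequestration_bp: int = 5000,
    sequestration_factor: float = 10.0,
) -> FeatureAnnotation:
    """Annotate a genome with transcribed regions and a hemimethylated-tract
    binding model.

    Bidirectional forks start at ``fork_origin`` and move at
    ``fork_speed_bp_s``; each replicated GATC stays hemimethylated for
    ``hemimeth_time_s``, so the tract of hemimethylated DNA trailing a fork is
    ``fork_speed_bp_s * hemimeth_time_s`` bp long (60,000 bp at 1000 bp/s and
    60 s). For an unsynchronized population with cell phases uniform over one
    replication cycle, a locus is hemimethylated in a ``tau / (T_fork + tau)``
    fraction of cells. Loci within ``sequestration_bp`` of the origin use a
    dwell time prolonged by ``sequestration_factor`` (capped at a full cycle),
    modelling origin sequestration; this is what makes the origin the
    strongest binding region.
    """
    n = len(genome)
    if n == 0:
        raise ValueError("genome must be non-empty")
    if fork_origin is None:
        fork_origin = n // 2
    if not (0 <= fork_origin < n):
        raise ValueError("fork_origin must lie within the genome")
    if fork_speed_bp_s <= 0 or hemimeth_time_s < 0:
        raise ValueError("fork speed must be positive and hemimethylation time >= 0")

    rng = np.random.default_rng(seed)
    tract_length_bp = int(round(fork_speed_bp_s * hemimeth_time_s))

    t_fork = (n / 2) / fork_speed_bp_s
    cycle = t_fork + hemimeth_time_s
    base_occupancy = hemimeth_time_s / cycle if cycle > 0 else 0.0
    seq_occupancy = min(sequestration_factor * hemimeth_time_s, cycle) / cycle if cycle > 0 else 0.0

    true_binding = np.zeros(n)
    gatc_starts = np.array(_find_gatc_starts(genome.sequence, genome.circular), dtype=int)
    if gatc_starts.size:
        d = np.abs(gatc_starts - fork_origin) % n
        d = np.minimum(d, n - d)
        occ = np.where(d <= sequestration_bp, seq_occupancy, base_occupancy)
        true_binding[gatc_starts] = occ

    # non-overlapping transcribed regions
    regions: list[tuple[int, int, float]] = []
    occupied: list[tuple[int, int]] = []
    for _ in range(n_transcribed):
        for _attempt in range(1000):
            start = int(rng.integers(0, max(1, n - transcribed_length_bp)))
            end = start + transcribed_length_bp
            if end > n:
                continue
            if any(start < e and end > s for s, e in occupied):
                continue
            break
        else:
            break  # genome too crowded; place what fits
        activity = float(rng.uniform(*activity_range))
        regions.append((start, end, activity))
        occupied.append((start, end))
    regions.sort()

    return FeatureAnnotation(
        genome=genome,
        transcribed_regions=regions,
        true_binding=true_binding,
        fork_origin=fork_origin,
        tract_length_bp=tract_length_bp,
    )


def planted_features(
    genome: GenomeSequence,
    n_targets: int,
    effect_log2: float = 2.0,
    tract_bp: int = 1200,
    binding_beta: float = 1.0,
    n_transcribed: int = 0,
    seed: int = 0,
) -> tuple[FeatureAnnotation, np.ndarray]:
    """Plant discrete binding targets of known effect size.

    Each target is a ``tract_bp``-long uniform occupancy tract centered at a
    random position, scaled so a probe whose 500-bp binding window lies fully
    inside the tract has expected enrichment ``2**effect_log2``. Targets are
    kept >= 5 kb apart (and away from any transcribed regions placed when
    ``n_transcribed > 0``). Returns the annotation and the target centers.
    """
    n = len(genome)
    if n_targets < 0:
        raise ValueError("n_targets must be non-negative")
    rng = np.random.default_rng(seed)
    features = place_features(
        genome, n_transcribed=n_transcribed, seed=seed, hemimeth_time_s=0.0
    )
    features.true_binding = np.zeros(n)

    density = (2.0**effect_log2 - 1.0) / binding_beta / BINDING_WINDOW_BP
    centers: list[int] = []
    margin = tract_bp // 2 + 500
    forbidden = [(s - margin, e + margin) for s, e, _ in features.transcribed_regions]
    for _ in range(n_targets):
        for _attempt in range(2000):
            c = int(rng.integers(0, n))
            if any(min(abs(c - x) % n, n - abs(c - x) % n) < 5000 for x in centers):
                continue
            if any(s <= c < e for s, e in forbidden):
                continue
            break
        else:
            raise ValueError("could not place targets 5 kb apart; genome too small")
        centers.append(c)
        idx = (np.arange(c - tract_bp // 2, c + tract_bp // 2) % n).astype(int)
        features.true_binding[idx] = density
    return features, np.array(sorted(centers), dtype=int)


# ---------------------------------------------------------------------------
# probe design
# ---------------------------------------------------------------------------


def design_probes(
    genome: GenomeSequence, probe_length: int = 60, spacing: int = 150
) -> pd.DataFrame:
    """Tile the circular genome with probes at fixed start-to-start spacing.

    Returns a ProbeSet DataFrame with columns ``probe_id, sequence, chrom,
    middle`` ordered by middle position; ``middle = start + probe_length // 2``
    (0-based) and the probe count is ``floor(genome_length / spacing)``.
    """
    n = len(genome)
    if not (0 < probe_length <= spacing <= n):
        raise ValueError(
            f"require 0 < probe_length ({probe_length}) <= spacing ({spacing}) "
            f"<= genome length ({n})"
        )
    count = n // spacing
    starts = np.arange(count) * spacing
    records = {
        "probe_id": [f"P{i:06d}" for i in range(count)],
        "sequence": [genome.fetch(int(s), probe_length) for s in starts],
        "chrom": genome.name,
        "middle": (starts + probe_length // 2) % n,
    }
    return pd.DataFrame(records, columns=PROBE_COLUMNS)


# ---------------------------------------------------------------------------
# array simulation
# ---------------------------------------------------------------------------


def _circular_window_sums(weights: np.ndarray, centers: np.ndarray, window: int) -> np.ndarray:
    """Sum of per-position weights over circular windows
    ``[c - window//2, c + window//2)`` for each center."""
    n = weights.size
    csum = np.concatenate([[0.0], np.cumsum(np.concatenate([weights, weights]))])
    lo = (centers - window // 2) % n
    hi = lo + window
    return csum[hi] - csum[lo]


def _expected_ratio_at(
    middles: np.ndarray,
    features: FeatureAnnotation,
    config: ArtifactConfig,
    probe_length: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free expected IP/reference ratio at single loci given by probe
    middle positions. Returns (ratio, binding_enrichment, transcribed_mask)."""
    n = len(features.genome)
    weight = _circular_window_sums(features.true_binding, middles, BINDING_WINDOW_BP)
    binding = 1.0 + config.binding_beta * weight

    activity = np.zeros(middles.size)
    half = probe_length // 2
    for rs, re, act in features.transcribed_regions:
        # probe footprint [mid - half, mid + half) overlaps [rs, re):
        # mid strictly inside (rs - half, re + half), circularly
        hit = ((middles - (rs - half + 1)) % n) < (re - rs + probe_length - 1)
        activity = np.where(hit, np.maximum(activity, act), activity)
    transcribed = activity > 0

    ratio = binding.copy()
    ratio = np.where(transcribed, ratio * (config.reversal_ip / config.reversal_input), ratio)
    ratio = np.where(transcribed, ratio * config.spin_column_factor, ratio)
    rna = config.rna_background_scale * activity * residual_rna(config.rnase_minutes)
    ratio = ratio * (1.0 + rna)
    return ratio, binding, transcribed


def _probe_loci(
    middles: np.ndarray, genome: GenomeSequence, probe_length: int
) -> list[list[int]]:
    """All genomic loci (as middle positions) each probe maps to, using the
    genome's duplication annotations. A probe is multi-locus only when its
    footprint lies entirely inside a duplicated segment."""
    half = probe_length // 2
    loci = [[int(m)] for m in middles]
    for src, dst, ln in genome.duplications:
        for i, m in enumerate(middles):
            start = int(m) - half
            if src <= start and start + probe_length <= src + ln:
                loci[i].append(int(m) - src + dst)
            elif dst <= start and start + probe_length <= dst + ln:
                loci[i].append(int(m) - dst + src)
    return loci


def simulate_arrays(
    probes: pd.DataFrame,
    features: FeatureAnnotation,
    config: ArtifactConfig,
    replicates: int = 2,
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Simulate two-channel array scans plus ground truth.

    The noise-free expected IP/reference ratio at a probe is::

        binding * reversal_ratio[transcribed] * spin[transcribed] * (1 + rna)

    with ``binding = 1 + beta * (summed GATC occupancy weight in 500 bp)``.
    Probes mapping to duplicated loci receive the arithmetic mean of their
    loci's linear-scale expected ratios (a medium enrichment at both
    positions). Observed log2 = expected log2 + Normal(0, noise_sd), drawn
    independently per replicate from sub-seeded streams; foreground/background
    intensities are constructed so that ``fg - bg`` reproduces the signal.

    Returns one ``(ArrayScan, TruthTable)`` DataFrame pair per replicate;
    the truth table is identical across replicates.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    genome = features.genome
    if (probes["chrom"] != genome.name).any():
        raise ValueError("probes and features refer to different genomes")
    middles = probes["middle"].to_numpy(dtype=int)
    if middles.size and middles.max() >= len(genome):
        raise ValueError("probe middle outside genome")
    probe_length = len(probes["sequence"].iloc[0]) if len(probes) else 60

    loci = _probe_loci(middles, genome, probe_length)
    flat = np.array([m for group in loci for m in group], dtype=int)
    ratio_flat, binding_flat, _ = _expected_ratio_at(flat, features, config, probe_length)

    n_probes = len(probes)
    expected_ratio = np.empty(n_probes)
    binding_mean = np.empty(n_probes)
    multi = np.zeros(n_probes, dtype=bool)
    pos = 0
    for i, group in enumerate(loci):
        k = len(group)
        expected_ratio[i] = ratio_flat[pos : pos + k].mean()
        binding_mean[i] = binding_flat[pos : pos + k].mean()
        multi[i] = k > 1
        pos += k

    expected_log2 = np.log2(expected_ratio)

    # artifact classification (precedence: nonunique > crosslink > spin > rna)
    _, _, transcribed = _expected_ratio_at(middles, features, config, probe_length)
    activity_on = transcribed
    cls = np.full(n_probes, "none", dtype=object)
    rna_on = (
        config.rna_background_scale > 0 and residual_rna(config.rnase_minutes) > 1e-6
    )
    cls[activity_on & rna_on] = "rna"
    if config.spin_column_factor > 1:
        cls[activity_on] = "spin_column"
    if config.reversal_ip != config.reversal_input:
        cls[activity_on] = "crosslink"
    cls[multi] = "nonunique"

    truth = pd.DataFrame(
        {
            "probe_id": probes["probe_id"].to_numpy(),
            "true_bound": binding_mean >= 2.0,
            "expected_log2": expected_log2,
            "artifact_class": cls,
        },
        columns=TRUTH_COLUMNS,
    )

    out: list[tuple[pd.DataFrame, pd.DataFrame]] = []
    for r in range(replicates):
        rng = np.random.default_rng([config.seed, r])
        observed = expected_log2 + (
            rng.normal(0.0, config.noise_sd, size=n_probes) if config.noise_sd > 0 else 0.0
        )
        ip_net = _REF_NET * np.power(2.0, observed)
        scan = pd.DataFrame(
            {
                "probe_id": probes["probe_id"].to_numpy(),
                "ip_fg": ip_net + _BG,
                "ip_bg": _BG,
                "ref_fg": _REF_NET + _BG,
                "ref_bg": _BG,
            },
            columns=SCAN_COLUMNS,
        )
        out.append((scan, truth.copy()))
    return out
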