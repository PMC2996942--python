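"""Probe uniqueness screening and GATC-context analysis.

Array probes whose sequence occurs at more than one chromosomal locus
hybridize a mixture of fragments from all copies and are a known source of
false-positive ChIP signal. This module counts exact matches of each probe
on both strands of the circular genome, flags non-unique probes together
with their neighborhoods for exclusion, and computes the number of GATC
(Dam methylation) sites around each probe's middle position with
signal-vs-GATC group summaries.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeSequence, circular_distance, reverse_complement

_VALID = frozenset("ACGT")


def _match_starts(pattern: str, genome: GenomeSequence) -> set[int]:
    """Start positions (0-based, circular) where ``pattern`` occurs exactly
    on the forward strand."""
    n = len(genome)
    k = len(pattern)
    text = genome.sequence + (genome.sequence[: k - 1] if genome.circular else "")
    starts: set[int] = set()
    i = text.find(pattern)
    while i != -1:
        if i < n:
            starts.add(i)
        i = text.find(pattern, i + 1)
    return starts


def count_genome_matches(probe_sequence: str, genome: GenomeSequence) -> int:
    """Number of distinct start positions on the circular genome where the
    probe matches exactly, forward strand plus reverse-complement matches.

    A position matching on both strands (a reverse-complement palindrome)
    counts once. Matching is exact only; ambiguity codes are rejected.
    """
    if not _VALID.issuperset(probe_sequence):
        bad = sorted(set(probe_sequence) - _VALID)
        raise ValueError(f"probe contains non-ACGT characters: {bad}")
    if len(probe_sequence) == 0 or len(probe_sequence) >= len(genome):
        raise ValueError("probe must be non-empty and shorter than the genome")
    starts = _match_starts(probe_sequence, genome)
    rc = reverse_complement(probe_sequence)
    if rc != probe_sequence:
        starts |= _match_starts(rc, genome)
    return len(starts)


def _bulk_match_counts(sequences: pd.Series, genome: GenomeSequence) -> np.ndarray:
    """Match counts for many same-length probes in one pass over the genome.

    Builds a counter of every k-mer start on the circular forward strand;
    a probe's two-strand count is counter[seq] + counter[rc(seq)] (one term
    when the probe is its own reverse complement). Equivalent to calling
    :func:`count_genome_matches` per probe.
    """
    from collections import Counter

    k = len(sequences.iloc[0])
    n = len(genome)
    text = genome.sequence + (genome.sequence[: k - 1] if genome.circular else "")
    counter = Counter(text[i : i + k] for i in range(n if genome.circular else n - k + 1))
    out = np.empty(len(sequences), dtype=int)
    for i, seq in enumerate(sequences):
        rc = reverse_complement(seq)
        out[i] = counter[seq] + (counter[rc] if rc != seq else 0)
    return out


def flag_nonunique(
    probes: pd.DataFrame, genome: GenomeSequence, flank_bp: int = 1000
) -> pd.DataFrame:
    """Screen a ProbeSet for genome uniqueness and flag exclusion zones.

    Sets ``n_genome_matches`` for every probe and ``excluded = True`` for
    every probe matching >= 2 loci as well as every probe whose middle lies
    within ``flank_bp`` (circular distance, inclusive) of such a probe's
    middle. Returns a new DataFrame; the input is not modified.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    out = probes.copy()
    lengths = out["sequence"].str.len()
    if len(out) and lengths.nunique() == 1:
        out["n_genome_matches"] = _bulk_match_counts(out["sequence"], genome)
    else:
        out["n_genome_matches"] = [
            count_genome_matches(s, genome) for s in out["sequence"]
        ]
    n = len(genome)
    middles = out["middle"].to_numpy(dtype=int)
    bad = middles[out["n_genome_matches"].to_numpy() >= 2]
    if bad.size == 0:
        out["excluded"] = False
        return out
    d = circular_distance(middles[:, None], bad[None, :], n).min(axis=1)
    out["excluded"] = d <= flank_bp
    return out


def count_gatc(genome: GenomeSequence, center: int, window_bp: int = 500) -> int:
    """Number of GATC occurrences whose start lies in the circular window
    ``[center - window_bp//2, center + window_bp//2)``.

    GATC is its own reverse complement, so counting one strand is complete.
    """
    if window_bp < 4:
        raise ValueError("window_bp must be >= 4")
    n = len(genome)
    w = min(window_bp, n)
    lo = (center - w // 2) % n
    # 3 extra bases so occurrences starting near the window end are seen
    if genome.circular:
        text = genome.fetch(lo, w) + genome.fetch((lo + w) % n, min(3, n))
    else:
        text = genome.sequence[lo : lo + w + 3]
    count = 0
    i = text.find("GATC")
    while i != -1:
        if i < w:
            count += 1
        i = text.find("GATC", i + 1)
    return count


def gatc_context(
    probes: pd.DataFrame, genome: GenomeSequence, window_bp: int = 500
) -> pd.DataFrame:
    """Per-probe GATC counts in a centered window (GatcContext table with
    columns ``probe_id, gatc_count, window_bp``)."""
    if window_bp < 4:
        raise ValueError("window_bp must be >= 4")
    n = len(genome)
    starts = []
    text = genome.sequence + (genome.sequence[:3] if genome.circular else "")
    i = text.find("GATC")
    while i != -1:
        if i < n:
            starts.append(i)
        i = text.find("GATC", i + 1)
    starts_arr = np.array(sorted(starts), dtype=int)
    middles = probes["middle"].to_numpy(dtype=int)
    w = min(window_bp, n)
    lo = (middles - w // 2) % n
    if starts_arr.size:
        doubled = np.concatenate([starts_arr, starts_arr + n])
        counts = np.searchsorted(doubled, lo + w) - np.searchsorted(doubled, lo)
    else:
        counts = np.zeros(middles.size, dtype=int)
    return pd.DataFrame(
        {
            "probe_id": probes["probe_id"].to_numpy(),
            "gatc_count": counts,
            "window_bp": window_bp,
        }
    )


def group_signal_by_gatc(
    track: pd.DataFrame,
    context: pd.DataFrame,
    excluded_mask: pd.Series | None = None,
) -> pd.DataFrame:
    """Boxplot-style summary of log2 ratios grouped by local GATC count.

    ``excluded_mask`` is a boolean Series indexed like ``track`` rows by
    ``probe_id`` (True = drop). One row per observed GATC count with the
    five-number summary; whiskers follow the Tukey 1.5 x IQR convention.
    Group sizes sum to the number of included probes.
    """
    merged = track.merge(context[["probe_id", "gatc_count"]], on="probe_id")
    if excluded_mask is not None:
        mask = excluded_mask.reindex(merged["probe_id"]).fillna(False).to_numpy(dtype=bool)
        merged = merged.loc[~mask]
    if merged.empty:
        raise ValueError("no included probes to group")

    rows = []
    for count, grp in merged.groupby("gatc_count"):
        vals = grp["log2_ratio"].to_numpy()
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        in_lo = vals[vals >= q1 - 1.5 * iqr]
        in_hi = vals[vals <= q3 + 1.5 * iqr]
        rows.append(
            {
                "gatc_count": int(count),
                "n": len(vals),
                "q1": q1,
                "median": med,
                "q3": q3,
                "lo_whisker": in_lo.min(),
                "hi_whisker": in_hi.max(),
            }
        )
    return pd.DataFrame(rows).sort_values("gatc_count", ignore_index=True)
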