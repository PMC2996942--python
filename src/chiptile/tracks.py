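"""Whole-chromosome summaries: moving-window binding tracks, top-N overlap
(Venn) analysis, and threshold-based locus extraction for browser export.

The moving-window track sums positive log2 ratios in 60-kb windows stepped
every 1 kb around the circular chromosome — the scale of the hemimethylated
tract trailing a replication fork — so regional binding (e.g. a SeqA maximum
at the replication origin) stands out above probe-level noise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def moving_window_sum(
    track: pd.DataFrame,
    genome_length: int,
    window_bp: int = 60000,
    step_bp: int = 1000,
    lowest_tail: bool = False,
) -> pd.DataFrame:
    """Sum of positive log2 ratios per circular window.

    Window centers lie on the step grid ``0, step_bp, 2*step_bp, ...``; each
    window covers ``[center - window_bp//2, center + window_bp//2)`` and sums
    ``max(log2, 0)`` over probes whose middle falls inside. With
    ``lowest_tail`` the sign selection is inverted (``max(-log2, 0)``), for
    depletion analyses. Returns a WindowTrack DataFrame with columns
    ``center, value, window_bp, step_bp``.
    """
    if step_bp <= 0:
        raise ValueError("step_bp must be positive")
    if not (0 < window_bp <= genome_length):
        raise ValueError("window_bp must be in (0, genome_length]")
    ordered = track.sort_values("middle")
    middles = ordered["middle"].to_numpy(dtype=int)
    v = ordered["log2_ratio"].to_numpy(dtype=float)
    pos = np.maximum(-v if lowest_tail else v, 0.0)

    centers = np.arange(0, genome_length, step_bp, dtype=int)
    doubled_mid = np.concatenate([middles, middles + genome_length])
    csum = np.concatenate([[0.0], np.cumsum(np.concatenate([pos, pos]))])
    lo = (centers - window_bp // 2) % genome_length
    hi = lo + window_bp
    values = csum[np.searchsorted(doubled_mid, hi)] - csum[np.searchsorted(doubled_mid, lo)]
    return pd.DataFrame(
        {"center": centers, "value": values, "window_bp": window_bp, "step_bp": step_bp}
    )


def top_n_cutoff(
    track: pd.DataFrame, n: int, lowest: bool = False
) -> tuple[float, pd.DataFrame]:
    """Cutoff selecting the ~n most extreme probes.

    The cutoff is the value of the n-th ranked probe (descending, or
    ascending with ``lowest``); every probe at or beyond the cutoff is
    selected, so ties at the cutoff inflate the selection beyond n.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(track):
        raise ValueError(f"n ({n}) exceeds the number of retained probes ({len(track)})")
    v = track["log2_ratio"].to_numpy()
    if lowest:
        cutoff = float(np.sort(v)[n - 1])
        selected = track.loc[v <= cutoff]
    else:
        cutoff = float(np.sort(v)[::-1][n - 1])
        selected = track.loc[v >= cutoff]
    return cutoff, selected.reset_index(drop=True)


@dataclass(frozen=True)
class OverlapResult:
    """Venn counts for two top-N probe selections."""

    n_a: int
    n_b: int
    n_overlap: int
    cutoff_a: float
    cutoff_b: float


def overlap_top_sets(
    track_a: pd.DataFrame,
    track_b: pd.DataFrame,
    n: int,
    lowest_a: bool = False,
    lowest_b: bool = False,
) -> OverlapResult:
    """How often the signal is beyond the top-N cutoff at the same probes in
    two data sets (both tracks must share a probe universe)."""
    universe_a = set(track_a["probe_id"])
    universe_b = set(track_b["probe_id"])
    if not universe_a & universe_b:
        raise ValueError("tracks have disjoint probe universes")
    cutoff_a, sel_a = top_n_cutoff(track_a, n, lowest=lowest_a)
    cutoff_b, sel_b = top_n_cutoff(track_b, n, lowest=lowest_b)
    ids_a = set(sel_a["probe_id"])
    ids_b = set(sel_b["probe_id"])
    return OverlapResult(
        n_a=len(ids_a),
        n_b=len(ids_b),
        n_overlap=len(ids_a & ids_b),
        cutoff_a=cutoff_a,
        cutoff_b=cutoff_b,
    )


def export_loci(
    track: pd.DataFrame,
    genome_length: int,
    threshold: float = 0.5,
    flank_bp: int = 1000,
) -> list[tuple[int, int]]:
    """Extract loci around probes above a log2 threshold.

    Each probe with ``log2_ratio > threshold`` contributes the circular
    interval ``[middle - flank_bp, middle + flank_bp)``; overlapping or
    touching intervals are merged. Returns sorted, pairwise disjoint
    intervals ``(start, end)`` with ``0 <= start < genome_length`` and
    ``start < end <= start + genome_length`` (an interval whose end exceeds
    the genome length wraps the origin).
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    middles = np.sort(
        track.loc[track["log2_ratio"] > threshold, "middle"].to_numpy(dtype=int)
    )
    if middles.size == 0:
        return []
    span = 2 * flank_bp
    if span >= genome_length:
        return [(0, genome_length)]
    starts = (middles - flank_bp) % genome_length
    order = np.argsort(starts)
    starts = starts[order]
    intervals = [(int(s), int(s) + span) for s in starts]

    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    # wrap: the last interval may reach around past the first one
    if len(merged) >= 2 and merged[-1][1] >= genome_length:
        wrapped_end = merged[-1][1] - genome_length
        while len(merged) >= 2 and merged[0][0] <= wrapped_end:
            first = merged.pop(0)
            merged[-1][1] = max(merged[-1][1], first[1] + genome_length)
            wrapped_end = merged[-1][1] - genome_length
    if len(merged) == 1 and merged[0][1] - merged[0][0] >= genome_length:
        return [(0, genome_length)]
    return [(s, e) for s, e in merged]
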