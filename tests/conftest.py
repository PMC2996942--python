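"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def make_track(
    values,
    spacing: int = 150,
    condition: str = "ip",
    replicate: int = 1,
    start: int = 30,
) -> pd.DataFrame:
    """RatioTrack DataFrame from a list of log2 values at regular spacing."""
    values = list(values)
    return pd.DataFrame(
        {
            "probe_id": [f"P{i:06d}" for i in range(len(values))],
            "middle": [start + i * spacing for i in range(len(values))],
            "log2_ratio": values,
            "condition": condition,
            "replicate": replicate,
        }
    )


def process_replicates(scans, probes, condition="ip"):
    """Standard per-replicate processing chain used across tests."""
    from chiptile import compute_log_ratios, normalize_to_array_average, subtract_background

    tracks = []
    for r, (scan, _truth) in enumerate(scans, start=1):
        net = subtract_background(scan)
        track = compute_log_ratios(net, probes, condition=condition, replicate=r)
        tracks.append(normalize_to_array_average(track))
    return tracks


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_count_matches(probe: str, genome_seq: str) -> int:
    """Naive circular two-strand matcher: check every rotation start."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(probe))
    n, k = len(genome_seq), len(probe)
    doubled = genome_seq + genome_seq[: k - 1]
    count = 0
    for i in range(n):
        window = doubled[i : i + k]
        if window == probe or window == rc:
            count += 1
    return count


def brute_neighbor_runs(values, middles, genome_length, threshold, min_run, max_gap):
    """Exhaustive circular run enumeration for the neighbor rule.

    ``values`` is (n_probes, n_replicates); returns runs as lists of probe
    indices in circular order.
    """
    values = np.asarray(values)
    middles = np.asarray(middles)
    n = len(middles)
    qual = (values > threshold).all(axis=1)

    def adj(i, j):
        return (middles[j] - middles[i]) % genome_length <= max_gap

    if qual.all() and all(adj(i, (i + 1) % n) for i in range(n)):
        return [list(range(n))] if n >= min_run else []
    runs = []
    for i in range(n):
        prev = (i - 1) % n
        if qual[i] and not (qual[prev] and adj(prev, i)):
            run = [i]
            j = i
            while True:
                nj = (j + 1) % n
                if nj != i and qual[nj] and adj(j, nj):
                    run.append(nj)
                    j = nj
                else:
                    break
            if len(run) >= min_run:
                runs.append(run)
    return runs


def brute_summit_groups(values, middles, genome_length, summit_thr, flank_thr, max_gap):
    """Direct application of the summit rule plus gap-based grouping."""
    values = np.asarray(values, dtype=float)
    middles = np.asarray(middles)
    n = len(values)
    summits = [
        i
        for i in range(n)
        if values[i] > summit_thr
        and values[(i - 1) % n] > flank_thr
        and values[(i + 1) % n] > flank_thr
    ]
    if not summits:
        return []
    m = len(summits)

    def adj(a, b):
        return (middles[summits[b]] - middles[summits[a]]) % genome_length <= max_gap

    if m == 1:
        return [[summits[0]]]
    if all(adj(i, (i + 1) % m) for i in range(m)):
        return [summits]
    groups = []
    for i in range(m):
        prev = (i - 1) % m
        if not adj(prev, i):
            group = [summits[i]]
            j = i
            while True:
                nj = (j + 1) % m
                if nj != i and adj(j, nj):
                    group.append(summits[nj])
                    j = nj
                else:
                    break
            groups.append(group)
    return groups


@pytest.fixture(scope="session")
def small_genome():
    from chiptile import generate_genome

    return generate_genome(20000, gatc_density=0.0043, seed=11)
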