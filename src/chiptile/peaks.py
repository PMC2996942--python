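"""Target and peak detection on probe-level log2 ratio tracks.

Two detection rules are implemented:

* **neighbor rule** — runs of two or more genomically adjacent probes whose
  log2 ratio exceeds a threshold (default 0.5) in *every* replicate;
* **summit rule** — a probe above a summit threshold (default 1.0) whose
  immediate left and right neighbors both exceed a flank threshold
  (default 0.5), on a single merged track.

Called targets can be re-tested on condition-subtracted tracks (e.g.
heat-shock minus non-heat-shock) and classified against reference target
lists by circular anchor distance.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PeakCallConfig:
    """Thresholds and distances for both detection rules.

    ``neighbor_threshold``/``min_run`` drive the neighbor rule,
    ``summit_threshold``/``flank_threshold`` the summit rule. ``max_gap_bp``
    bounds the center-to-center distance between probes considered adjacent
    (~3x the 150-bp probe spacing by default), so gaps left by excluded
    probes break runs. ``match_distance_bp`` is the circular distance within
    which a call and a reference position count as the same binding site.
    """

    neighbor_threshold: float = 0.5
    min_run: int = 2
    summit_threshold: float = 1.0
    flank_threshold: float = 0.5
    max_gap_bp: int = 500
    match_distance_bp: int = 2000

    def __post_init__(self) -> None:
        for name in ("neighbor_threshold", "summit_threshold", "flank_threshold"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.min_run < 2:
            raise ValueError("min_run must be >= 2 (two or more neighboring probes)")
        if self.max_gap_bp <= 0 or self.match_distance_bp < 0:
            raise ValueError("distances must be positive")


@dataclass
class TargetCall:
    """One called binding region.

    ``start``/``end`` are the first and last qualifying probe middles;
    ``end`` may exceed the genome length for calls wrapping the origin
    (``start <= end`` always holds after this unwrapping). ``anchor`` is the
    middle of the maximal probe, in ``[0, genome_length)``.
    """

    start: int
    end: int
    anchor: int
    score: float
    n_probes: int
    classification: str = "unclassified"
    matched_name: str | None = None
    probe_ids: tuple[str, ...] = field(default_factory=tuple)


def _aligned_values(tracks: list[pd.DataFrame]) -> pd.DataFrame:
    """Inner-join replicate tracks on probe_id; columns ``probe_id, middle,
    v1..vk`` sorted by middle."""
    base = tracks[0][["probe_id", "middle", "log2_ratio"]].rename(
        columns={"log2_ratio": "v1"}
    )
    for i, t in enumerate(tracks[1:], start=2):
        base = base.merge(
            t[["probe_id", "log2_ratio"]].rename(columns={"log2_ratio": f"v{i}"}),
            on="probe_id",
        )
    return base.sort_values("middle", ignore_index=True)


def _circular_runs(
    qualifies: np.ndarray, middles: np.ndarray, genome_length: int, max_gap_bp: int
) -> list[list[int]]:
    """Maximal runs of qualifying probes in circular genomic order, where
    consecutive (adjacent retained) probes must be <= max_gap_bp apart."""
    n = qualifies.size
    if n == 0:
        return []
    gap_ok = np.empty(n, dtype=bool)  # gap_ok[i]: probe i connects to i+1 (mod n)
    nxt = np.roll(middles, -1)
    gap_ok[:] = ((nxt - middles) % genome_length) <= max_gap_bp
    if n == 1:
        return [[0]] if qualifies[0] else []

    runs: list[list[int]] = []
    current: list[int] = []
    for i in range(n):
        if qualifies[i]:
            current.append(i)
        if not qualifies[i] or not gap_ok[i]:
            if qualifies[i] and current:
                runs.append(current)
                current = []
            elif not qualifies[i] and current:
                runs.append(current)
                current = []
    if current:
        runs.append(current)
    # wrap: last run ends at n-1, first run starts at 0, both qualify and the
    # wrap gap is fine -> merge (unless they are the same run = full circle)
    if (
        len(runs) >= 2
        and runs[0][0] == 0
        and runs[-1][-1] == n - 1
        and qualifies[n - 1]
        and qualifies[0]
        and gap_ok[n - 1]
    ):
        runs[0] = runs.pop() + runs[0]
    return runs


def _run_to_call(
    run: list[int],
    middles: np.ndarray,
    mean_signal: np.ndarray,
    probe_ids: np.ndarray,
    genome_length: int,
) -> TargetCall:
    # unwrap coordinates: positions must be non-decreasing along the run
    pos = middles[run].astype(int).copy()
    for j in range(1, len(pos)):
        if pos[j] < pos[j - 1]:
            pos[j:] += genome_length
    sig = mean_signal[run]
    best = int(np.argmax(sig))  # argmax takes the first (leftmost) maximum
    return TargetCall(
        start=int(pos[0]),
        end=int(pos[-1]),
        anchor=int(middles[run[best]]),
        score=float(sig[best]),
        n_probes=len(run),
        probe_ids=tuple(probe_ids[run]),
    )


def call_targets_neighbor_rule(
    tracks: list[pd.DataFrame], config: PeakCallConfig, genome_length: int
) -> list[TargetCall]:
    """Runs of >= ``min_run`` adjacent probes above ``neighbor_threshold`` in
    every replicate become one target each.

    The span covers the first to last qualifying probe middle; the anchor is
    the probe with the maximal mean signal across replicates (leftmost on
    ties).
    """
    if len(tracks) < 2:
        raise ValueError("the neighbor rule requires at least 2 replicate tracks")
    aligned = _aligned_values(tracks)
    value_cols = [c for c in aligned.columns if c.startswith("v")]
    values = aligned[value_cols].to_numpy()
    qualifies = (values > config.neighbor_threshold).all(axis=1)
    middles = aligned["middle"].to_numpy(dtype=int)
    probe_ids = aligned["probe_id"].to_numpy()
    mean_signal = values.mean(axis=1)
    runs = _circular_runs(qualifies, middles, genome_length, config.max_gap_bp)
    return [
        _run_to_call(run, middles, mean_signal, probe_ids, genome_length)
        for run in runs
        if len(run) >= config.min_run
    ]


def call_peaks_summit_rule(
    track: pd.DataFrame, config: PeakCallConfig, genome_length: int
) -> list[TargetCall]:
    """Summit peaks on a single merged track: a probe above
    ``summit_threshold`` whose immediate circular neighbors both exceed
    ``flank_threshold``. Qualifying summits <= ``max_gap_bp`` apart merge
    into one call anchored at the maximal summit."""
    if len(track) < 3:
        raise ValueError("the summit rule needs at least 3 probes")
    ordered = track.sort_values("middle", ignore_index=True)
    v = ordered["log2_ratio"].to_numpy()
    middles = ordered["middle"].to_numpy(dtype=int)
    probe_ids = ordered["probe_id"].to_numpy()
    left = np.roll(v, 1)
    right = np.roll(v, -1)
    summit = (
        (v > config.summit_threshold)
        & (left > config.flank_threshold)
        & (right > config.flank_threshold)
    )
    idx = np.flatnonzero(summit)
    if idx.size == 0:
        return []
    # group summits by circular gap between consecutive summit middles
    groups = _circular_runs(
        np.ones(idx.size, dtype=bool), middles[idx], genome_length, config.max_gap_bp
    )
    calls = []
    for g in groups:
        run = [int(idx[j]) for j in g]
        calls.append(_run_to_call(run, middles, v, probe_ids, genome_length))
    return calls


def filter_targets_by_control(
    targets: list[TargetCall],
    subtracted_tracks: list[pd.DataFrame],
    config: PeakCallConfig,
    genome_length: int,
) -> list[TargetCall]:
    """Keep targets for which the neighbor rule still holds within their span
    on condition-subtracted replicate tracks.

    Survivors keep their original spans; scores are recomputed as the maximal
    mean subtracted signal among qualifying probes. The output is always a
    subset of the input.
    """
    if not targets:
        return []
    if len(subtracted_tracks) < 2:
        raise ValueError("control filtering requires at least 2 subtracted tracks")
    aligned = _aligned_values(subtracted_tracks)
    value_cols = [c for c in aligned.columns if c.startswith("v")]
    available = set(aligned["probe_id"])
    by_id = aligned.set_index("probe_id")

    survivors: list[TargetCall] = []
    for target in targets:
        missing = [p for p in target.probe_ids if p not in available]
        if missing:
            raise ValueError(
                f"target at {target.anchor} references probes absent from the "
                f"subtracted tracks, e.g. {missing[:3]}"
            )
        sub = by_id.loc[list(target.probe_ids)].reset_index()
        sub = sub.sort_values("middle", ignore_index=True)
        values = sub[value_cols].to_numpy()
        qualifies = (values > config.neighbor_threshold).all(axis=1)
        middles = sub["middle"].to_numpy(dtype=int)
        # span probes only: linear adjacency within the span (no wrap)
        runs: list[list[int]] = []
        current: list[int] = []
        for i in range(len(sub)):
            connected = (
                current
                and ((middles[i] - middles[current[-1]]) % genome_length)
                <= config.max_gap_bp
            )
            if qualifies[i] and (not current or connected):
                current.append(i)
            elif qualifies[i]:
                runs.append(current)
                current = [i]
            else:
                if current:
                    runs.append(current)
                current = []
        if current:
            runs.append(current)
        good = [r for r in runs if len(r) >= config.min_run]
        if good:
            qual_scores = values.mean(axis=1)[qualifies]
            survivors.append(replace(target, score=float(qual_scores.max())))
    return survivors


# ---------------------------------------------------------------------------
# classification against reference lists
# ---------------------------------------------------------------------------


def _check_references(refs: list[tuple[int, str]], label: str) -> None:
    positions = [p for p, _ in refs]
    if len(set(positions)) != len(positions):
        dup = sorted({p for p in positions if positions.count(p) > 1})
        raise ValueError(f"duplicate reference positions in {label} list: {dup}")


def classify_targets(
    targets: list[TargetCall],
    known_positions: list[tuple[int, str]],
    chip_only_positions: list[tuple[int, str]],
    config: PeakCallConfig,
    genome_length: int,
) -> tuple[list[TargetCall], dict[str, int], pd.DataFrame]:
    """Classify calls against reference lists by circular anchor distance.

    A target matches a reference entry iff the circular distance between its
    anchor and the (1-based) reference position is <= ``match_distance_bp``.
    Assignment is nearest-first and each reference entry consumes at most one
    target; previously described sites take precedence over ChIP-only sites,
    and unmatched targets are ``novel``.

    Returns annotated targets, per-class counts, and a per-reference
    detection table.
    """
    _check_references(known_positions, "known")
    _check_references(chip_only_positions, "chip_only")

    annotated = [replace(t) for t in targets]
    anchors = np.array([t.anchor for t in annotated], dtype=int)
    taken = np.zeros(len(annotated), dtype=bool)
    detection_rows = []

    for label, refs in (("known", known_positions), ("chip_only", chip_only_positions)):
        assigned_refs: dict[int, int] = {}
        pairs = []
        for ri, (pos1, name) in enumerate(refs):
            pos0 = pos1 - 1
            if anchors.size:
                d = np.abs(anchors - pos0) % genome_length
                d = np.minimum(d, genome_length - d)
                for ti in np.flatnonzero(d <= config.match_distance_bp):
                    pairs.append((int(d[ti]), ri, int(ti)))
        for dist, ri, ti in sorted(pairs):
            if ri in assigned_refs or taken[ti]:
                continue
            assigned_refs[ri] = ti
            taken[ti] = True
            annotated[ti].classification = label
            annotated[ti].matched_name = refs[ri][1]
        for ri, (pos1, name) in enumerate(refs):
            ti = assigned_refs.get(ri)
            detection_rows.append(
                {
                    "list": label,
                    "position": pos1,
                    "name": name,
                    "detected": ti is not None,
                    "anchor_1based": annotated[ti].anchor + 1 if ti is not None else pd.NA,
                    "score": annotated[ti].score if ti is not None else np.nan,
                }
            )

    for t, was_taken in zip(annotated, taken):
        if not was_taken:
            t.classification = "novel"
    counts = {
        "known": int(sum(t.classification == "known" for t in annotated)),
        "chip_only": int(sum(t.classification == "chip_only" for t in annotated)),
        "novel": int(sum(t.classification == "novel" for t in annotated)),
    }
    return annotated, counts, pd.DataFrame(detection_rows)
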