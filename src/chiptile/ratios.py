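"""Two-channel signal processing: background subtraction, log2 ratios,
array-average normalization, replicate merging, condition subtraction, and
qPCR relative quantification.

A RatioTrack is a DataFrame with columns ``probe_id, middle, log2_ratio,
condition, replicate`` (the ``replicate`` column is dropped after merging).
Probes removed by a filter are absent from the track, never zero-filled.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TRACK_COLUMNS = ["probe_id", "middle", "log2_ratio", "condition", "replicate"]


def subtract_background(scan: pd.DataFrame) -> pd.DataFrame:
    """Per-channel net intensity ``fg - bg``; probes with net <= 0 in either
    channel are removed from the table (a zero net has no defined ratio).

    Returns a DataFrame with columns ``probe_id, ip_net, ref_net``. The
    number of removed probes is logged.
    """
    for col in ("ip_fg", "ip_bg", "ref_fg", "ref_bg"):
        if (scan[col] < 0).any():
            raise ValueError(f"negative intensities in column {col}")
    ip_net = scan["ip_fg"] - scan["ip_bg"]
    ref_net = scan["ref_fg"] - scan["ref_bg"]
    keep = (ip_net > 0) & (ref_net > 0)
    removed = int((~keep).sum())
    if removed:
        log.info("background subtraction removed %d of %d probes", removed, len(scan))
    return pd.DataFrame(
        {
            "probe_id": scan.loc[keep, "probe_id"].to_numpy(),
            "ip_net": ip_net[keep].to_numpy(dtype=float),
            "ref_net": ref_net[keep].to_numpy(dtype=float),
        }
    )


def compute_log_ratios(
    net: pd.DataFrame,
    probes: pd.DataFrame,
    condition: str = "ip_vs_input",
    replicate: int = 1,
) -> pd.DataFrame:
    """log2(IP net / reference net) per probe, annotated with genomic middle
    positions from the probe table."""
    if (net["ip_net"] <= 0).any() or (net["ref_net"] <= 0).any():
        raise ValueError("net intensities must be positive; filter first")
    merged = net.merge(probes[["probe_id", "middle"]], on="probe_id", how="left")
    if merged["middle"].isna().any():
        missing = merged.loc[merged["middle"].isna(), "probe_id"].head().tolist()
        raise ValueError(f"probes absent from probe table, e.g. {missing}")
    track = pd.DataFrame(
        {
            "probe_id": merged["probe_id"],
            "middle": merged["middle"].astype(int),
            "log2_ratio": np.log2(merged["ip_net"] / merged["ref_net"]),
            "condition": condition,
            "replicate": replicate,
        },
        columns=TRACK_COLUMNS,
    )
    return track.sort_values("middle", ignore_index=True)


def normalize_to_array_average(track: pd.DataFrame) -> pd.DataFrame:
    """Center the track so the mean log2 ratio over retained probes is 0.

    Equivalent to dividing every ratio by the array-wide geometric mean.
    Idempotent; variance is unchanged.
    """
    if track.empty:
        raise ValueError("cannot normalize an empty track")
    out = track.copy()
    out["log2_ratio"] = out["log2_ratio"] - out["log2_ratio"].mean()
    return out


def merge_replicates(tracks: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-probe arithmetic mean of normalized log2 ratios over replicates.

    All tracks must carry the same condition; probes missing in any replicate
    are dropped (intersection semantics). The merged track has no
    ``replicate`` column.
    """
    if not tracks:
        raise ValueError("no tracks to merge")
    conditions = {t["condition"].iloc[0] for t in tracks if len(t)}
    if len(conditions) > 1:
        raise ValueError(f"cannot merge mixed conditions: {sorted(conditions)}")
    condition = conditions.pop() if conditions else ""
    merged = tracks[0][["probe_id", "middle", "log2_ratio"]]
    for i, t in enumerate(tracks[1:], start=2):
        merged = merged.merge(
            t[["probe_id", "log2_ratio"]], on="probe_id", suffixes=("", f"_{i}")
        )
    value_cols = [c for c in merged.columns if c.startswith("log2_ratio")]
    out = pd.DataFrame(
        {
            "probe_id": merged["probe_id"],
            "middle": merged["middle"],
            "log2_ratio": merged[value_cols].mean(axis=1),
            "condition": condition,
        }
    )
    return out.sort_values("middle", ignore_index=True)


def subtract_condition(
    track_a: pd.DataFrame, track_b: pd.DataFrame
) -> pd.DataFrame:
    """Replicate-wise log2 difference a - b (e.g. heat-shock minus control).

    Tracks are matched on ``(probe_id, replicate)``; the replicate structure
    must correspond exactly (index-matched pairing).
    """
    reps_a = set(track_a["replicate"].unique())
    reps_b = set(track_b["replicate"].unique())
    if reps_a != reps_b:
        raise ValueError(
            f"unmatched replicate structure: {sorted(reps_a)} vs {sorted(reps_b)}"
        )
    merged = track_a.merge(
        track_b[["probe_id", "replicate", "log2_ratio"]],
        on=["probe_id", "replicate"],
        suffixes=("_a", "_b"),
    )
    cond = (
        f"{track_a['condition'].iloc[0]}-{track_b['condition'].iloc[0]}"
        if len(merged)
        else "difference"
    )
    out = pd.DataFrame(
        {
            "probe_id": merged["probe_id"],
            "middle": merged["middle"],
            "log2_ratio": merged["log2_ratio_a"] - merged["log2_ratio_b"],
            "condition": cond,
            "replicate": merged["replicate"],
        },
        columns=TRACK_COLUMNS,
    )
    return out.sort_values(["replicate", "middle"], ignore_index=True)


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------


@dataclass
class QpcrMeasurement:
    """Ct triplicate for one genomic region (TaqMan-style assay)."""

    region: str
    cts: tuple[float, ...]

    def __post_init__(self) -> None:
        self.cts = tuple(float(c) for c in self.cts if not math.isnan(float(c)))
        if len(self.cts) < 2:
            raise ValueError(
                f"{self.region}: need at least 2 usable Ct values, got {len(self.cts)}"
            )
        if any(c <= 0 for c in self.cts):
            raise ValueError(f"{self.region}: Ct values must be positive")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.cts))

    @property
    def sd_ct(self) -> float:
        return float(np.std(self.cts, ddof=1))

    @property
    def quantity(self) -> float:
        """Relative template quantity assuming perfect doubling: 2^(-mean Ct)."""
        return 2.0 ** (-self.mean_ct)


def qpcr_relative(
    sample: QpcrMeasurement, reference_region: QpcrMeasurement
) -> tuple[float, float]:
    """Template quantity of ``sample`` relative to a reference region.

    ratio = 2^(Ct_ref - Ct_sample) with first-order error propagation from
    the triplicate Ct standard deviations:
    sd(ratio) = ratio * ln(2) * sqrt(sd_s^2 + sd_r^2).
    """
    ratio = sample.quantity / reference_region.quantity
    sd = ratio * math.log(2.0) * math.hypot(sample.sd_ct, reference_region.sd_ct)
    return ratio, sd
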