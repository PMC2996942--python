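"""Tab-delimited, BED and bedGraph input/output.

Tabular reports use 1-based inclusive genomic positions; BED and bedGraph
use their standard 0-based half-open convention. Files written by the
pipeline carry ``#``-prefixed provenance headers (seed, config hash) which
every reader here skips.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .peaks import TargetCall


def write_table(
    df: pd.DataFrame, path: str | Path, meta: dict[str, object] | None = None
) -> None:
    """Write a DataFrame as TSV with optional ``# key: value`` header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_track(track: pd.DataFrame, path: str | Path, meta=None) -> None:
    """RatioTrack as TSV: probe_id, chrom(optional), middle_1based, log2_ratio."""
    out = track.copy()
    out["middle_1based"] = out["middle"].astype(int) + 1
    cols = ["probe_id", "middle_1based", "log2_ratio"]
    if "condition" in out.columns:
        cols.append("condition")
    if "replicate" in out.columns:
        cols.append("replicate")
    write_table(out[cols], path, meta)


def read_track(path: str | Path, condition: str = "", replicate: int = 1) -> pd.DataFrame:
    df = read_table(path)
    out = pd.DataFrame(
        {
            "probe_id": df["probe_id"],
            "middle": df["middle_1based"].astype(int) - 1,
            "log2_ratio": df["log2_ratio"],
            "condition": df["condition"] if "condition" in df.columns else condition,
            "replicate": df["replicate"] if "replicate" in df.columns else replicate,
        }
    )
    return out


def write_probes(probes: pd.DataFrame, path: str | Path, meta=None) -> None:
    """Probe table as TSV: probe_id, sequence, chrom, middle_1based plus any
    screening columns (n_genome_matches, excluded)."""
    out = probes.copy()
    out["middle_1based"] = out["middle"].astype(int) + 1
    cols = ["probe_id", "sequence", "chrom", "middle_1based"] + [
        c for c in ("n_genome_matches", "excluded") if c in out.columns
    ]
    write_table(out[cols], path, meta)


def read_probes(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    df["middle"] = df["middle_1based"].astype(int) - 1
    return df.drop(columns=["middle_1based"])


def write_targets(targets: list[TargetCall], path: str | Path, meta=None) -> None:
    rows = [
        {
            "anchor_1based": t.anchor + 1,
            "start_1based": t.start + 1,
            "end_1based": t.end + 1,
            "score": round(t.score, 6),
            "n_probes": t.n_probes,
            "classification": t.classification,
            "matched_name": t.matched_name or "",
        }
        for t in targets
    ]
    cols = [
        "anchor_1based",
        "start_1based",
        "end_1based",
        "score",
        "n_probes",
        "classification",
        "matched_name",
    ]
    write_table(pd.DataFrame(rows, columns=cols), path, meta)


def write_bed(
    intervals: list[tuple[int, int]],
    path: str | Path,
    chrom: str,
    genome_length: int,
    names: list[str] | None = None,
) -> None:
    """Interval list as BED (0-based half-open); intervals wrapping the
    circular origin are split into two lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# BED: 0-based half-open coordinates\n")
        for i, (start, end) in enumerate(intervals):
            name = names[i] if names else f"region_{i + 1}"
            if end <= genome_length:
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{genome_length}\t{name}\n")
                fh.write(f"{chrom}\t0\t{end - genome_length}\t{name}\n")


def write_bedgraph(
    window_track: pd.DataFrame, path: str | Path, chrom: str, genome_length: int
) -> None:
    """WindowTrack as bedGraph; each window's value is reported over the step
    interval anchored at the window center."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    step = int(window_track["step_bp"].iloc[0]) if len(window_track) else 1
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="window_sum"\n')
        for center, value in zip(window_track["center"], window_track["value"]):
            end = min(int(center) + step, genome_length)
            fh.write(f"{chrom}\t{int(center)}\t{end}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# reference target lists
# ---------------------------------------------------------------------------


def read_reference_list(path: str | Path) -> list[tuple[int, str]]:
    """Read a reference target list (TSV with 1-based ``position`` and
    ``name`` columns; extra columns ignored)."""
    df = read_table(path)
    return [(int(p), str(n)) for p, n in zip(df["position"], df["name"])]


def bundled_reference_path(which: str) -> Path:
    """Path to a bundled sigma32 reference list: ``known`` (previously
    described sites), ``chip_only`` (sites reported only by the earlier
    ChIP-chip screen) or ``new_candidates``."""
    names = {
        "known": "sigma32_known_targets.tsv",
        "chip_only": "sigma32_chip_only_targets.tsv",
        "new_candidates": "sigma32_new_candidates.tsv",
    }
    if which not in names:
        raise ValueError(f"unknown reference list {which!r}; choose from {sorted(names)}")
    return Path(str(resources.files("chiptile").joinpath("data", names[which])))
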