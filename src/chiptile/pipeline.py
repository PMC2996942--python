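"""End-to-end orchestration: simulate -> screen -> process -> call -> summarize.

A single YAML config drives the whole run. Stages execute in a fixed order
(probe exclusion -> background filter -> ratio -> normalize -> merge /
per-replicate -> call -> control filter -> classify -> window/overlap);
every output file records the seed and a hash of the resolved config, so a
rerun with the same config is byte-identical.
"""
from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .peaks import PeakCallConfig, TargetCall, call_targets_neighbor_rule, classify_targets, filter_targets_by_control
from .ratios import compute_log_ratios, merge_replicates, normalize_to_array_average, subtract_background, subtract_condition
from .simulate import ArtifactConfig, FeatureAnnotation, design_probes, generate_genome, place_features, planted_features, simulate_arrays
from .probes import flag_nonunique
from .tracks import export_loci, moving_window_sum, overlap_top_sets

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A configuration value failed validation (reported with its key path)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


DEFAULTS: dict[str, dict] = {
    "simulate": {
        "genome_length": 500000,
        "gatc_density": 0.0043,
        "n_duplications": 0,
        "dup_length": 3000,
        "probe_length": 60,
        "spacing": 150,
        "n_transcribed": 10,
        "fork_origin": None,
        "fork_speed_bp_s": 1000.0,
        "hemimeth_time_s": 60.0,
        "replicates": 2,
        "planted_targets": 0,
        "planted_effect_log2": 2.0,
        "control": "none",  # "none" | "knockout"
    },
    "artifacts": {
        "reversal_ip": 1.0,
        "reversal_input": 1.0,
        "spin_column_factor": 1.0,
        "rnase_minutes": 90.0,
        "rna_background_scale": 0.0,
        "noise_sd": 0.3,
        "binding_beta": 1.0,
    },
    "peaks": {
        "neighbor_threshold": 0.5,
        "min_run": 2,
        "summit_threshold": 1.0,
        "flank_threshold": 0.5,
        "max_gap_bp": 500,
        "match_distance_bp": 2000,
    },
    "screen": {"flank_bp": 1000, "gatc_window_bp": 500},
    "window": {"window_bp": 60000, "step_bp": 1000},
    "loci": {"threshold": 0.5, "flank_bp": 1000},
    "overlap": {"n": 1000},
    "references": {"known": None, "chip_only": None},
}

_TOP_LEVEL = {"seed", "out_dir", *DEFAULTS}


@dataclass
class RunConfig:
    """A validated, fully defaulted pipeline configuration."""

    seed: int
    out_dir: str
    data: dict

    @property
    def config_hash(self) -> str:
        payload = {"seed": self.seed, **self.data}
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    def artifact_config(self, seed_offset: int = 0) -> ArtifactConfig:
        return ArtifactConfig(seed=self.seed + seed_offset, **self.data["artifacts"])

    def peak_config(self) -> PeakCallConfig:
        return PeakCallConfig(**self.data["peaks"])


def _check_types(section: str, values: dict, defaults: dict) -> None:
    for key, value in values.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key: {section}.{key}")
        default = defaults[key]
        if default is None or value is None:
            continue
        if isinstance(default, bool) != isinstance(value, bool):
            raise ConfigError(f"{section}.{key}: expected {type(default).__name__}")
        if isinstance(default, (int, float)) and not isinstance(value, (int, float)):
            raise ConfigError(
                f"{section}.{key}: expected a number, got {value!r}"
            )
        if isinstance(default, str) and not isinstance(value, str):
            raise ConfigError(f"{section}.{key}: expected text, got {value!r}")


def validate_config(source: dict | str | Path | None = None) -> RunConfig:
    """Resolve a config mapping or YAML file against the defaults.

    Unknown keys are rejected; type and range violations are reported with
    their key path. An empty config yields the full default run.
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = copy.deepcopy(source)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of sections")

    unknown = set(raw) - _TOP_LEVEL
    if unknown:
        raise ConfigError(f"unknown config key: {sorted(unknown)[0]}")

    seed = raw.pop("seed", 0)
    out_dir = raw.pop("out_dir", "chiptile_out")
    if not isinstance(seed, int) or isinstance(seed, bool):
        raise ConfigError(f"seed: expected an integer, got {seed!r}")

    data = copy.deepcopy(DEFAULTS)
    for section, values in raw.items():
        if not isinstance(values, dict):
            raise ConfigError(f"{section}: expected a mapping of keys")
        _check_types(section, values, DEFAULTS[section])
        data[section].update(values)

    cfg = RunConfig(seed=seed, out_dir=str(out_dir), data=data)
    # range validation, reported with key paths
    try:
        cfg.artifact_config()
    except ValueError as exc:
        raise ConfigError(f"artifacts: {exc}") from exc
    try:
        cfg.peak_config()
    except ValueError as exc:
        raise ConfigError(f"peaks: {exc}") from exc
    sim = data["simulate"]
    if sim["genome_length"] <= 0:
        raise ConfigError("simulate.genome_length: must be positive")
    if sim["control"] not in ("none", "knockout"):
        raise ConfigError("simulate.control: must be 'none' or 'knockout'")
    if not (0 < sim["probe_length"] <= sim["spacing"]):
        raise ConfigError("simulate.spacing: must be >= probe_length (> 0)")
    for section, key in (("screen", "flank_bp"), ("window", "step_bp"), ("overlap", "n")):
        if data[section][key] <= 0 and key != "flank_bp":
            raise ConfigError(f"{section}.{key}: must be positive")
    for which in ("known", "chip_only"):
        path = data["references"][which]
        if path is not None and not Path(path).exists():
            raise ConfigError(f"references.{which}: file not found: {path}")
    return cfg


@dataclass
class RunReport:
    """Per-stage record counts for one pipeline run (the detection funnel)."""

    seed: int
    config_hash: str
    n_probes: int = 0
    n_excluded: int = 0
    n_retained_after_background: int = 0
    n_targets_called: int = 0
    n_targets_after_control: int = 0
    class_counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _process_replicates(
    scans: list, probes: pd.DataFrame, retained_ids: set, condition: str
) -> list[pd.DataFrame]:
    tracks = []
    for r, (scan, _truth) in enumerate(scans, start=1):
        scan_kept = scan.loc[scan["probe_id"].isin(retained_ids)]
        net = subtract_background(scan_kept)
        track = compute_log_ratios(net, probes, condition=condition, replicate=r)
        tracks.append(normalize_to_array_average(track))
    return tracks


def run_pipeline(config: RunConfig | dict | str | Path | None) -> RunReport:
    """Execute the full simulated workflow described by ``config``.

    Writes probe tables, per-replicate and merged tracks, target calls,
    window tracks and the run report into ``config.out_dir`` and returns the
    :class:`RunReport`.
    """
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": cfg.seed, "config_hash": cfg.config_hash}
    report = RunReport(seed=cfg.seed, config_hash=cfg.config_hash)
    sim = cfg.data["simulate"]

    stage = "simulate"
    t0 = time.perf_counter()
    try:
        genome = generate_genome(
            length=sim["genome_length"],
            gatc_density=sim["gatc_density"],
            n_duplications=sim["n_duplications"],
            dup_length=sim["dup_length"],
            seed=cfg.seed,
        )
        if sim["planted_targets"] > 0:
            features, centers = planted_features(
                genome,
                n_targets=sim["planted_targets"],
                effect_log2=sim["planted_effect_log2"],
                binding_beta=cfg.data["artifacts"]["binding_beta"],
                n_transcribed=sim["n_transcribed"],
                seed=cfg.seed + 1,
            )
            report.outputs["planted_centers"] = [int(c) for c in centers]
        else:
            features = place_features(
                genome,
                n_transcribed=sim["n_transcribed"],
                fork_origin=sim["fork_origin"],
                fork_speed_bp_s=sim["fork_speed_bp_s"],
                hemimeth_time_s=sim["hemimeth_time_s"],
                seed=cfg.seed + 1,
            )
        probes = design_probes(genome, sim["probe_length"], sim["spacing"])
        scans = simulate_arrays(
            probes, features, cfg.artifact_config(), replicates=sim["replicates"]
        )
        control_tracks: list[pd.DataFrame] = []
        if sim["control"] == "knockout":
            null_features = FeatureAnnotation(
                genome=genome,
                transcribed_regions=features.transcribed_regions,
                true_binding=np.zeros(len(genome)),
                fork_origin=features.fork_origin,
                tract_length_bp=features.tract_length_bp,
            )
            control_scans = simulate_arrays(
                probes,
                null_features,
                cfg.artifact_config(seed_offset=50021),
                replicates=sim["replicates"],
            )
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "screen"
        screened = flag_nonunique(probes, genome, cfg.data["screen"]["flank_bp"])
        retained_ids = set(screened.loc[~screened["excluded"], "probe_id"])
        report.n_probes = len(screened)
        report.n_excluded = int(screened["excluded"].sum())
        cio.write_probes(screened, out / "probes.tsv", meta)
        genome.to_fasta(out / "genome.fa")
        cio.write_table(scans[0][1], out / "truth.tsv", meta)

        stage = "process"
        tracks = _process_replicates(scans, probes, retained_ids, condition="ip")
        report.n_retained_after_background = min(len(t) for t in tracks)
        merged = merge_replicates(tracks)
        for r, t in enumerate(tracks, start=1):
            cio.write_track(t, out / f"track_rep{r}.tsv", meta)
        cio.write_track(merged, out / "track_merged.tsv", meta)
        if sim["control"] == "knockout":
            control_tracks = _process_replicates(
                control_scans, probes, retained_ids, condition="control"
            )

        stage = "call"
        pcfg = cfg.peak_config()
        calls = call_targets_neighbor_rule(tracks, pcfg, len(genome))
        report.n_targets_called = len(calls)

        stage = "control-filter"
        if control_tracks:
            subtracted = [
                subtract_condition(a, b) for a, b in zip(tracks, control_tracks)
            ]
            survivors = filter_targets_by_control(calls, subtracted, pcfg, len(genome))
        else:
            survivors = calls
        report.n_targets_after_control = len(survivors)

        stage = "classify"
        refs = cfg.data["references"]
        if refs["known"] or refs["chip_only"]:
            known = cio.read_reference_list(refs["known"]) if refs["known"] else []
            chip_only = (
                cio.read_reference_list(refs["chip_only"]) if refs["chip_only"] else []
            )
            survivors, counts, detection = classify_targets(
                survivors, known, chip_only, pcfg, len(genome)
            )
            report.class_counts = counts
            cio.write_table(detection, out / "reference_detection.tsv", meta)
        cio.write_targets(survivors, out / "targets.tsv", meta)

        stage = "window"
        wt = moving_window_sum(
            merged,
            len(genome),
            cfg.data["window"]["window_bp"],
            cfg.data["window"]["step_bp"],
        )
        cio.write_bedgraph(wt, out / "window.bedgraph", genome.name, len(genome))
        loci = export_loci(
            merged,
            len(genome),
            cfg.data["loci"]["threshold"],
            cfg.data["loci"]["flank_bp"],
        )
        cio.write_bed(loci, out / "loci.bed", genome.name, len(genome))

        stage = "overlap"
        if control_tracks:
            n_top = min(cfg.data["overlap"]["n"], len(merged))
            ov = overlap_top_sets(merged, merge_replicates(control_tracks), n_top)
            report.outputs["overlap"] = {
                "n_a": ov.n_a,
                "n_b": ov.n_b,
                "n_overlap": ov.n_overlap,
            }
    except (ConfigError, ValueError, KeyError) as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    report.outputs.setdefault("out_dir", str(out))
    report.to_json(out / "report.json")
    return report
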