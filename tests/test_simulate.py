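"""Synthetic genome/array generator: seeded determinism, planted structure,
artifact arithmetic, and truth recovery."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chiptile import (
    ArtifactConfig,
    FeatureAnnotation,
    GenomeSequence,
    design_probes,
    generate_genome,
    place_features,
    planted_features,
    residual_rna,
    simulate_arrays,
)
from conftest import process_replicates


class TestGenerateGenome:
    def test_zero_density_sequence_has_no_gatc(self):
        g = generate_genome(1000, gatc_density=0.0, n_duplications=0, seed=1)
        assert len(g) == 1000
        assert "GATC" not in (g.sequence + g.sequence[:3])

    def test_duplicated_segments_recoverable_by_exact_search(self):
        g = generate_genome(50000, n_duplications=2, dup_length=3000, seed=7)
        doubled = g.sequence + g.sequence[:2999]
        for src, dst, ln in g.duplications:
            segment = g.sequence[src : src + ln]
            hits = []
            i = doubled.find(segment)
            while i != -1:
                if i < len(g):
                    hits.append(i)
                i = doubled.find(segment, i + 1)
            assert len(hits) >= 2

    def test_same_seed_is_byte_identical(self):
        a = generate_genome(5000, n_duplications=1, dup_length=400, seed=42)
        b = generate_genome(5000, n_duplications=1, dup_length=400, seed=42)
        assert a.sequence == b.sequence
        assert a.duplications == b.duplications

    def test_gatc_density_approximately_met(self):
        g = generate_genome(200000, gatc_density=0.0043, seed=3)
        n_gatc = (g.sequence + g.sequence[:3]).count("GATC")
        expected = 0.0043 * 200000
        assert 0.8 * expected <= n_gatc <= 1.2 * expected

    def test_impossible_duplications_rejected_with_named_constraint(self):
        with pytest.raises(ValueError, match="dup_length"):
            generate_genome(10000, n_duplications=1, dup_length=2000, seed=0)


class TestPlaceFeatures:
    def test_tract_length_is_speed_times_time(self):
        g = generate_genome(200000, seed=5)
        f = place_features(g, fork_speed_bp_s=1000, hemimeth_time_s=60, seed=0)
        assert f.tract_length_bp == 60000
        f2 = place_features(g, fork_speed_bp_s=500, hemimeth_time_s=60, seed=0)
        assert f2.tract_length_bp == 30000

    def test_no_gatc_means_no_binding(self):
        g = generate_genome(5000, gatc_density=0.0, seed=2)
        f = place_features(g, seed=0)
        assert np.all(f.true_binding == 0)

    def test_binding_weight_sits_on_gatc_starts(self):
        g = generate_genome(50000, seed=9)
        f = place_features(g, seed=0)
        doubled = g.sequence + g.sequence[:3]
        nz = np.flatnonzero(f.true_binding)
        assert nz.size > 0
        assert all(doubled[i : i + 4] == "GATC" for i in nz)

    def test_transcribed_regions_disjoint_and_in_bounds(self):
        g = generate_genome(100000, seed=4)
        f = place_features(g, n_transcribed=15, seed=1)
        regions = sorted(f.transcribed_regions)
        assert len(regions) == 15
        for (s1, e1, a1), (s2, e2, _) in zip(regions, regions[1:]):
            assert 0 <= s1 < e1 <= len(g) and e1 <= s2
            assert a1 >= 0

    def test_origin_occupancy_exceeds_bulk(self):
        g = generate_genome(100000, gatc_density=0.01, seed=6)
        f = place_features(g, fork_origin=50000, seed=0)
        nz = np.flatnonzero(f.true_binding)
        near = nz[np.abs(nz - 50000) <= 5000]
        far = nz[np.abs(nz - 50000) > 10000]
        assert near.size and far.size
        assert f.true_binding[near].min() > f.true_binding[far].max()


class TestDesignProbes:
    def test_probe_count_is_floor_of_length_over_spacing(self):
        g = generate_genome(15000, seed=1)
        probes = design_probes(g, probe_length=60, spacing=150)
        assert len(probes) == 100

    def test_single_probe_genome(self):
        g = generate_genome(150, seed=2)
        probes = design_probes(g, probe_length=60, spacing=150)
        assert len(probes) == 1
        assert probes["middle"].iloc[0] == 30

    def test_probe_sequences_match_genome_substrings_with_wrap(self):
        g = generate_genome(5000, seed=8)
        probes = design_probes(g, probe_length=60, spacing=145)
        doubled = g.sequence + g.sequence[:60]
        for i, row in probes.iterrows():
            start = i * 145
            assert row["sequence"] == doubled[start : start + 60]

    def test_spacing_below_probe_length_rejected(self):
        g = generate_genome(5000, seed=1)
        with pytest.raises(ValueError, match="probe_length"):
            design_probes(g, probe_length=60, spacing=50)


def _neutral(seed=0, **kw):
    kw.setdefault("noise_sd", 0.0)
    return ArtifactConfig(seed=seed, **kw)


def _null_features(genome, regions=()):
    return FeatureAnnotation(
        genome=genome,
        transcribed_regions=list(regions),
        true_binding=np.zeros(len(genome)),
        fork_origin=0,
        tract_length_bp=60000,
    )


class TestSimulateArrays:
    def test_differential_reversal_gives_twofold_at_transcribed_probes(self):
        g = generate_genome(30000, gatc_density=0.0, seed=3)
        f = _null_features(g, [(10000, 12000, 1.0)])
        scans = simulate_arrays(
            design_probes(g), f, _neutral(reversal_ip=0.6, reversal_input=0.3)
        )
        truth = scans[0][1]
        probes = design_probes(g)
        inside = (probes["middle"] >= 10000 + 30) & (probes["middle"] < 12000 - 30)
        assert np.allclose(truth.loc[inside.to_numpy(), "expected_log2"], 1.0)
        outside = (probes["middle"] < 10000 - 300) | (probes["middle"] >= 12000 + 300)
        assert np.allclose(truth.loc[outside.to_numpy(), "expected_log2"], 0.0)

    def test_null_array_is_identically_zero(self):
        g = generate_genome(20000, gatc_density=0.0, seed=4)
        scans = simulate_arrays(design_probes(g), _null_features(g), _neutral())
        assert np.allclose(scans[0][1]["expected_log2"], 0.0)
        net = scans[0][0]
        assert np.allclose(
            net["ip_fg"] - net["ip_bg"], net["ref_fg"] - net["ref_bg"]
        )

    def test_duplicated_probe_reports_mean_of_locus_ratios(self):
        # probe inside the dest copy of a duplication; binding (ratio 4) only
        # at the source locus -> probe expected ratio (4 + 1) / 2 = 2.5
        g = generate_genome(50000, gatc_density=0.0, n_duplications=1, dup_length=3000, seed=7)
        src, dst, ln = g.duplications[0]
        binding = np.zeros(len(g))
        probes = design_probes(g)
        inside_dst = probes.loc[
            ((probes["middle"] - 30 - dst) % len(g) < ln - 60), "middle"
        ]
        probe_mid = int(inside_dst.iloc[len(inside_dst) // 2])
        # weight at the probe's mirrored source locus: enrichment 4 there,
        # 1 at the probe's own locus
        binding[probe_mid - dst + src] = 3.0
        f = FeatureAnnotation(
            genome=g, transcribed_regions=[], true_binding=binding,
            fork_origin=0, tract_length_bp=0,
        )
        _, truth = simulate_arrays(probes, f, _neutral())[0]
        row = truth.loc[(probes["middle"] == probe_mid).to_numpy()].iloc[0]
        assert row["artifact_class"] == "nonunique"
        assert row["expected_log2"] == pytest.approx(np.log2(2.5))

    def test_replicates_share_truth_but_differ_in_noise(self):
        g = generate_genome(20000, seed=5)
        f = place_features(g, seed=1)
        scans = simulate_arrays(
            design_probes(g), f, ArtifactConfig(noise_sd=0.3, seed=9), replicates=2
        )
        pd.testing.assert_frame_equal(scans[0][1], scans[1][1])
        assert not np.allclose(scans[0][0]["ip_fg"], scans[1][0]["ip_fg"])

    def test_seeded_determinism(self):
        g = generate_genome(20000, seed=5)
        f = place_features(g, seed=1)
        probes = design_probes(g)
        cfg = ArtifactConfig(noise_sd=0.3, seed=9)
        a = simulate_arrays(probes, f, cfg)[0][0]
        b = simulate_arrays(probes, f, cfg)[0][0]
        pd.testing.assert_frame_equal(a, b)

    def test_replicates_below_one_rejected(self):
        g = generate_genome(20000, seed=5)
        with pytest.raises(ValueError, match="replicates"):
            simulate_arrays(design_probes(g), _null_features(g), _neutral(), replicates=0)

    @pytest.mark.parametrize(
        "knob",
        [
            {"reversal_ip": 0.6, "reversal_input": 0.3},
            {"spin_column_factor": 5.0},
            {"rna_background_scale": 1.0, "rnase_minutes": 30.0},
        ],
        ids=["crosslink", "spin_column", "rna"],
    )
    def test_single_artifact_raises_affected_probes_only(self, knob):
        g = generate_genome(30000, gatc_density=0.0, seed=6)
        f = _null_features(g, [(5000, 8000, 1.0)])
        probes = design_probes(g)
        base = simulate_arrays(probes, f, _neutral())[0][1]["expected_log2"].to_numpy()
        on = simulate_arrays(probes, f, _neutral(**knob))[0][1]["expected_log2"].to_numpy()
        mids = probes["middle"].to_numpy()
        affected = (mids > 5000 - 30) & (mids < 8000 + 30)
        assert np.all(on[affected] > base[affected])
        assert np.allclose(on[~affected], base[~affected])


class TestResidualRna:
    def test_monotone_nonincreasing_and_vanishing(self):
        grid = np.linspace(0, 300, 61)
        vals = [residual_rna(m) for m in grid]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert residual_rna(0) == 1.0
        assert residual_rna(30) == pytest.approx(np.exp(-1))
        assert residual_rna(600) < 1e-8

    def test_negative_minutes_rejected(self):
        with pytest.raises(ValueError):
            residual_rna(-1)


def _roc_auc(scores, labels):
    """Rank-based (Mann-Whitney) ROC area."""
    scores = np.asarray(scores)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores))
    ranks[order] = np.arange(1, len(scores) + 1)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def test_truth_recovery_roc_over_twenty_seeds():
    """Probes at expected binding log2 >= 1 separate from unbound probes by
    processed ratio with ROC area > 0.9 in every seeded simulation."""
    aucs = []
    for seed in range(20):
        g = generate_genome(100000, seed=100 + seed)
        f, _centers = planted_features(g, n_targets=8, effect_log2=1.0, seed=seed)
        probes = design_probes(g)
        scans = simulate_arrays(probes, f, ArtifactConfig(noise_sd=0.3, seed=seed), 2)
        tracks = process_replicates(scans, probes)
        merged = (
            tracks[0].set_index("probe_id")["log2_ratio"]
            + tracks[1].set_index("probe_id")["log2_ratio"]
        ) / 2
        truth = scans[0][1].set_index("probe_id").loc[merged.index]
        aucs.append(_roc_auc(merged.to_numpy(), truth["true_bound"].to_numpy()))
    assert min(aucs) > 0.9
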