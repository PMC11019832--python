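"""Synthetic generators: determinism, planted ground truth, and the
statistical properties the downstream pipeline relies on."""

import numpy as np
import pytest

from chromadyn.docr import extract_nucleosome_free
from chromadyn.simulate import (
    SeSpec,
    SimulationConfig,
    TssPairSpec,
    _draw_fragment_lengths,
    gen_accessibility_experiment,
    gen_annotation,
    gen_cohort,
    gen_se_landscape,
    gen_signal_tracks,
    gen_startseq,
    gen_state_scores,
)
from chromadyn.intervals import GenomicInterval


SMALL = dict(
    chrom_sizes={"chr1": 500_000, "chr2": 400_000},
    n_genes=40,
    n_regions=60,
    reads_per_sample=40_000,
)


class TestDeterminism:
    def test_same_seed_reproduces_everything(self):
        a = SimulationConfig(seed=77, **SMALL)
        b = SimulationConfig(seed=77, **SMALL)
        ann_a, ann_b = gen_annotation(a), gen_annotation(b)
        assert [
            (g.gene_id, g.chrom, g.strand, g.body_start, g.body_end)
            for g in ann_a.genes
        ] == [
            (g.gene_id, g.chrom, g.strand, g.body_start, g.body_end)
            for g in ann_b.genes
        ]
        fr_a, pk_a, _, tr_a = gen_accessibility_experiment(a, ann_a)
        fr_b, pk_b, _, tr_b = gen_accessibility_experiment(b, ann_b)
        for sid in fr_a:
            assert [(f.start, f.end) for f in fr_a[sid]] == [
                (f.start, f.end) for f in fr_b[sid]
            ]
        assert tr_a.differential_regions.equals(tr_b.differential_regions)

    def test_different_seeds_differ(self):
        a = SimulationConfig(seed=1, **SMALL)
        b = SimulationConfig(seed=2, **SMALL)
        fr_a = gen_accessibility_experiment(a, gen_annotation(a))[0]
        fr_b = gen_accessibility_experiment(b, gen_annotation(b))[0]
        sid = sorted(fr_a)[0]
        assert [(f.start, f.end) for f in fr_a[sid]] != [
            (f.start, f.end) for f in fr_b[sid]
        ]

    def test_stages_are_independent_streams(self):
        # the startseq stage gives the same output whether or not the
        # accessibility stage ran first
        c1 = SimulationConfig(seed=5, **SMALL)
        p1, m1, t1 = gen_startseq(c1, gen_annotation(c1))
        c2 = SimulationConfig(seed=5, **SMALL)
        ann2 = gen_annotation(c2)
        gen_accessibility_experiment(c2, ann2)
        p2, m2, t2 = gen_startseq(c2, ann2)
        assert t1.tss_pairs.equals(t2.tss_pairs)


class TestAnnotation:
    def test_genes_disjoint_within_chromosome(self):
        cfg = SimulationConfig(seed=3, **SMALL)
        ann = gen_annotation(cfg)
        assert len(ann) == cfg.n_genes
        for chrom in cfg.chrom_sizes:
            genes = sorted(ann.genes_on(chrom), key=lambda g: g.body_start)
            for a, b in zip(genes, genes[1:]):
                assert a.body_end <= b.body_start

    def test_zero_genes_allowed(self):
        cfg = SimulationConfig(seed=3, chrom_sizes={"chr1": 100_000}, n_genes=0)
        assert len(gen_annotation(cfg)) == 0

    def test_too_many_genes_rejected(self):
        cfg = SimulationConfig(
            seed=3, chrom_sizes={"chr1": 100_000}, n_genes=1_000
        )
        with pytest.raises(ValueError, match="cannot fit"):
            gen_annotation(cfg)


class TestFragmentLengths:
    def test_component_supports(self, rng):
        lens = _draw_fragment_lengths(rng, 20_000, 0.6)
        nfr = lens[lens < 100]
        mono = lens[lens >= 100]
        assert nfr.min() >= 36 and nfr.max() <= 99
        assert mono.min() >= 150 and mono.max() <= 250

    def test_nfr_fraction_within_3_sigma(self, rng):
        n = 50_000
        lens = _draw_fragment_lengths(rng, n, 0.6)
        frac = np.mean(lens < 100)
        se = np.sqrt(0.6 * 0.4 / n)
        assert abs(frac - 0.6) < 3 * se

    def test_extreme_fractions(self, rng):
        assert (_draw_fragment_lengths(rng, 1_000, 1.0) < 100).all()
        assert (_draw_fragment_lengths(rng, 1_000, 0.0) >= 150).all()


class TestAccessibilityExperiment:
    def test_truth_split_half_gain_half_lost(self):
        cfg = SimulationConfig(seed=11, **SMALL)
        ann = gen_annotation(cfg)
        _, _, _, truth = gen_accessibility_experiment(cfg, ann)
        t = truth.differential_regions
        n_diff = int(t["is_differential"].sum())
        assert n_diff == int(round(len(t) * cfg.frac_differential))
        gains = (t["log2fc"] > 0).sum()
        losts = (t["log2fc"] < 0).sum()
        assert abs(gains - losts) <= 1
        assert set(np.abs(t.loc[t["is_differential"], "log2fc"])) == {2.0}

    def test_zero_frac_differential_plants_nothing(self):
        cfg = SimulationConfig(seed=11, frac_differential=0.0, **SMALL)
        ann = gen_annotation(cfg)
        _, _, _, truth = gen_accessibility_experiment(cfg, ann)
        assert not truth.differential_regions["is_differential"].any()
        assert (truth.differential_regions["log2fc"] == 0).all()

    def test_sample_layout_and_conditions(self):
        cfg = SimulationConfig(seed=11, **SMALL)
        ann = gen_annotation(cfg)
        frags, peaks, conds, _ = gen_accessibility_experiment(cfg, ann)
        assert sorted(conds) == sorted(frags) == sorted(peaks)
        assert sum(v == "control" for v in conds.values()) == 3
        assert sum(v == "treated" for v in conds.values()) == 3

    def test_nfr_fraction_realized_in_fragments(self):
        cfg = SimulationConfig(seed=11, **SMALL)
        ann = gen_annotation(cfg)
        frags, _, _, _ = gen_accessibility_experiment(cfg, ann)
        sid = sorted(frags)[0]
        nfr = extract_nucleosome_free(frags[sid])
        frac = len(nfr) / len(frags[sid])
        assert abs(frac - cfg.nfr_fraction) < 0.03

    def test_regions_separated_for_unambiguous_merging(self):
        cfg = SimulationConfig(seed=11, **SMALL)
        ann = gen_annotation(cfg)
        _, _, _, truth = gen_accessibility_experiment(cfg, ann)
        t = truth.differential_regions
        for chrom, grp in t.groupby("chrom"):
            centers = sorted((grp["start"] + grp["end"]) // 2)
            assert all(b - a >= 2_500 for a, b in zip(centers, centers[1:]))

    def test_symmetric_planting_centers_counts_on_base_mean(self):
        # control mean * treated mean == base_mean^2: the planted shift is
        # split evenly, so neither condition carries a depth artifact
        cfg = SimulationConfig(seed=13, **SMALL)
        ann = gen_annotation(cfg)
        frags, _, conds, truth = gen_accessibility_experiment(cfg, ann)
        from chromadyn.docr import count_fragments

        t = truth.differential_regions
        regions = [
            GenomicInterval(r.chrom, r.start, r.end)
            for r in t.itertuples(index=False)
        ]
        m = count_fragments(regions, frags, conds)
        # count_fragments sorts regions: align truth rows to matrix rows
        row_of = {fid: i for i, fid in enumerate(m.feature_ids)}
        order = [
            row_of[f"{r.chrom}:{r.start}-{r.end}"]
            for r in t.itertuples(index=False)
        ]
        counts = m.counts[order]
        ctrl = counts[:, [c == "control" for c in m.conditions]].mean(axis=1)
        trt = counts[:, [c == "treated" for c in m.conditions]].mean(axis=1)
        gain = t["log2fc"].to_numpy() > 0
        lost = t["log2fc"].to_numpy() < 0
        # pooled over planted regions the fold changes mirror each other
        assert np.log2(trt[gain].sum() / ctrl[gain].sum()) > 1.5
        assert np.log2(trt[lost].sum() / ctrl[lost].sum()) < -1.5
        # and the unplanted regions sit near zero
        null = ~(gain | lost)
        assert abs(np.log2(trt[null].sum() / ctrl[null].sum())) < 0.2


class TestStartseq:
    def test_truth_distances_exact_and_planted_reads_present(self):
        cfg = SimulationConfig(seed=21, **SMALL)
        ann = gen_annotation(cfg)
        plus, minus, truth = gen_startseq(cfg, ann)
        t = truth.tss_pairs
        assert (t["sense_pos"] - t["antisense_pos"] == t["distance"]).all()
        for row in t.head(50).itertuples(index=False):
            assert plus.value_at(row.chrom, row.sense_pos) >= 50
            assert minus.value_at(row.chrom, row.antisense_pos) >= 50

    def test_lognormal_median_within_10pct(self):
        # a genome large enough for 600 pairs on the 4 kb anchor grid
        cfg = SimulationConfig(
            seed=22,
            chrom_sizes={"chr1": 3_000_000},
            n_genes=0,
            tss_pair_spec={
                "gain": TssPairSpec(count=300, median=188.0),
                "lost": TssPairSpec(count=300, median=277.0),
            },
        )
        ann = gen_annotation(cfg)
        _, _, truth = gen_startseq(cfg, ann)
        t = truth.tss_pairs
        med_gain = t.loc[t["pair_class"] == "gain", "distance"].median()
        med_lost = t.loc[t["pair_class"] == "lost", "distance"].median()
        assert abs(med_gain - 188) / 188 < 0.10
        assert abs(med_lost - 277) / 277 < 0.10

    def test_zero_background_leaves_only_planted_signal(self):
        cfg = SimulationConfig(seed=23, tss_background_rate=0.0, **SMALL)
        ann = gen_annotation(cfg)
        plus, minus, truth = gen_startseq(cfg, ann)
        t = truth.tss_pairs
        planted_plus = set(zip(t["chrom"], t["sense_pos"]))
        for chrom in plus.chroms():
            pos, vals = plus.base_positions(chrom)
            for p in pos:
                assert (chrom, int(p)) in planted_plus

    def test_anchor_spacing_prevents_pair_collisions(self):
        cfg = SimulationConfig(seed=24, **SMALL)
        ann = gen_annotation(cfg)
        _, _, truth = gen_startseq(cfg, ann)
        t = truth.tss_pairs
        for chrom, grp in t.groupby("chrom"):
            sense = sorted(grp["sense_pos"])
            assert all(b - a >= 2_000 for a, b in zip(sense, sense[1:]))


class TestSignalTracks:
    def test_track_set_and_flat_controls(self):
        cfg = SimulationConfig(seed=31, **SMALL)
        regions = [GenomicInterval("chr1", 50_000 + i * 10_000, 50_500 + i * 10_000)
                   for i in range(4)]
        tracks = gen_signal_tracks(cfg, regions)
        assert set(tracks) == {
            "ATAC", "H3K27ac", "H3K4me1", "H3K4me3", "H3", "RNAPII", "input"
        }
        assert tracks["H3"].value_at("chr1", 123) == 1.0
        assert tracks["input"].value_at("chr1", 123) == 0.5

    def test_unimodal_peak_at_center_bimodal_dip(self):
        cfg = SimulationConfig(seed=31, **SMALL)
        uni = GenomicInterval("chr1", 50_000, 50_500)     # index 0: unimodal
        bi = GenomicInterval("chr1", 80_000, 80_500)      # index 1: bimodal
        tracks = gen_signal_tracks(cfg, [uni, bi])
        t = tracks["H3K27ac"]
        c_uni, c_bi = uni.center, bi.center
        # unimodal: maximum at the center
        assert t.value_at("chr1", c_uni) > t.value_at("chr1", c_uni + 400)
        # bimodal: center is a local dip between the two modes at +/-250
        assert t.value_at("chr1", c_bi + 250) > t.value_at("chr1", c_bi)
        assert t.value_at("chr1", c_bi - 250) > t.value_at("chr1", c_bi)

    def test_mark_equals_h3_plus_profile_far_from_regions(self):
        cfg = SimulationConfig(seed=31, **SMALL)
        regions = [GenomicInterval("chr1", 50_000, 50_500)]
        tracks = gen_signal_tracks(cfg, regions)
        # far away the mark sits exactly on the H3 baseline
        assert tracks["H3K27ac"].value_at("chr1", 300_000) == pytest.approx(
            tracks["H3"].value_at("chr1", 300_000)
        )


class TestSeLandscape:
    def test_planted_scores_sit_above_a_gap(self):
        cfg = SimulationConfig(seed=41, **SMALL)
        ann = gen_annotation(cfg)
        peaks, tracks, truth = gen_se_landscape(cfg, ann)
        scores = {p.name: p.score for p in peaks}
        truth_set = set(truth.super_set)
        assert len(truth_set) == cfg.se_spec.n_super_true
        top = min(scores[n] for n in truth_set)
        rest = max(s for n, s in scores.items() if n not in truth_set)
        assert top >= 4.0 * rest

    def test_mark_track_integral_recovers_scores(self):
        cfg = SimulationConfig(seed=41, **SMALL)
        ann = gen_annotation(cfg)
        peaks, tracks, _ = gen_se_landscape(cfg, ann)
        mark = tracks["mark"]
        for p in peaks[:30]:
            got = mark.integral(p.chrom, p.start, p.end)
            assert got == pytest.approx(p.score, rel=1e-9)

    def test_peaks_separated_beyond_stitch_distance(self):
        cfg = SimulationConfig(seed=41, **SMALL)
        ann = gen_annotation(cfg)
        peaks, _, _ = gen_se_landscape(cfg, ann)
        by_chrom = {}
        for p in peaks:
            by_chrom.setdefault(p.chrom, []).append(p)
        for ps in by_chrom.values():
            ps.sort(key=lambda p: p.start)
            for a, b in zip(ps, ps[1:]):
                assert b.start - a.end > 12_500

    def test_zero_tail_is_degenerate_with_empty_truth(self):
        cfg = SimulationConfig(
            seed=41, se_spec=SeSpec(tail_exponent=0.0), **SMALL
        )
        ann = gen_annotation(cfg)
        peaks, _, truth = gen_se_landscape(cfg, ann)
        assert truth.super_set == []
        assert len({p.score for p in peaks}) == 1


class TestCohort:
    def test_layout_and_truth_blocks(self):
        cfg = SimulationConfig(seed=51, **SMALL)
        regions = [
            GenomicInterval("chr1", i * 5_000, i * 5_000 + 1_000)
            for i in range(60)
        ]
        samples, subtypes, truth = gen_cohort(cfg, regions)
        assert len(samples) == 20
        assert sum(v == "basal" for v in subtypes.values()) == 10
        assert set(truth.cohort_clusters) == set(range(1, 7))
        # blocks are contiguous
        assert (np.diff(truth.cohort_clusters) >= 0).all()

    def test_block_means_oppose_across_subtypes(self):
        cfg = SimulationConfig(seed=52, **SMALL)
        regions = [
            GenomicInterval("chr1", i * 5_000, i * 5_000 + 1_000)
            for i in range(60)
        ]
        samples, subtypes, truth = gen_cohort(cfg, regions)
        k = cfg.cohort_spec.n_clusters
        basal = [s for s, t in subtypes.items() if t == "basal"]
        nonb = [s for s, t in subtypes.items() if t == "non_basal"]

        def block_mean(sids, cluster):
            idx = np.flatnonzero(truth.cohort_clusters == cluster)
            vals = []
            for sid in sids:
                for i in idx:
                    r = regions[i]
                    vals.append(samples[sid].mean_over(r.chrom, r.start, r.end))
            return np.mean(vals)

        # extreme clusters separate strongly with opposite sign
        d_basal = block_mean(basal, k) - block_mean(basal, 1)
        d_nonb = block_mean(nonb, k) - block_mean(nonb, 1)
        assert d_basal > 1.0
        assert d_nonb < -1.0

    def test_too_many_clusters_rejected(self):
        cfg = SimulationConfig(seed=51, **SMALL)
        with pytest.raises(ValueError, match="exceeds"):
            gen_cohort(cfg, [GenomicInterval("chr1", 0, 100)])


def test_state_scores_table_shape_and_range():
    cfg = SimulationConfig(seed=61, chrom_sizes={"chr1": 10_000}, n_genes=0)
    df = gen_state_scores(cfg)
    assert len(df) == 50  # 10_000 / 200 bins
    assert list(df.columns[:3]) == ["chrom", "start", "end"]
    assert df.shape[1] == 3 + 15
    assert (df[[f"state{i+1}" for i in range(15)]].to_numpy() >= 0).all()
    assert (df["start"] % 200 == 0).all()
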