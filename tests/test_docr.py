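"""DOCR pipeline: NFR filter boundaries, OCR consensus, fragment counting,
the testable/FDR gates, genomic categories, and chromatin-state consensus."""

import numpy as np
import pandas as pd
import pytest

from chromadyn.annotation import GeneModel, GenomeAnnotation
from chromadyn.docr import (
    ChromatinStateTable,
    DocrConfig,
    DocrRecord,
    annotate_docrs,
    build_global_ocrs,
    call_docrs,
    call_peaks_simple,
    classify_genomic_category,
    count_fragments,
    extract_nucleosome_free,
    summarize_docrs,
)
from chromadyn.intervals import GenomicInterval, merge_intervals
from chromadyn.nb import CountMatrix

from conftest import random_intervals


def frag(chrom, start, end):
    return GenomicInterval(chrom, start, end)


class TestNfrFilter:
    def test_length_boundary_strictly_below_100(self):
        frags = [
            frag("chr1", 0, 99),    # len 99 -> kept
            frag("chr1", 0, 100),   # len 100 -> dropped
            frag("chr1", 0, 101),   # len 101 -> dropped
            frag("chr1", 50, 86),   # len 36 -> kept
        ]
        kept = extract_nucleosome_free(frags)
        assert [(f.start, f.end) for f in kept] == [(0, 99), (50, 86)]

    def test_custom_threshold(self):
        kept = extract_nucleosome_free([frag("chr1", 0, 120)], nfr_max_len=150)
        assert len(kept) == 1


class TestPeakCalling:
    def test_enriched_block_found_with_correct_bounds(self, rng):
        frags = []
        # sparse background plus a dense 600-b block
        for p in rng.integers(0, 50_000, size=60):
            frags.append(frag("chr1", int(p), int(p) + 80))
        for p in rng.integers(20_000, 20_600, size=400):
            frags.append(frag("chr1", int(p), int(p) + 80))
        peaks = call_peaks_simple(frags, {"chr1": 51_000})
        hit = [p for p in peaks if p.start < 20_800 and p.end > 20_000]
        assert hit, "dense block not called"
        best = max(hit, key=lambda p: len(p))
        assert 19_500 <= best.start <= 20_300
        assert 20_400 <= best.end <= 21_200

    def test_no_fragments_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert call_peaks_simple([], {"chr1": 10_000}) == []


class TestGlobalOcrs:
    def test_two_stage_merge_example(self):
        per_sample = [
            [GenomicInterval("chr1", 0, 200), GenomicInterval("chr1", 280, 400)],
            [GenomicInterval("chr1", 150, 260)],
        ]
        ocrs = build_global_ocrs(per_sample)
        assert [(o.start, o.end) for o in ocrs] == [(0, 400)]

    def test_distant_peaks_stay_separate(self):
        per_sample = [
            [GenomicInterval("chr1", 0, 100)],
            [GenomicInterval("chr1", 300, 400)],
        ]
        assert len(build_global_ocrs(per_sample)) == 2

    def test_matches_pooled_merge_oracle(self, rng):
        per_sample = [random_intervals(rng, 150, span=30_000) for _ in range(4)]
        got = build_global_ocrs(per_sample)
        pooled = [iv for s in per_sample for iv in s]
        expected = merge_intervals(merge_intervals(pooled, gap=0), gap=100)
        assert [(o.start, o.end) for o in got] == [
            (o.start, o.end) for o in expected
        ]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_global_ocrs([])


class TestCountFragments:
    def test_overlap_is_half_open(self):
        ocrs = [GenomicInterval("chr1", 100, 200)]
        frags = {
            "s1": [
                frag("chr1", 50, 100),   # abuts left: no overlap
                frag("chr1", 50, 101),   # 1 base in
                frag("chr1", 199, 250),  # 1 base in
                frag("chr1", 200, 250),  # abuts right: no overlap
                frag("chr1", 120, 130),  # inside
            ]
        }
        m = count_fragments(ocrs, frags, {"s1": "control"})
        assert m.counts[0, 0] == 3

    def test_fragment_spanning_two_regions_counted_in_both(self):
        ocrs = [
            GenomicInterval("chr1", 0, 100),
            GenomicInterval("chr1", 150, 250),
        ]
        m = count_fragments(ocrs, {"s1": [frag("chr1", 90, 160)]}, {"s1": "x"})
        assert m.counts[:, 0].tolist() == [1, 1]

    def test_matches_quadratic_scan_oracle(self, rng):
        # disjoint regions (as produced by the merge stage)
        ocrs = merge_intervals(
            random_intervals(rng, 80, span=20_000, max_len=500), gap=0
        )
        samples = {
            f"s{j}": random_intervals(rng, 400, span=20_000, max_len=300)
            for j in range(3)
        }
        m = count_fragments(ocrs, samples, {k: "c" for k in samples})
        for j, sid in enumerate(m.sample_ids):
            for i, r in enumerate(ocrs):
                expected = sum(
                    1
                    for f in samples[sid]
                    if f.chrom == r.chrom and f.start < r.end and r.start < f.end
                )
                assert m.counts[i, j] == expected


def make_docr_inputs(rng, n=400, planted=60):
    """Disjoint OCRs with NB counts; `planted` regions get a symmetric
    2^(+/-1) shift in each direction (total log2 fold change +/-2)."""
    ocrs = [GenomicInterval("chr1", i * 1_000, i * 1_000 + 500) for i in range(n)]
    lfc = np.zeros(n)
    idx = rng.choice(n, planted, replace=False)
    if planted:
        lfc[idx[: planted // 2]] = 2.0
        lfc[idx[planted // 2:]] = -2.0
    cols = []
    for scale in (-0.5, -0.5, -0.5, 0.5, 0.5, 0.5):
        mu = 300 * 2.0 ** (lfc * scale)
        counts = rng.poisson(rng.gamma(1 / 0.05, mu * 0.05))
        cols.append(counts)
    counts = np.column_stack(cols).astype(np.int64)
    matrix = CountMatrix(
        counts=counts,
        feature_ids=[f"{o.chrom}:{o.start}-{o.end}" for o in ocrs],
        sample_ids=["c0", "c1", "c2", "t0", "t1", "t2"],
        conditions=["control"] * 3 + ["treated"] * 3,
    )
    return ocrs, matrix, lfc


class TestCallDocrs:
    def test_low_count_regions_excluded_from_testing(self, rng):
        ocrs, matrix, _ = make_docr_inputs(rng, n=50, planted=0)
        matrix.counts[7, :] = 99   # just below the gate in every sample
        matrix.counts[8, :] = 100  # exactly at the gate -> testable
        matrix.counts[9, :] = 100
        matrix.counts[9, 2] = 99   # one sample below -> excluded
        docrs, table = call_docrs(ocrs, matrix, ("treated", "control"))
        assert matrix.feature_ids[7] not in table.index
        assert matrix.feature_ids[8] in table.index
        assert matrix.feature_ids[9] not in table.index
        assert table.attrs["n_testable"] == len(table)

    def test_fdr_gate_is_strict_and_direction_partition(self, rng):
        ocrs, matrix, _ = make_docr_inputs(rng)
        docrs, table = call_docrs(ocrs, matrix, ("treated", "control"))
        called = {(d.interval.start, d.interval.end) for d in docrs}
        for fid, row in table.iterrows():
            chrom, rest = fid.split(":")
            s, e = map(int, rest.split("-"))
            if (s, e) in called:
                assert row["fdr"] < 0.05
            else:
                assert not (row["fdr"] < 0.05)
        for d in docrs:
            assert d.direction == ("GAIN" if d.log2fc > 0 else "LOST")

    def test_planted_regions_dominate_calls(self, rng):
        ocrs, matrix, lfc = make_docr_inputs(rng)
        docrs, _ = call_docrs(ocrs, matrix, ("treated", "control"))
        ids = [d.interval.start // 1_000 for d in docrs]
        true_pos = sum(1 for i in ids if lfc[i] != 0)
        assert true_pos / max(len(ids), 1) >= 0.9       # empirical FDR <= 10%
        assert true_pos >= 0.8 * (lfc != 0).sum()       # sensitivity >= 80%
        for d in docrs:
            i = d.interval.start // 1_000
            if lfc[i] > 0:
                assert d.direction == "GAIN"
            elif lfc[i] < 0:
                assert d.direction == "LOST"

    def test_misaligned_matrix_rejected(self, rng):
        ocrs, matrix, _ = make_docr_inputs(rng, n=20, planted=0)
        with pytest.raises(ValueError, match="not aligned"):
            call_docrs(ocrs[:-1], matrix, ("treated", "control"))


@pytest.fixture
def category_annotation():
    # plus-strand gene gP: body [10_000, 20_000), TSS 10_000
    # minus-strand gene gM: body [40_000, 50_000), TSS 49_999
    genes = [
        GeneModel("gP", "chr1", "+", 10_000, 20_000),
        GeneModel("gM", "chr1", "-", 40_000, 50_000),
    ]
    return GenomeAnnotation(genes, {"chr1": 100_000})


class TestGenomicCategory:
    """Promoter window [TSS-1000, TSS+500) in gene orientation; precedence
    promoter > genic > intergenic; classification is by region center."""

    @pytest.mark.parametrize(
        "center,expected",
        [
            (9_000, "promoter"),      # exactly TSS-1000
            (8_999, "intergenic"),    # one base too far upstream
            (10_499, "promoter"),     # TSS+499: last promoter base
            (10_500, "genic"),        # TSS+500: past promoter, in body
            (15_000, "genic"),
            (19_999, "genic"),        # last body base
            (20_000, "intergenic"),   # first base past body end
        ],
    )
    def test_plus_strand_boundaries(self, category_annotation, center, expected):
        assert (
            classify_genomic_category(center, "chr1", category_annotation)
            == expected
        )

    @pytest.mark.parametrize(
        "center,expected",
        [
            # minus strand: upstream is to the RIGHT of the TSS at 49_999
            (50_999, "promoter"),     # exactly TSS-1000 in gene orientation
            (51_000, "intergenic"),
            (49_500, "promoter"),     # TSS+499 downstream (left of TSS)
            (49_499, "genic"),        # TSS+500: first non-promoter body base
            (45_000, "genic"),
            (40_000, "genic"),        # leftmost body base
            (39_999, "intergenic"),
        ],
    )
    def test_minus_strand_mirror(self, category_annotation, center, expected):
        assert (
            classify_genomic_category(center, "chr1", category_annotation)
            == expected
        )

    def test_promoter_precedence_over_genic(self):
        # center inside gene A's body AND in gene B's promoter window
        genes = [
            GeneModel("gA", "chr1", "+", 0, 30_000),
            GeneModel("gB", "chr1", "+", 15_500, 40_000),
        ]
        ann = GenomeAnnotation(genes, {"chr1": 100_000})
        assert classify_genomic_category(15_000, "chr1", ann) == "promoter"


def state_frame(rows):
    """rows: list of (chrom, start, scores[15])"""
    data = {"chrom": [r[0] for r in rows], "start": [r[1] for r in rows]}
    for k in range(15):
        data[f"state{k + 1}"] = [r[2][k] for r in rows]
    return pd.DataFrame(data)


class TestChromatinStates:
    def test_per_bin_argmax(self):
        scores = np.zeros(15)
        scores[6] = 2.0
        table = ChromatinStateTable(state_frame([("chr1", 400, scores)]))
        assert table.state_at("chr1", 450) == 7
        assert table.state_at("chr1", 599) == 7
        assert table.state_at("chr1", 600) is None

    def test_tie_goes_to_lowest_state_index(self):
        scores = np.zeros(15)
        scores[4] = 1.0
        scores[9] = 1.0  # states 5 and 10 tied
        table = ChromatinStateTable(state_frame([("chr1", 0, scores)]))
        assert table.state_at("chr1", 100) == 5

    def test_states_match_argmax_oracle(self, rng):
        rows = [("chr1", i * 200, rng.exponential(size=15)) for i in range(50)]
        table = ChromatinStateTable(state_frame(rows))
        for chrom, start, scores in rows:
            assert table.state_at(chrom, start) == int(np.argmax(scores)) + 1

    def test_missing_chromosome_returns_none(self):
        table = ChromatinStateTable(state_frame([("chr1", 0, np.ones(15))]))
        assert table.state_at("chr2", 0) is None

    def test_wrong_column_count_rejected(self):
        df = state_frame([("chr1", 0, np.ones(15))]).drop(columns=["state15"])
        with pytest.raises(ValueError, match="state columns"):
            ChromatinStateTable(df)

    def test_tsv_read(self, tmp_path, rng):
        df = state_frame(
            [("chr1", i * 200, rng.exponential(size=15).round(4)) for i in range(10)]
        )
        path = tmp_path / "states.tsv"
        df.to_csv(path, sep="\t", index=False)
        table = ChromatinStateTable.read_tsv(path)
        scores = df[[f"state{k+1}" for k in range(15)]].to_numpy()
        for i in range(10):
            assert table.state_at("chr1", i * 200) == int(np.argmax(scores[i])) + 1


def test_annotate_and_summarize_margins(category_annotation):
    specs = [
        ("GAIN", 9_500), ("GAIN", 15_000), ("LOST", 9_200),
        ("LOST", 70_000), ("GAIN", 70_400),
    ]
    docrs = [
        DocrRecord(
            interval=GenomicInterval("chr1", c - 100, c + 100),
            center=c,
            log2fc=1.0 if d == "GAIN" else -1.0,
            pvalue=0.001,
            fdr=0.01,
            direction=d,
        )
        for d, c in specs
    ]
    states = ChromatinStateTable(
        state_frame([("chr1", b, np.eye(15)[2]) for b in range(9_000, 9_600, 200)])
    )
    annotate_docrs(docrs, category_annotation, states)
    assert [d.category for d in docrs] == [
        "promoter", "genic", "promoter", "intergenic", "intergenic"
    ]
    assert docrs[0].chromatin_state == 3
    assert docrs[3].chromatin_state is None

    summary = summarize_docrs(docrs)
    assert summary["count"].sum() == 5
    gain = summary[summary["direction"] == "GAIN"]
    assert gain["count"].sum() == 3
    assert set(gain["category"]) == {"promoter", "genic", "intergenic"}
    lost = summary[summary["direction"] == "LOST"]
    assert lost["count"].sum() == 2
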