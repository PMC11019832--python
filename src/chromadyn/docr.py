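"""Differential open-chromatin region (DOCR) calling and annotation.

Pipeline: nucleosome-free fragment filter -> global OCR construction from
per-sample peaks (two-stage merge) -> fragment counting -> NB differential
test on the high-confidence set -> genomic-category and chromatin-state
annotation -> summary tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation
from .intervals import GenomicInterval, IntervalError, merge_intervals, sort_intervals
from .nb import CountMatrix, benjamini_hochberg, nb_differential

log = logging.getLogger(__name__)


@dataclass
class DocrConfig:
    """Thresholds of the accessibility pipeline.

    Defaults follow the analysis conventions this pipeline encodes:
    nucleosome-free fragments are strictly shorter than 100 bases, merged
    peaks within 100 bases coalesce, a region is testable only with at
    least 100 raw reads in every sample, significance is FDR < 0.05, and
    a promoter spans 1 kb upstream to 500 bases downstream of an
    annotated TSS. Chromatin states live in 200-base bins with 15 states.
    """

    nfr_max_len: int = 100
    merge_gap: int = 100
    min_reads_per_sample: int = 100
    fdr_threshold: float = 0.05
    promoter_upstream: int = 1000
    promoter_downstream: int = 500
    state_bin: int = 200
    n_states: int = 15

    def __post_init__(self) -> None:
        for name in (
            "nfr_max_len",
            "merge_gap",
            "min_reads_per_sample",
            "promoter_upstream",
            "promoter_downstream",
            "state_bin",
            "n_states",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")


@dataclass
class DocrRecord:
    """A significantly differential open-chromatin region."""

    interval: GenomicInterval
    center: int
    log2fc: float
    pvalue: float
    fdr: float
    direction: str  # GAIN | LOST
    category: Optional[str] = None  # promoter | genic | intergenic
    chromatin_state: Optional[int] = None  # 1..n_states, None if unscored

    def __post_init__(self) -> None:
        if self.direction not in ("GAIN", "LOST"):
            raise ValueError(f"direction must be GAIN or LOST, got {self.direction}")
        if not 0 <= self.fdr <= 1:
            raise ValueError("fdr outside [0, 1]")


# ----------------------------------------------------------------------
def extract_nucleosome_free(
    fragments: Iterable[GenomicInterval], nfr_max_len: int = 100
) -> list[GenomicInterval]:
    """Keep fragments strictly shorter than ``nfr_max_len`` bases.

    Sub-nucleosomal (<100 b) fragments reflect protein-free accessible
    DNA; mono-nucleosome-sized fragments are discarded. Fragment length
    is ``end - start``; zero-length records are invalid upstream.
    """
    kept, dropped = [], 0
    for f in fragments:
        if len(f) < nfr_max_len:
            kept.append(f)
        else:
            dropped += 1
    log.info(
        "nucleosome-free filter: kept %d, dropped %d (max_len=%d)",
        len(kept),
        dropped,
        nfr_max_len,
    )
    return kept


def call_peaks_simple(
    fragments: Sequence[GenomicInterval],
    chrom_sizes: dict[str, int],
    window: int = 200,
    p_cut: float = 1e-6,
) -> list[GenomicInterval]:
    """Minimal sliding-window Poisson peak caller (pipeline plumbing).

    Counts fragment midpoints in non-overlapping windows, tests each
    window against the genome-wide background rate with a Poisson
    upper-tail test, and merges adjacent significant windows. This is a
    simple fallback so the pipeline can run end-to-end on raw fragments;
    it makes no claim of equivalence with dedicated peak callers.
    """
    if not fragments:
        warnings.warn("no fragments supplied; emitting no peaks")
        return []
    genome = sum(chrom_sizes.values())
    n = len(fragments)
    lam = n * window / genome  # expected midpoints per window
    peaks: list[GenomicInterval] = []
    mids: dict[str, list[int]] = {}
    for f in fragments:
        mids.setdefault(f.chrom, []).append((f.start + f.end) // 2)
    for chrom in sorted(mids):
        size = chrom_sizes[chrom]
        m = np.asarray(mids[chrom])
        n_win = int(np.ceil(size / window))
        counts = np.bincount(np.minimum(m // window, n_win - 1), minlength=n_win)
        pvals = stats.poisson.sf(counts - 1, lam)
        sig = np.flatnonzero(pvals < p_cut)
        if sig.size == 0:
            continue
        runs = np.split(sig, np.flatnonzero(np.diff(sig) > 1) + 1)
        for r in runs:
            start = int(r[0]) * window
            end = min((int(r[-1]) + 1) * window, size)
            peaks.append(GenomicInterval(chrom, start, end))
    return peaks


def build_global_ocrs(
    peak_sets: Sequence[Sequence[GenomicInterval]], merge_gap: int = 100
) -> list[GenomicInterval]:
    """Merge per-sample peaks into a global open-chromatin-region set.

    Two-stage merge: overlapping/touching peaks across all samples are
    unioned, then merged regions within ``merge_gap`` bases of each other
    are coalesced.
    """
    if not peak_sets:
        raise ValueError("need at least one peak set")
    all_peaks = [p for ps in peak_sets for p in ps]
    stage1 = merge_intervals(all_peaks, gap=0)
    stage2 = merge_intervals(stage1, gap=merge_gap)
    log.info(
        "global OCRs: %d peaks -> %d overlap-merged -> %d gap-merged",
        len(all_peaks),
        len(stage1),
        len(stage2),
    )
    return stage2


def count_fragments(
    ocrs: Sequence[GenomicInterval],
    fragments_per_sample: dict[str, Sequence[GenomicInterval]],
    conditions: dict[str, str],
) -> CountMatrix:
    """Count fragments overlapping each OCR (>= 1 bp) per sample.

    A fragment spanning two OCRs counts in both. Half-open intervals:
    a fragment abutting an OCR end shares no base and does not count.
    """
    ocrs = sort_intervals(ocrs)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {o.chrom for o in ocrs}:
        idx = np.array([i for i, o in enumerate(ocrs) if o.chrom == chrom])
        starts = np.array([ocrs[i].start for i in idx])
        ends = np.array([ocrs[i].end for i in idx])
        by_chrom[chrom] = (starts, ends, idx)

    sample_ids = sorted(fragments_per_sample)
    counts = np.zeros((len(ocrs), len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        frags = fragments_per_sample[sid]
        if not frags:
            warnings.warn(f"sample {sid!r} has zero fragments")
            continue
        for chrom, (starts, ends, idx) in by_chrom.items():
            fs = np.array([f.start for f in frags if f.chrom == chrom])
            fe = np.array([f.end for f in frags if f.chrom == chrom])
            if fs.size == 0:
                continue
            # OCRs are disjoint+sorted: overlapping OCRs form a contiguous range
            lo = np.searchsorted(ends, fs, side="right")
            hi = np.searchsorted(starts, fe, side="left")
            single = hi == lo + 1
            # vectorized add for single-overlap fragments
            add = np.bincount(lo[single], minlength=len(idx))
            counts[idx, j] += add
            multi = np.flatnonzero(hi > lo + 1)
            for k in multi:
                counts[idx[lo[k] : hi[k]], j] += 1
    feature_ids = [
        o.name or f"{o.chrom}:{o.start}-{o.end}" for o in ocrs
    ]
    return CountMatrix(
        counts=counts,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        conditions=[conditions[s] for s in sample_ids],
    )


# ----------------------------------------------------------------------
def call_docrs(
    ocrs: Sequence[GenomicInterval],
    matrix: CountMatrix,
    contrast: tuple[str, str],
    config: DocrConfig = DocrConfig(),
) -> tuple[list[DocrRecord], pd.DataFrame]:
    """Test high-confidence OCRs for differential accessibility.

    The testable set is OCRs with at least ``min_reads_per_sample`` RAW
    reads in EVERY sample of the contrast; the NB Wald test and the BH
    adjustment run over that set only. A DOCR is a testable OCR with
    FDR strictly below ``fdr_threshold``; direction is GAIN when treated
    accessibility exceeds control (log2fc > 0), LOST otherwise.

    Returns the DOCR records plus the full per-testable-region results
    table (columns of :func:`chromadyn.nb.nb_differential` plus
    ``testable`` bookkeeping in its attrs).
    """
    ocrs = sort_intervals(ocrs)
    if len(ocrs) != matrix.n_features:
        raise ValueError("OCR list and count matrix are not aligned")
    used_cols = np.concatenate(
        [matrix.columns_for(contrast[0]), matrix.columns_for(contrast[1])]
    )
    testable = np.all(
        matrix.counts[:, used_cols] >= config.min_reads_per_sample, axis=1
    )
    log.info(
        "OCRs: %d total, %d testable (>= %d reads in every sample)",
        len(ocrs),
        int(testable.sum()),
        config.min_reads_per_sample,
    )
    sub = CountMatrix(
        counts=matrix.counts[testable],
        feature_ids=[f for f, t in zip(matrix.feature_ids, testable) if t],
        sample_ids=matrix.sample_ids,
        conditions=matrix.conditions,
    )
    results = nb_differential(sub, contrast)
    results.attrs["n_ocrs"] = len(ocrs)
    results.attrs["n_testable"] = int(testable.sum())

    docrs: list[DocrRecord] = []
    testable_ocrs = [o for o, t in zip(ocrs, testable) if t]
    for ocr, (fid, row) in zip(testable_ocrs, results.iterrows()):
        if not np.isfinite(row["fdr"]):
            continue
        if row["fdr"] < config.fdr_threshold:
            docrs.append(
                DocrRecord(
                    interval=ocr,
                    center=ocr.center,
                    log2fc=float(row["log2fc"]),
                    pvalue=float(row["pvalue"]),
                    fdr=float(row["fdr"]),
                    direction="GAIN" if row["log2fc"] > 0 else "LOST",
                )
            )
    log.info("DOCRs: %d at FDR < %g", len(docrs), config.fdr_threshold)
    return docrs, results


def classify_genomic_category(
    center: int,
    chrom: str,
    annotation: GenomeAnnotation,
    config: DocrConfig = DocrConfig(),
) -> str:
    """Assign promoter / genic / intergenic by the region center.

    Promoter: the center falls in the window from ``promoter_upstream``
    bases upstream to ``promoter_downstream`` bases downstream of ANY
    annotated TSS, measured in the gene's orientation (half-open at the
    downstream edge). Otherwise genic if the center lies in any gene
    body, else intergenic. Precedence: promoter > genic > intergenic.
    """
    for t in annotation.tss_sites(chrom):
        offset = center - t.position if t.strand == "+" else t.position - center
        if -config.promoter_upstream <= offset < config.promoter_downstream:
            return "promoter"
    for g in annotation.genes_on(chrom):
        if g.body_start <= center < g.body_end:
            return "genic"
    return "intergenic"


class ChromatinStateTable:
    """Per-bin chromatin-state scores (fixed-width bins x n_states).

    The consensus state of a bin is the argmax over states, ties broken
    toward the lowest state index. Bins absent from the table are
    unscored and yield ``None``.
    """

    def __init__(self, frame: pd.DataFrame, bin_size: int = 200, n_states: int = 15):
        required = {"chrom", "start"}
        if not required.issubset(frame.columns):
            raise ValueError("state table needs 'chrom' and 'start' columns")
        score_cols = [c for c in frame.columns if c.startswith("state")]
        if len(score_cols) != n_states:
            raise ValueError(
                f"expected {n_states} state columns, found {len(score_cols)}"
            )
        self.bin_size = bin_size
        self.n_states = n_states
        self.score_cols = score_cols
        self._lookup: dict[tuple[str, int], int] = {}
        scores = frame[score_cols].to_numpy(dtype=np.float64)
        consensus = np.argmax(scores, axis=1) + 1  # argmax takes first on ties
        for (chrom, start), state in zip(
            frame[["chrom", "start"]].itertuples(index=False), consensus
        ):
            self._lookup[(chrom, int(start) // bin_size)] = int(state)

    def state_at(self, chrom: str, pos: int) -> Optional[int]:
        return self._lookup.get((chrom, pos // self.bin_size))

    @classmethod
    def read_tsv(cls, path, bin_size: int = 200, n_states: int = 15):
        return cls(pd.read_csv(path, sep="\t"), bin_size, n_states)


def annotate_docrs(
    docrs: Sequence[DocrRecord],
    annotation: GenomeAnnotation,
    states: Optional[ChromatinStateTable] = None,
    config: DocrConfig = DocrConfig(),
) -> list[DocrRecord]:
    """Fill genomic category and chromatin state on each DOCR (in place)."""
    for d in docrs:
        d.category = classify_genomic_category(
            d.center, d.interval.chrom, annotation, config
        )
        if states is not None:
            d.chromatin_state = states.state_at(d.interval.chrom, d.center)
    return list(docrs)


def summarize_docrs(docrs: Sequence[DocrRecord]) -> pd.DataFrame:
    """Contingency counts by (direction x category x chromatin state).

    Margins sum to the total number of DOCRs; unscored states appear as
    the string ``"NA"`` so the table remains complete.
    """
    if not docrs:
        return pd.DataFrame(columns=["direction", "category", "state", "count"])
    rows = [
        (
            d.direction,
            d.category or "NA",
            d.chromatin_state if d.chromatin_state is not None else "NA",
        )
        for d in docrs
    ]
    df = pd.DataFrame(rows, columns=["direction", "category", "state"])
    out = (
        df.groupby(["direction", "category", "state"], dropna=False)
        .size()
        .reset_index(name="count")
    )
    return out


def docrs_to_frame(docrs: Sequence[DocrRecord]) -> pd.DataFrame:
    """Flat table of DOCRs (the on-disk results format)."""
    return pd.DataFrame(
        {
            "chrom": [d.interval.chrom for d in docrs],
            "start": [d.interval.start for d in docrs],
            "end": [d.interval.end for d in docrs],
            "center": [d.center for d in docrs],
            "log2fc": [d.log2fc for d in docrs],
            "pvalue": [d.pvalue for d in docrs],
            "fdr": [d.fdr for d in docrs],
            "direction": [d.direction for d in docrs],
            "category": [d.category for d in docrs],
            "state": [d.chromatin_state for d in docrs],
        }
    )
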