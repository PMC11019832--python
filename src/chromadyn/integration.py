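"""Cohort-level accessibility clustering, ER-signal matrices, and
expression joins at differential regions.

Covers: merging technical-replicate coverage, hierarchical clustering of
tumor-cohort signal at super-enhancer regions (rows row-centered,
Ward/Euclidean, tree cut at k), ER-minus-input scaled profiles with an
externally imposed row order, and RNA counts in +/-250 b windows around
region centers joined to nearest-gene differential-expression flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .annotation import GenomeAnnotation, locate
from .coverage import CoverageTrack, merge_replicate_tracks  # re-export
from .docr import DocrRecord
from .intervals import GenomicInterval
from .matrix import SignalMatrix, row_transform, scaled_region_matrix

log = logging.getLogger(__name__)

__all__ = [
    "merge_replicate_tracks",
    "CohortMatrix",
    "cohort_cluster",
    "er_matrix",
    "rna_at_docrs",
]


@dataclass
class CohortMatrix:
    """Region x cohort-sample mean signal with row cluster labels."""

    values: np.ndarray  # (n_regions, n_samples)
    region_ids: list[str]
    sample_ids: list[str]
    subtypes: list[str]  # per sample: basal | non_basal
    clusters: np.ndarray  # per region, labels 1..k
    chrom_table: pd.DataFrame  # cluster x chromosome counts

    def __post_init__(self) -> None:
        k = self.clusters.max() if self.clusters.size else 0
        labels = set(np.unique(self.clusters))
        if self.clusters.size and labels != set(range(1, int(k) + 1)):
            raise ValueError("cluster labels must be contiguous 1..k")


def cohort_cluster(
    sample_tracks: dict[str, CoverageTrack],
    subtypes: dict[str, str],
    regions: Sequence[GenomicInterval],
    k: int = 6,
) -> CohortMatrix:
    """Hierarchically cluster regions by cohort accessibility profiles.

    Per region and sample the mean signal over the region is taken, rows
    are centered (row minus row mean), and rows are clustered with Ward
    linkage on Euclidean distances; the tree is cut into ``k`` clusters.
    Columns are grouped by subtype (basal first) without clustering
    across the subtype boundary. Also emits a cluster-by-chromosome
    count table whose row sums equal the cluster sizes.
    """
    if len(regions) < k:
        raise ValueError(f"k={k} exceeds number of regions {len(regions)}")
    sample_ids = sorted(
        sample_tracks, key=lambda s: (subtypes.get(s, ""), s)
    )  # basal sorts before non_basal
    values = np.zeros((len(regions), len(sample_ids)))
    region_ids = []
    for i, r in enumerate(regions):
        region_ids.append(r.name or f"{r.chrom}:{r.start}-{r.end}")
        for j, sid in enumerate(sample_ids):
            values[i, j] = sample_tracks[sid].mean_over(r.chrom, r.start, r.end)
    centered = values - values.mean(axis=1, keepdims=True)
    if k == 1:
        clusters = np.ones(len(regions), dtype=int)
    else:
        Z = linkage(centered, method="ward", metric="euclidean")
        clusters = fcluster(Z, t=k, criterion="maxclust")
        # relabel contiguously 1..k in order of first appearance
        remap: dict[int, int] = {}
        for c in clusters:
            if c not in remap:
                remap[c] = len(remap) + 1
        clusters = np.array([remap[c] for c in clusters], dtype=int)
    chroms = [r.chrom for r in regions]
    chrom_table = (
        pd.DataFrame({"cluster": clusters, "chrom": chroms})
        .groupby(["cluster", "chrom"])
        .size()
        .unstack(fill_value=0)
    )
    log.info(
        "cohort clustering: %d regions, %d samples, k=%d",
        len(regions),
        len(sample_ids),
        k,
    )
    return CohortMatrix(
        values=values,
        region_ids=region_ids,
        sample_ids=sample_ids,
        subtypes=[subtypes[s] for s in sample_ids],
        clusters=clusters,
        chrom_table=chrom_table,
    )


def er_matrix(
    er_track: CoverageTrack,
    input_track: CoverageTrack,
    se_regions: Sequence[GenomicInterval],
    row_order: Sequence[str],
    body_bins: int = 20,
    flank: int = 2000,
    flank_bin: int = 200,
) -> SignalMatrix:
    """ER-minus-input scaled profile matrix with an imposed row order.

    Builds the 10 + 20 + 10 scaled profile of (ER - input) across each
    super-enhancer region, reorders rows to ``row_order`` (typically the
    cohort heat-map order), and z-scores each row. Unknown ids in
    ``row_order`` raise.
    """
    mat_er = scaled_region_matrix(er_track, se_regions, body_bins, flank, flank_bin)
    mat_in = scaled_region_matrix(input_track, se_regions, body_bins, flank, flank_bin)
    diff = SignalMatrix(
        values=mat_er.values - mat_in.values,
        row_ids=list(mat_er.row_ids),
        normalization=dict(mat_er.normalization),
        subtraction="input",
        flagged_rows=sorted(set(mat_er.flagged_rows) | set(mat_in.flagged_rows)),
    )
    index = {rid: i for i, rid in enumerate(diff.row_ids)}
    missing = [rid for rid in row_order if rid not in index]
    if missing:
        raise ValueError(f"row_order ids not matching regions: {missing[:5]}")
    order = [index[rid] for rid in row_order]
    reordered = SignalMatrix(
        values=diff.values[order],
        row_ids=list(row_order),
        normalization=diff.normalization,
        subtraction="input",
        row_order="external",
        flagged_rows=diff.flagged_rows,
    )
    return row_transform(reordered, "zscore")


def rna_at_docrs(
    docrs: Sequence[DocrRecord],
    rna_fragments: Sequence[GenomicInterval],
    gene_results: pd.DataFrame,
    annotation: GenomeAnnotation,
    window: int = 250,
    log2fc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """RNA counts around DOCR centers joined to nearest-gene DE flags.

    Counts RNA fragments overlapping (>= 1 bp) the window
    ``[center - window, center + window]`` of each DOCR, assigns the
    nearest gene, and flags differential expression from
    ``gene_results`` (index gene_id, columns log2fc/fdr): ``up`` iff
    log2fc >= +threshold and fdr <= fdr_threshold, ``down`` iff
    log2fc <= -threshold and fdr <= fdr_threshold, else ``ns``
    (thresholds inclusive). Emits exactly one row per DOCR.
    """
    frag_by_chrom: dict[str, np.ndarray] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for f in rna_fragments:
        tmp.setdefault(f.chrom, []).append((f.start, f.end))
    for c, ivs in tmp.items():
        arr = np.array(sorted(ivs), dtype=np.int64)
        frag_by_chrom[c] = arr

    rows = []
    for i, d in enumerate(docrs):
        c = d.center
        lo, hi = c - window, c + window + 1  # +/- window inclusive of both edges
        arr = frag_by_chrom.get(d.interval.chrom)
        if arr is None:
            count = 0
        else:
            count = int(np.sum((arr[:, 0] < hi) & (arr[:, 1] > lo)))
        hits = locate((d.interval.chrom, c), annotation, "nearest_gene")
        gene = hits[0].gene.gene_id if hits else None
        log2fc = fdr = np.nan
        flag = "ns"
        if gene is not None and gene in gene_results.index:
            log2fc = float(gene_results.loc[gene, "log2fc"])
            fdr = float(gene_results.loc[gene, "fdr"])
            if np.isfinite(log2fc) and np.isfinite(fdr) and fdr <= fdr_threshold:
                if log2fc >= log2fc_threshold:
                    flag = "up"
                elif log2fc <= -log2fc_threshold:
                    flag = "down"
        rows.append(
            {
                "docr_id": d.interval.name
                or f"{d.interval.chrom}:{d.interval.start}-{d.interval.end}",
                "chrom": d.interval.chrom,
                "center": c,
                "direction": d.direction,
                "category": d.category,
                "rna_count": count,
                "nearest_gene": gene,
                "gene_log2fc": log2fc,
                "gene_fdr": fdr,
                "de_flag": flag,
            }
        )
    return pd.DataFrame(rows)
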