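"""ROSE-style super-enhancer identification and SE set comparison.

Enhancer peaks near annotated TSSs are excluded, survivors are stitched
within a fixed genomic distance, stitched regions are scored by
background-subtracted mark signal over their constituents, and the
scaled rank-vs-signal ("hockey stick") curve is cut where its tangent
slope reaches 1; regions above the cutoff are super-enhancers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annotation import GenomeAnnotation
from .coverage import CoverageTrack
from .docr import DocrRecord
from .intervals import GenomicInterval, merge_intervals, sort_intervals

log = logging.getLogger(__name__)


@dataclass
class SeConfig:
    """Stitching and cutoff parameters.

    ``tss_exclusion`` removes peaks whose center lies within that many
    bases of an annotated TSS (the conventional 2,500); ``stitch_distance``
    merges surviving peaks within 12,500 bases; ``slope_window`` sets the
    finite-difference half-window for the tangent-slope estimate as a
    fraction of the number of regions (minimum 1 point).
    """

    stitch_distance: int = 12500
    tss_exclusion: int = 2500
    slope_window: float = 0.01

    def __post_init__(self) -> None:
        if self.stitch_distance <= 0 or self.tss_exclusion <= 0:
            raise ValueError("distances must be positive")
        if self.slope_window <= 0:
            raise ValueError("slope_window must be positive")


@dataclass
class StitchedRegion:
    interval: GenomicInterval
    constituents: list[GenomicInterval]
    score: float = 0.0
    rank: Optional[int] = None
    scaled_rank: Optional[float] = None
    scaled_score: Optional[float] = None
    is_super: bool = False


# ----------------------------------------------------------------------
def stitch_peaks(
    peaks: Sequence[GenomicInterval],
    annotation: GenomeAnnotation,
    config: SeConfig = SeConfig(),
) -> list[StitchedRegion]:
    """TSS-exclude and stitch enhancer peaks.

    A peak is removed when its CENTER lies within ``tss_exclusion`` bases
    of any annotated TSS. Remaining peaks within ``stitch_distance``
    bases of each other merge (transitively) into stitched regions; every
    surviving peak belongs to exactly one stitched region.
    """
    surviving = []
    for p in peaks:
        c = p.center
        near_tss = any(
            abs(c - t.position) <= config.tss_exclusion
            for t in annotation.tss_sites(p.chrom)
        )
        if not near_tss:
            surviving.append(p)
    log.info(
        "TSS exclusion: %d peaks in, %d surviving", len(peaks), len(surviving)
    )
    if not surviving:
        warnings.warn("no peaks survive TSS exclusion; no stitched regions")
        return []
    merged = merge_intervals(surviving, gap=config.stitch_distance)
    regions = []
    for m in merged:
        members = [p for p in surviving if p.chrom == m.chrom and p.start < m.end and m.start < p.end]
        regions.append(StitchedRegion(interval=m, constituents=sort_intervals(members)))
    return regions


def _constituent_score(
    region: StitchedRegion,
    mark_track: CoverageTrack,
    input_track: Optional[CoverageTrack],
) -> float:
    """Sum of (mark - input) signal over constituent peaks, floored at 0."""
    total = 0.0
    for p in region.constituents:
        s = mark_track.integral(p.chrom, p.start, p.end)
        if input_track is not None:
            s -= input_track.integral(p.chrom, p.start, p.end)
        total += s
    return max(total, 0.0)


def rank_and_cutoff(
    regions: Sequence[StitchedRegion],
    mark_track: Optional[CoverageTrack] = None,
    input_track: Optional[CoverageTrack] = None,
    config: SeConfig = SeConfig(),
    scores: Optional[Sequence[float]] = None,
) -> tuple[list[StitchedRegion], float]:
    """Score, rank, and apply the tangent-slope-1 cutoff.

    Scores (if not given directly) are the background-subtracted mark
    signal summed over constituents. Regions are sorted by ascending
    score; with ``x = rank/n`` and ``y`` the min-max scaled score, the
    cutoff is the smallest x where the finite-difference slope of y(x)
    reaches 1. Regions with ``y > y_cutoff`` are super-enhancers. An
    all-equal score vector is degenerate: no super-enhancers.

    Returns the regions (ranked, flags set) and the y cutoff.
    """
    regions = list(regions)
    if len(regions) < 3:
        raise ValueError("need at least 3 stitched regions to rank")
    if scores is None:
        if mark_track is None:
            raise ValueError("either scores or a mark track is required")
        if input_track is None:
            warnings.warn(
                "no input track: scores are raw mark signal (unsubtracted)"
            )
        scores = [
            _constituent_score(r, mark_track, input_track) for r in regions
        ]
    s = np.asarray(scores, dtype=np.float64)
    if s.size != len(regions):
        raise ValueError("scores length mismatch")
    order = np.argsort(s, kind="stable")
    n = s.size
    s_sorted = s[order]
    smin, smax = s_sorted[0], s_sorted[-1]
    for rank_pos, idx in enumerate(order):
        r = regions[idx]
        r.score = float(s[idx])
        r.rank = rank_pos + 1
        r.scaled_rank = (rank_pos + 1) / n
    if smax == smin:
        warnings.warn("degenerate score curve (all scores equal); no supers")
        for r in regions:
            r.scaled_score = 0.0
            r.is_super = False
        return regions, float("inf")
    y = (s_sorted - smin) / (smax - smin)
    x = np.arange(1, n + 1) / n
    w = max(int(round(config.slope_window * n)), 1)
    # centered finite differences, one-sided at the ends
    lo = np.maximum(np.arange(n) - w, 0)
    hi = np.minimum(np.arange(n) + w, n - 1)
    slope = (y[hi] - y[lo]) / (x[hi] - x[lo])
    above = np.flatnonzero(slope >= 1.0)
    if above.size == 0:
        cut_idx = n - 1
    else:
        cut_idx = int(above[0])
    y_cut = float(y[cut_idx])
    for rank_pos, idx in enumerate(order):
        r = regions[idx]
        r.scaled_score = float(y[rank_pos])
        r.is_super = y[rank_pos] > y_cut
    n_super = sum(r.is_super for r in regions)
    log.info("super-enhancers: %d of %d above y_cutoff=%.4f", n_super, n, y_cut)
    return regions, y_cut


# ----------------------------------------------------------------------
def compare_se_sets(
    set_a: Sequence[StitchedRegion],
    set_b: Sequence[StitchedRegion],
    docrs: Sequence[DocrRecord] = (),
) -> dict:
    """Partition two SE sets into a-only / b-only / shared and annotate
    DOCR overlaps.

    An SE in one set is *shared* when its interval intersects (>= 1 bp)
    any SE in the other set; each SE lands in exactly one category, so
    ``|a_only| + |shared_a| = |set_a|``. For every SE the overlapping
    DOCRs are listed with their GAIN/LOST direction.
    """

    def _overlaps_any(r: StitchedRegion, others: Sequence[StitchedRegion]) -> bool:
        return any(r.interval.overlaps(o.interval) for o in others)

    a_only = [r for r in set_a if not _overlaps_any(r, set_b)]
    shared_a = [r for r in set_a if _overlaps_any(r, set_b)]
    b_only = [r for r in set_b if not _overlaps_any(r, set_a)]
    shared_b = [r for r in set_b if _overlaps_any(r, set_a)]

    def _docr_overlaps(r: StitchedRegion):
        return [
            (d, d.direction) for d in docrs if r.interval.overlaps(d.interval)
        ]

    overlaps = {
        "a": [_docr_overlaps(r) for r in set_a],
        "b": [_docr_overlaps(r) for r in set_b],
    }
    return {
        "a_only": a_only,
        "b_only": b_only,
        "shared_a": shared_a,
        "shared_b": shared_b,
        "docr_overlaps": overlaps,
    }
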