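"""Nascent TSS calling and divergent-transcription classification.

Calls transcription start sites from strand-specific 5'-end base counts,
labels each call as annotated (obsTSS) or unannotated (uTSS, further split
genic/intergenic), pairs divergently oriented opposite-strand calls, and
classifies pairs as bidirectional (head-to-head, partner annotated) or
PROMPT (partner unannotated), with distance statistics between groups.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .annotation import GenomeAnnotation
from .coverage import CoverageTrack
from .docr import DocrRecord

log = logging.getLogger(__name__)


@dataclass
class TssConfig:
    """TSS-caller thresholds.

    ``min_count`` of ``None`` means auto: the smallest integer k whose
    Poisson upper tail at the estimated background rate is below 1e-6,
    floored at 5. The 1 kb windows (cluster suppression, annotation
    association, maximum divergent distance) comfortably contain typical
    divergent-pair distances of a few hundred bases.
    """

    min_count: Optional[int] = None
    cluster_window: int = 1000
    annotation_window: int = 1000
    max_divergent_distance: int = 1000
    background_p: float = 1e-6
    min_count_floor: int = 5
    allow_overlapping_pairs: bool = False

    def __post_init__(self) -> None:
        for name in ("cluster_window", "annotation_window", "max_divergent_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TssCall:
    chrom: str
    position: int
    strand: str
    read_count: int
    tss_class: Optional[str] = None  # obsTSS | uTSS
    associated_gene: Optional[str] = None
    utss_subclass: Optional[str] = None  # genic | intergenic
    divergent_partner: Optional["TssCall"] = None
    divergent_class: Optional[str] = None  # bidirectional | PROMPT


@dataclass
class DivergentPair:
    sense: TssCall
    antisense: TssCall
    distance: int
    pair_class: str  # bidirectional | PROMPT

    def __post_init__(self) -> None:
        if self.sense.strand == self.antisense.strand:
            raise ValueError("pair members must be on opposite strands")
        if self.distance < 0:
            raise ValueError("negative pair distance")


# ----------------------------------------------------------------------
def auto_min_count(
    plus: CoverageTrack,
    minus: CoverageTrack,
    genome_size: int,
    config: TssConfig = TssConfig(),
) -> int:
    """Poisson threshold: smallest k with P(X >= k) < background_p at
    the genome-wide background rate, floored at ``min_count_floor``."""
    total = plus.total_signal() + minus.total_signal()
    lam = total / max(2 * genome_size, 1)  # per strand-base
    k = int(stats.poisson.isf(config.background_p, lam)) + 1
    return max(k, config.min_count_floor)


def call_tss(
    plus: CoverageTrack,
    minus: CoverageTrack,
    config: TssConfig = TssConfig(),
    genome_size: Optional[int] = None,
) -> list[TssCall]:
    """Call TSSs from strand-specific single-base 5'-end counts.

    Candidates are bases with count >= ``min_count``. Per strand, calls
    are selected greedily by descending count; an accepted call
    suppresses weaker candidates within ``cluster_window`` bases on the
    same strand. Count ties resolve to the 5'-most position in the
    transcription orientation (smaller coordinate on +, larger on -).
    """
    min_count = config.min_count
    if min_count is None:
        if genome_size is None:
            genome_size = sum(
                int(plus.runs(c)[1][-1]) if plus.runs(c)[0].size else 0
                for c in plus.chroms()
            ) + sum(
                int(minus.runs(c)[1][-1]) if minus.runs(c)[0].size else 0
                for c in minus.chroms()
            )
        min_count = auto_min_count(plus, minus, max(genome_size, 1), config)
    calls: list[TssCall] = []
    for strand, track in (("+", plus), ("-", minus)):
        for chrom in track.chroms():
            pos, vals = track.base_positions(chrom)
            keep = vals >= min_count
            pos, vals = pos[keep], vals[keep]
            if pos.size == 0:
                continue
            # greedy: descending count, ties toward the 5'-most base
            tie = pos if strand == "+" else -pos
            order = np.lexsort((tie, -vals))
            taken = np.zeros(pos.size, dtype=bool)
            sorted_pos = pos  # already ascending from base_positions
            for i in order:
                if taken[i]:
                    continue
                calls.append(
                    TssCall(chrom, int(pos[i]), strand, int(vals[i]))
                )
                lo = bisect.bisect_left(sorted_pos, pos[i] - config.cluster_window)
                hi = bisect.bisect_right(sorted_pos, pos[i] + config.cluster_window)
                taken[lo:hi] = True
    calls.sort(key=lambda c: (c.chrom, c.position, c.strand))
    log.info("TSS caller: %d calls at min_count=%d", len(calls), min_count)
    return calls


def classify_tss(
    calls: Sequence[TssCall],
    annotation: GenomeAnnotation,
    config: TssConfig = TssConfig(),
) -> list[TssCall]:
    """Label calls obsTSS/uTSS; subclassify uTSS as genic/intergenic.

    A call is an obsTSS when a same-strand annotated TSS lies within
    ``annotation_window`` bases; it is assigned to the nearest such TSS.
    Any other call is a uTSS: genic if its position falls inside ANY gene
    body (either strand), else intergenic.
    """
    for call in calls:
        best = None
        for t in annotation.tss_sites(call.chrom):
            if t.strand != call.strand:
                continue
            d = abs(t.position - call.position)
            if d <= config.annotation_window and (best is None or d < best[0]):
                best = (d, t.gene_id)
        if best is not None:
            call.tss_class = "obsTSS"
            call.associated_gene = best[1]
            call.utss_subclass = None
        else:
            call.tss_class = "uTSS"
            call.associated_gene = None
            in_body = any(
                g.body_start <= call.position < g.body_end
                for g in annotation.genes_on(call.chrom)
            )
            call.utss_subclass = "genic" if in_body else "intergenic"
    return list(calls)


def pair_divergent(
    calls: Sequence[TssCall], config: TssConfig = TssConfig()
) -> list[DivergentPair]:
    """Pair each call with its nearest upstream divergent partner.

    For a reference on + at position p, the partner is the nearest
    - strand call at q with ``p - max_divergent_distance <= q <= p``
    (mirrored for - references): the two initiation events point away
    from each other. Each reference takes at most one partner (nearest;
    count ties resolve to the larger read count). The pair class comes
    from the partner: obsTSS partner -> bidirectional, uTSS -> PROMPT.
    Pairs are emitted once per reference call whose partner search
    succeeds; symmetric duplicates (A-B and B-A) are collapsed, keeping
    the orientation whose reference is the obsTSS when only one member
    is annotated.
    """
    by_chrom_strand: dict[tuple[str, str], list[TssCall]] = {}
    for c in calls:
        by_chrom_strand.setdefault((c.chrom, c.strand), []).append(c)
    for lst in by_chrom_strand.values():
        lst.sort(key=lambda c: c.position)

    pairs: list[DivergentPair] = []
    seen: set[tuple[int, int, str]] = set()
    for ref in calls:
        opp = "-" if ref.strand == "+" else "+"
        cands = by_chrom_strand.get((ref.chrom, opp), [])
        if not cands:
            continue
        positions = [c.position for c in cands]
        if ref.strand == "+":
            lo_pos = ref.position - config.max_divergent_distance
            hi_pos = ref.position
        else:
            lo_pos = ref.position
            hi_pos = ref.position + config.max_divergent_distance
        lo = bisect.bisect_left(positions, lo_pos)
        hi = bisect.bisect_right(positions, hi_pos)
        window = cands[lo:hi]
        if not config.allow_overlapping_pairs:
            window = [c for c in window if c.position != ref.position]
        if not window:
            continue
        partner = min(
            window,
            key=lambda c: (abs(c.position - ref.position), -c.read_count),
        )
        ref.divergent_partner = partner
        ref.divergent_class = (
            "bidirectional" if partner.tss_class == "obsTSS" else "PROMPT"
        )
        key_members = (
            min(ref.position, partner.position),
            max(ref.position, partner.position),
            ref.chrom,
        )
        if key_members in seen:
            continue
        # report from the annotated member's perspective where possible
        if ref.tss_class != "obsTSS" and partner.tss_class == "obsTSS":
            continue  # the partner will (or did) report this pair
        seen.add(key_members)
        pairs.append(
            DivergentPair(
                sense=ref,
                antisense=partner,
                distance=abs(ref.position - partner.position),
                pair_class=ref.divergent_class,
            )
        )
    log.info("divergent pairs: %d", len(pairs))
    return pairs


# ----------------------------------------------------------------------
def tss_docr_overlap(
    calls: Sequence[TssCall], docrs: Sequence[DocrRecord]
) -> dict[str, list[TssCall]]:
    """Split TSS calls by the direction of the DOCR they fall inside.

    A call overlaps a DOCR iff its base position lies inside the DOCR's
    half-open interval. Returns GAIN/LOST overlap sets, each further
    split by annotated (obsTSS, 'genic' in the reporting sense) versus
    unannotated calls.
    """
    out: dict[str, list[TssCall]] = {
        "GAIN_obsTSS": [],
        "LOST_obsTSS": [],
        "GAIN_uTSS": [],
        "LOST_uTSS": [],
    }
    by_chrom: dict[str, list[DocrRecord]] = {}
    for d in docrs:
        by_chrom.setdefault(d.interval.chrom, []).append(d)
    for lst in by_chrom.values():
        lst.sort(key=lambda d: d.interval.start)
    for call in calls:
        for d in by_chrom.get(call.chrom, []):
            if d.interval.start <= call.position < d.interval.end:
                key = f"{d.direction}_{call.tss_class or 'uTSS'}"
                out[key].append(call)
                break
    return out


def divergent_distance_stats(
    distances_a: Sequence[int], distances_b: Sequence[int]
) -> dict:
    """Compare divergent-pair distance distributions between two groups.

    Returns the two medians and a two-sided Wilcoxon rank-sum (Mann-
    Whitney U) p-value. With fewer than 3 pairs on either side the
    medians are still reported but the p-value is flagged unreliable.
    """
    a = np.asarray(distances_a, dtype=np.float64)
    b = np.asarray(distances_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both distance sets must be non-empty")
    reliable = a.size >= 3 and b.size >= 3
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "rank_sum_p": p,
        "p_reliable": reliable,
        "n_a": int(a.size),
        "n_b": int(b.size),
    }
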