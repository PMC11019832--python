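"""Gene annotation model and nearest-feature queries.

A :class:`GeneModel` is a single gene body with an oriented transcription
start site (TSS); multi-isoform genes may carry one TSS per annotated
transcript. :class:`GenomeAnnotation` indexes genes per chromosome for
overlap and nearest-feature queries with deterministic tie-breaking.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

from .intervals import GenomicInterval

BIOTYPES = ("protein_coding", "non_coding", "other")


@dataclass(frozen=True)
class GeneModel:
    """A gene body with an oriented TSS.

    The TSS is the 5' end of the annotated body: ``body_start`` on the
    plus strand, ``body_end - 1`` on the minus strand (half-open
    coordinates). ``transcript_tss`` lists every annotated transcript
    start; it always includes the gene-level TSS.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    body_start: int
    body_end: int
    biotype: str = "protein_coding"
    transcript_tss: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.body_start < self.body_end):
            raise ValueError(
                f"gene {self.gene_id}: invalid body "
                f"{self.body_start}-{self.body_end}"
            )
        if not self.transcript_tss:
            object.__setattr__(self, "transcript_tss", (self.tss,))

    @property
    def tss(self) -> int:
        """5' end of the gene body under the half-open convention."""
        return self.body_start if self.strand == "+" else self.body_end - 1

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.body_start, self.body_end, self.strand, self.gene_id
        )


@dataclass(frozen=True)
class TssSite:
    """One annotated transcript start with its host gene's orientation."""

    chrom: str
    position: int
    strand: str
    gene_id: str


class GenomeAnnotation:
    """A set of genes plus chromosome sizes, indexed for spatial queries."""

    def __init__(self, genes: Iterable[GeneModel], chrom_sizes: dict[str, int]):
        self.genes: list[GeneModel] = sorted(
            genes, key=lambda g: (g.chrom, g.body_start, g.gene_id)
        )
        self.chrom_sizes = dict(chrom_sizes)
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            size = self.chrom_sizes.get(g.chrom)
            if size is not None and g.body_end > size:
                raise ValueError(
                    f"gene {g.gene_id} extends past {g.chrom} length {size}"
                )
        # per-chromosome indices
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._starts: dict[str, list[int]] = {
            c: [g.body_start for g in gs] for c, gs in self._by_chrom.items()
        }
        # TSS sites (one per annotated transcript start), sorted by position
        self._tss_by_chrom: dict[str, list[TssSite]] = {}
        for g in self.genes:
            for p in g.transcript_tss:
                self._tss_by_chrom.setdefault(g.chrom, []).append(
                    TssSite(g.chrom, p, g.strand, g.gene_id)
                )
        for c in self._tss_by_chrom:
            self._tss_by_chrom[c].sort(key=lambda t: (t.position, t.gene_id))

    def __len__(self) -> int:
        return len(self.genes)

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return self._by_chrom.get(chrom, [])

    def tss_sites(self, chrom: Optional[str] = None) -> list[TssSite]:
        if chrom is not None:
            return self._tss_by_chrom.get(chrom, [])
        return [t for c in sorted(self._tss_by_chrom) for t in self._tss_by_chrom[c]]

    # ------------------------------------------------------------------
    def overlapping_genes(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """All genes whose body intersects [start, end) by >= 1 bp."""
        genes = self._by_chrom.get(chrom)
        if genes is None:
            warnings.warn(f"chromosome {chrom!r} absent from annotation")
            return []
        # genes sorted by body_start; scan the candidate window
        hits = [g for g in genes if g.body_start < end and start < g.body_end]
        return hits


def _signed_distance(pos: int, feature_pos: int, feature_strand: str) -> int:
    """Signed distance of a position from an oriented feature.

    Negative means the query lies upstream of the feature in the
    feature's own orientation.
    """
    d = pos - feature_pos
    return d if feature_strand == "+" else -d


@dataclass(frozen=True)
class LocateHit:
    gene: GeneModel
    distance: int  # unsigned
    signed_distance: int
    tss_position: Optional[int] = None


def locate(
    query: GenomicInterval | tuple[str, int],
    annotation: GenomeAnnotation,
    mode: Literal["overlapping_genes", "nearest_gene", "nearest_tss"],
) -> list[LocateHit]:
    """Locate annotation features relative to a query.

    ``overlapping_genes`` returns every gene whose body intersects the
    query. ``nearest_gene`` / ``nearest_tss`` return the single feature at
    minimum unsigned distance (distance 0 inside a body / at a TSS), with
    ties broken by lower start coordinate then lexicographic gene_id.
    A query chromosome absent from the annotation yields an empty result
    with a warning.
    """
    if isinstance(query, GenomicInterval):
        chrom, qs, qe = query.chrom, query.start, query.end
    else:
        chrom, pos = query
        qs, qe = pos, pos + 1

    if chrom not in annotation._by_chrom:
        warnings.warn(f"chromosome {chrom!r} absent from annotation")
        return []

    if mode == "overlapping_genes":
        hits = annotation.overlapping_genes(chrom, qs, qe)
        out = []
        for g in hits:
            out.append(LocateHit(g, 0, _signed_distance(qs, g.tss, g.strand)))
        return out

    if mode == "nearest_gene":
        best: Optional[LocateHit] = None
        for g in annotation.genes_on(chrom):
            if g.body_start < qe and qs < g.body_end:
                d = 0
            elif g.body_end <= qs:
                d = qs - g.body_end + 1
            else:
                d = g.body_start - qe + 1
            sd = _signed_distance(qs, g.tss, g.strand)
            cand = LocateHit(g, d, sd)
            if best is None or (d, g.body_start, g.gene_id) < (
                best.distance,
                best.gene.body_start,
                best.gene.gene_id,
            ):
                best = cand
        return [best] if best else []

    if mode == "nearest_tss":
        sites = annotation.tss_sites(chrom)
        if not sites:
            return []
        best_key = None
        best_hit: Optional[LocateHit] = None
        gene_by_id = {g.gene_id: g for g in annotation.genes_on(chrom)}
        for t in sites:
            d = abs(qs - t.position)
            g = gene_by_id[t.gene_id]
            key = (d, g.body_start, g.gene_id)
            if best_key is None or key < best_key:
                best_key = key
                best_hit = LocateHit(
                    g, d, _signed_distance(qs, t.position, t.strand), t.position
                )
        return [best_hit] if best_hit else []

    raise ValueError(f"unknown locate mode {mode!r}")
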