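"""Readers and writers for the plain-text genomics formats the pipeline uses.

BED3/BED6, narrowPeak, bedGraph and chrom.sizes are consumed/emitted with
0-based half-open coordinates; GTF (1-based inclusive) is converted on
read. All writers emit sorted, tab-separated, newline-terminated records.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np

from .annotation import GeneModel, GenomeAnnotation
from .coverage import CoverageTrack
from .intervals import GenomicInterval, sort_intervals

PathLike = Union[str, Path]


# ----------------------------------------------------------------------
# BED / narrowPeak
# ----------------------------------------------------------------------
def read_bed(path: PathLike) -> list[GenomicInterval]:
    """Read BED3/BED6 (or wider; extra columns ignored beyond 6)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score = None
            if len(f) > 4 and f[4] not in (".", ""):
                score = float(f[4])
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            out.append(
                GenomicInterval(f[0], int(f[1]), int(f[2]), strand, name, score)
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in sort_intervals(intervals):
            if iv.name is None and iv.score is None and iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                score = "." if iv.score is None else format_number(iv.score)
                name = iv.name if iv.name is not None else "."
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )


def read_narrowpeak(path: PathLike) -> list[GenomicInterval]:
    """Read a 10-column narrowPeak; only chrom/start/end/name/score/strand used."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}:{lineno}: narrowPeak needs 10 columns")
            strand = f[5] if f[5] in ("+", "-") else "."
            score = float(f[6])  # signalValue column
            name = f[3] if f[3] != "." else None
            out.append(
                GenomicInterval(f[0], int(f[1]), int(f[2]), strand, name, score)
            )
    return out


def write_narrowpeak(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(sort_intervals(intervals)):
            name = iv.name if iv.name is not None else f"peak_{i}"
            sig = iv.score if iv.score is not None else 0.0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\t"
                f"{format_number(sig)}\t-1\t-1\t-1\n"
            )


# ----------------------------------------------------------------------
# bedGraph
# ----------------------------------------------------------------------
def read_bedgraph(
    path: PathLike,
    total_fragments: Optional[int] = None,
    label: str = "",
) -> CoverageTrack:
    """Read a 4-column bedGraph into a CoverageTrack.

    A header comment of the form ``# total_fragments=N`` (written by
    :func:`write_bedgraph`) restores the normalization denominator.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                m = re.search(r"total_fragments=(\d+)", line)
                if m and total_fragments is None:
                    total_fragments = int(m.group(1))
                continue
            if line.startswith(("track", "browser")):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
            per_chrom.setdefault(f[0], []).append(
                (int(f[1]), int(f[2]), float(f[3]))
            )
    track = CoverageTrack(total_fragments, label or Path(path).stem)
    for chrom, rows in per_chrom.items():
        arr = np.array(rows, dtype=np.float64)
        track.set_chrom(
            chrom,
            arr[:, 0].astype(np.int64),
            arr[:, 1].astype(np.int64),
            arr[:, 2],
        )
    return track


def write_bedgraph(track: CoverageTrack, path: PathLike) -> None:
    with open(path, "w") as fh:
        if track.total_fragments is not None:
            fh.write(f"# total_fragments={track.total_fragments}\n")
        for chrom in track.chroms():
            starts, ends, values = track.runs(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{format_number(v)}\n")


# ----------------------------------------------------------------------
# chrom.sizes
# ----------------------------------------------------------------------
def read_chrom_sizes(path: PathLike) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


# ----------------------------------------------------------------------
# GTF
# ----------------------------------------------------------------------
_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attrs(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(
    path: PathLike, chrom_sizes: Optional[dict[str, int]] = None
) -> GenomeAnnotation:
    """Read gene and transcript records from a GTF into a GenomeAnnotation.

    GTF coordinates (1-based inclusive) are converted to 0-based
    half-open. ``gene_id`` and ``gene_type``/``gene_biotype`` attributes
    are parsed; transcript lines contribute per-isoform TSS positions.
    """
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, feature, start1, end1, _, strand, _, attrs = f[:9]
            if feature not in ("gene", "transcript"):
                continue
            a = _parse_attrs(attrs)
            gid = a.get("gene_id")
            if gid is None:
                continue
            start0, end0 = int(start1) - 1, int(end1)
            rec = genes.setdefault(
                gid,
                {
                    "chrom": chrom,
                    "strand": strand,
                    "start": None,
                    "end": None,
                    "biotype": "other",
                    "tx_tss": set(),
                },
            )
            if feature == "gene":
                rec["start"], rec["end"] = start0, end0
                bt = a.get("gene_type", a.get("gene_biotype", "other"))
                if bt == "protein_coding":
                    rec["biotype"] = "protein_coding"
                elif bt in ("lncRNA", "lincRNA", "non_coding", "ncRNA", "miRNA"):
                    rec["biotype"] = "non_coding"
                else:
                    rec["biotype"] = "other"
            else:
                tss = start0 if strand == "+" else end0 - 1
                rec["tx_tss"].add(tss)
    models = []
    for gid, rec in genes.items():
        if rec["start"] is None:
            # transcript-only gene: infer body from transcript extremes
            continue
        tss_set = rec["tx_tss"] or {
            rec["start"] if rec["strand"] == "+" else rec["end"] - 1
        }
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                body_start=rec["start"],
                body_end=rec["end"],
                biotype=rec["biotype"],
                transcript_tss=tuple(sorted(tss_set)),
            )
        )
    return GenomeAnnotation(models, chrom_sizes or {})


def write_gtf(annotation: GenomeAnnotation, path: PathLike, source: str = "chromadyn") -> None:
    """Write gene + transcript lines (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for g in annotation.genes:
            attrs = f'gene_id "{g.gene_id}"; gene_type "{g.biotype}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.body_start + 1}\t{g.body_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for i, tss in enumerate(g.transcript_tss):
                if g.strand == "+":
                    ts, te = tss, g.body_end
                else:
                    ts, te = g.body_start, tss + 1
                tattrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t{i + 1}"; '
                    f'gene_type "{g.biotype}";'
                )
                fh.write(
                    f"{g.chrom}\t{source}\ttranscript\t{ts + 1}\t{te}\t.\t"
                    f"{g.strand}\t.\t{tattrs}\n"
                )


def format_number(x: float) -> str:
    """Compact numeric formatting: integers without decimals, else repr."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))
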