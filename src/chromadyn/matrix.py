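"""Normalized region-by-bin signal matrices, difference maps, and metaplots.

Signal is depth-normalized to 10 million fragments, averaged per base in
equal-width bins across anchored windows (or scaled across variable-length
regions), optionally control-subtracted (total H3 for histone marks, input
for RNAPII), and summarized column-wise as metaplots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .intervals import GenomicInterval

NORMALIZATION_CONSTANT = 1e7


@dataclass
class MatrixSpec:
    """Layout of an anchored signal matrix.

    ``anchor`` selects the reference point (region center or TSS);
    ``flank`` is the half-window in bases; the window is split into
    ``n_bins`` equal bins. ``orientation='by_strand'`` reverses rows on
    minus-strand anchors so downstream is always rightward.
    """

    anchor: str = "region_center"  # region_center | tss
    flank: int = 1000
    n_bins: int = 100
    orientation: str = "none"  # none | by_strand
    sort_key: str = "external_order"  # abs_log2fc_desc | pair_distance_asc | external_order

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.flank <= 0:
            raise ValueError("flank must be positive")


@dataclass
class SignalMatrix:
    """Regions x bins of normalized signal with provenance."""

    values: np.ndarray  # (n_rows, n_bins)
    row_ids: list[str]
    normalization: dict = field(default_factory=dict)
    subtraction: str = "none"  # none | H3 | input | difference
    row_order: str = "input"
    flagged_rows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("matrix values must be 2-D")
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row_ids length mismatch")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.row_ids, name="region"),
            columns=[f"bin{i + 1}" for i in range(self.n_bins)],
        )


# ----------------------------------------------------------------------
def normalize_depth(track: CoverageTrack) -> CoverageTrack:
    """Scale a track to depth per 10 million fragments.

    Every value is multiplied by 1e7 / total_fragments. Guarded by the
    track's ``normalized`` flag so normalization is applied once.
    """
    if track.normalized:
        return track
    if not track.total_fragments:
        raise ValueError(
            f"track {track.label!r}: total_fragments required for normalization"
        )
    out = track.scale(NORMALIZATION_CONSTANT / track.total_fragments)
    out.normalized = True
    return out


def _anchor_of(region: GenomicInterval, spec: MatrixSpec) -> int:
    if spec.anchor == "region_center":
        return region.center
    if spec.anchor == "tss":
        # anchored at the oriented 5' end of the region
        return region.start if region.strand != "-" else region.end - 1
    raise ValueError(f"unknown anchor {spec.anchor!r}")


def region_matrix(
    track: CoverageTrack,
    regions: Sequence[GenomicInterval],
    spec: MatrixSpec = MatrixSpec(),
) -> SignalMatrix:
    """Average per-base signal in ``n_bins`` bins over anchored windows.

    Each row covers ``[anchor - flank, anchor + flank)``. Windows running
    past a chromosome end are truncated to available bases and the row is
    flagged. With ``orientation='by_strand'`` minus-strand rows are
    reversed.
    """
    values = np.zeros((len(regions), spec.n_bins))
    flagged = []
    row_ids = []
    for i, r in enumerate(regions):
        rid = r.name or f"{r.chrom}:{r.start}-{r.end}"
        row_ids.append(rid)
        a = _anchor_of(r, spec)
        start, end = a - spec.flank, a + spec.flank
        if start < 0:
            start = 0
            flagged.append(rid)
        row = track.bin_means(r.chrom, start, end, spec.n_bins)
        if spec.orientation == "by_strand" and r.strand == "-":
            row = row[::-1]
        values[i] = row
    return SignalMatrix(
        values=values,
        row_ids=row_ids,
        normalization={
            "constant": NORMALIZATION_CONSTANT,
            "total_fragments": track.total_fragments,
            "normalized": track.normalized,
        },
        row_order=spec.sort_key,
        flagged_rows=flagged,
    )


def subtract_control(
    mark: SignalMatrix, control: SignalMatrix, mode: str
) -> SignalMatrix:
    """Elementwise mark minus control (H3 or input); negatives retained."""
    if mode not in ("H3", "input"):
        raise ValueError(f"mode must be 'H3' or 'input', got {mode!r}")
    if mark.values.shape != control.values.shape:
        raise ValueError(
            f"shape mismatch: mark {mark.values.shape} vs control "
            f"{control.values.shape}"
        )
    if mark.row_ids != control.row_ids:
        raise ValueError("row id mismatch between mark and control matrices")
    return SignalMatrix(
        values=mark.values - control.values,
        row_ids=list(mark.row_ids),
        normalization=dict(mark.normalization),
        subtraction=mode,
        row_order=mark.row_order,
        flagged_rows=sorted(set(mark.flagged_rows) | set(control.flagged_rows)),
    )


def difference_matrix(treated: SignalMatrix, control: SignalMatrix) -> SignalMatrix:
    """Per-bin treated-minus-control difference map."""
    if treated.values.shape != control.values.shape:
        raise ValueError(
            f"shape mismatch: treated {treated.values.shape} vs control "
            f"{control.values.shape}"
        )
    if treated.row_ids != control.row_ids:
        raise ValueError("row id mismatch between difference operands")
    return SignalMatrix(
        values=treated.values - control.values,
        row_ids=list(treated.row_ids),
        normalization=dict(treated.normalization),
        subtraction="difference",
        row_order=treated.row_order,
        flagged_rows=sorted(set(treated.flagged_rows) | set(control.flagged_rows)),
    )


def metaplot(matrix: SignalMatrix, with_sem: bool = False):
    """Column means across all rows (the average profile).

    With ``with_sem`` also returns the per-bin standard error of the
    mean. Raises on an empty matrix.
    """
    if matrix.values.shape[0] == 0:
        raise ValueError("cannot metaplot an empty matrix")
    means = matrix.values.mean(axis=0)
    if with_sem:
        n = matrix.values.shape[0]
        sem = matrix.values.std(axis=0, ddof=0) / np.sqrt(n)
        return means, sem
    return means


def scaled_region_matrix(
    track: CoverageTrack,
    regions: Sequence[GenomicInterval],
    body_bins: int = 20,
    flank: int = 2000,
    flank_bin: int = 200,
) -> SignalMatrix:
    """Scaled profile: fixed flank bins around a variable-width body.

    Each row is ``flank/flank_bin`` upstream bins of ``flank_bin`` bases,
    ``body_bins`` equal-width bins across the region (variable bases per
    bin), and the mirrored downstream flank — 10 + 20 + 10 = 40 bins at
    the defaults. Regions shorter than ``body_bins`` bases are flagged
    and profiled with a single merged body bin replicated.
    """
    n_flank = flank // flank_bin
    n_total = 2 * n_flank + body_bins
    values = np.zeros((len(regions), n_total))
    flagged = []
    row_ids = []
    for i, r in enumerate(regions):
        rid = r.name or f"{r.chrom}:{r.start}-{r.end}"
        row_ids.append(rid)
        up_start = r.start - flank
        if up_start < 0:
            up_start = 0
            flagged.append(rid)
        up = (
            track.bin_means(r.chrom, up_start, r.start, n_flank)
            if r.start > up_start
            else np.zeros(n_flank)
        )
        if len(r) >= body_bins:
            body = track.bin_means(r.chrom, r.start, r.end, body_bins)
        else:
            flagged.append(rid)
            body = np.full(body_bins, track.mean_over(r.chrom, r.start, r.end))
        down = track.bin_means(r.chrom, r.end, r.end + flank, n_flank)
        values[i] = np.concatenate([up, body, down])
    return SignalMatrix(
        values=values,
        row_ids=row_ids,
        normalization={
            "constant": NORMALIZATION_CONSTANT,
            "total_fragments": track.total_fragments,
            "normalized": track.normalized,
        },
        flagged_rows=sorted(set(flagged)),
    )


def row_transform(matrix: SignalMatrix, mode: str) -> SignalMatrix:
    """Row-center or row z-score a matrix.

    ``center``: subtract the row mean (rows then sum to 0). ``zscore``:
    centered values divided by the population standard deviation
    (divisor n); zero-variance rows become all zeros and are flagged.
    """
    if mode not in ("zscore", "center"):
        raise ValueError(f"mode must be 'zscore' or 'center', got {mode!r}")
    if mode == "zscore" and matrix.n_bins < 2:
        raise ValueError("zscore needs at least 2 columns")
    centered = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    flagged = list(matrix.flagged_rows)
    if mode == "center":
        values = centered
    else:
        sd = matrix.values.std(axis=1, ddof=0, keepdims=True)
        zero = sd[:, 0] == 0
        sd[zero] = 1.0
        values = centered / sd
        values[zero] = 0.0
        flagged.extend(rid for rid, z in zip(matrix.row_ids, zero) if z)
    return SignalMatrix(
        values=values,
        row_ids=list(matrix.row_ids),
        normalization=dict(matrix.normalization),
        subtraction=matrix.subtraction,
        row_order=matrix.row_order,
        flagged_rows=sorted(set(flagged)),
    )


def sort_rows(
    matrix: SignalMatrix,
    key_values: Sequence[float],
    descending: bool = False,
) -> SignalMatrix:
    """Reorder rows by an external key (e.g. |log2FC| or pair distance)."""
    key = np.asarray(key_values, dtype=np.float64)
    if key.size != len(matrix.row_ids):
        raise ValueError("key length does not match row count")
    order = np.argsort(-key if descending else key, kind="stable")
    return SignalMatrix(
        values=matrix.values[order],
        row_ids=[matrix.row_ids[i] for i in order],
        normalization=dict(matrix.normalization),
        subtraction=matrix.subtraction,
        row_order="sorted",
        flagged_rows=list(matrix.flagged_rows),
    )
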