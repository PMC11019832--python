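"""Run-length coverage tracks with exact binned-signal extraction.

A :class:`CoverageTrack` stores, per chromosome, sorted non-overlapping
runs ``(start, end, value)`` — the in-memory form of a bedGraph. Signal
extraction integrates the step function exactly via prefix sums, so bin
means are exact (not sampled) regardless of bin width.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional

import numpy as np


class CoverageTrack:
    """Piecewise-constant genomic signal with a depth-normalization record.

    Parameters
    ----------
    total_fragments : int, optional
        Number of aligned fragments behind the track; required before
        depth normalization.
    label : str
        Free-form track name (mark, sample, condition).
    """

    def __init__(self, total_fragments: Optional[int] = None, label: str = ""):
        # chrom -> (starts, ends, values) as numpy arrays, sorted, non-overlapping
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, np.ndarray] = {}  # prefix integral per chrom
        self.total_fragments = total_fragments
        self.label = label
        self.normalized = False

    # ------------------------------------------------------------------
    def set_chrom(
        self,
        chrom: str,
        starts: np.ndarray,
        ends: np.ndarray,
        values: np.ndarray,
    ) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=np.float64)
        if starts.size:
            if np.any(starts >= ends):
                raise ValueError(f"{chrom}: run with start >= end")
            if np.any(starts < 0):
                raise ValueError(f"{chrom}: negative coordinate")
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"{chrom}: overlapping runs")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"{chrom}: non-finite value")
        self._runs[chrom] = (starts, ends, values)
        self._cum[chrom] = np.concatenate(
            [[0.0], np.cumsum((ends - starts) * values)]
        )

    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._runs.get(
            chrom,
            (
                np.empty(0, np.int64),
                np.empty(0, np.int64),
                np.empty(0, np.float64),
            ),
        )

    # ------------------------------------------------------------------
    def _integral_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integral of the signal over [0, pos) for each position."""
        if chrom not in self._runs:
            return np.zeros(len(pos), dtype=np.float64)
        starts, ends, values = self._runs[chrom]
        cum = self._cum[chrom]
        pos = np.asarray(pos, dtype=np.int64)
        idx = np.searchsorted(starts, pos, side="right")  # runs fully left + maybe current
        out = cum[idx].copy()
        inside = idx > 0
        if np.any(inside):
            k = idx[inside] - 1
            # subtract the part of run k that lies at or beyond pos
            over = np.maximum(ends[k] - np.maximum(pos[inside], starts[k]), 0)
            out[inside] -= over * values[k]
        return out

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Exact integral of per-base signal over [start, end)."""
        res = self._integral_at(chrom, np.array([start, end]))
        return float(res[1] - res[0])

    def bin_means(
        self, chrom: str, start: int, end: int, n_bins: int
    ) -> np.ndarray:
        """Mean per-base signal in ``n_bins`` equal-width bins over [start, end).

        Bin boundaries are integers; the final bin absorbs the remainder
        when the span is not divisible by ``n_bins``.
        """
        if n_bins < 1 or end <= start:
            raise ValueError("need n_bins >= 1 and end > start")
        width = (end - start) // n_bins
        if width < 1:
            raise ValueError(
                f"span {end - start} too short for {n_bins} bins"
            )
        edges = start + width * np.arange(n_bins + 1, dtype=np.int64)
        edges[-1] = end
        F = self._integral_at(chrom, edges)
        widths = np.diff(edges).astype(np.float64)
        return np.diff(F) / widths

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        return self.integral(chrom, start, end) / (end - start)

    def value_at(self, chrom: str, pos: int) -> float:
        return self.integral(chrom, pos, pos + 1)

    # ------------------------------------------------------------------
    def scale(self, factor: float) -> "CoverageTrack":
        out = CoverageTrack(self.total_fragments, self.label)
        out.normalized = self.normalized
        for c, (s, e, v) in self._runs.items():
            out.set_chrom(c, s, e, v * factor)
        return out

    def copy(self) -> "CoverageTrack":
        return self.scale(1.0)

    def total_signal(self) -> float:
        return float(sum(self._cum[c][-1] for c in self._runs))

    # ------------------------------------------------------------------
    @classmethod
    def from_base_counts(
        cls,
        counts: dict[str, dict[int, float]],
        total_fragments: Optional[int] = None,
        label: str = "",
    ) -> "CoverageTrack":
        """Build a track from sparse single-base counts (e.g. 5' ends)."""
        track = cls(total_fragments, label)
        for chrom, d in counts.items():
            if not d:
                continue
            pos = np.array(sorted(d), dtype=np.int64)
            vals = np.array([d[p] for p in pos], dtype=np.float64)
            track.set_chrom(chrom, pos, pos + 1, vals)
        return track

    @classmethod
    def from_fragments(
        cls,
        fragments: Iterable,
        chrom_sizes: dict[str, int],
        label: str = "",
    ) -> "CoverageTrack":
        """Pileup coverage (fragment overlap depth) from fragment intervals."""
        events: dict[str, list[tuple[int, int]]] = {}
        n = 0
        for f in fragments:
            events.setdefault(f.chrom, []).append((f.start, f.end))
            n += 1
        track = cls(total_fragments=n, label=label)
        for chrom, ivs in events.items():
            arr = np.array(ivs, dtype=np.int64)
            bounds = np.unique(arr)
            depth = np.zeros(len(bounds), dtype=np.float64)
            left = np.searchsorted(bounds, arr[:, 0])
            right = np.searchsorted(bounds, arr[:, 1])
            np.add.at(depth, left, 1.0)
            minus = right[right < len(bounds)]
            np.add.at(depth, minus, -1.0)
            depth = np.cumsum(depth)
            starts = bounds[:-1]
            ends = bounds[1:]
            vals = depth[:-1]
            keep = vals != 0
            track.set_chrom(chrom, starts[keep], ends[keep], vals[keep])
        return track

    def base_positions(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Nonzero single-base positions and values (for 5'-count tracks)."""
        starts, ends, values = self.runs(chrom)
        pos_list = []
        val_list = []
        for s, e, v in zip(starts, ends, values):
            if v != 0:
                pos_list.append(np.arange(s, e, dtype=np.int64))
                val_list.append(np.full(e - s, v))
        if not pos_list:
            return np.empty(0, np.int64), np.empty(0, np.float64)
        return np.concatenate(pos_list), np.concatenate(val_list)


def merge_replicate_tracks(tracks: list[CoverageTrack], label: str = "") -> CoverageTrack:
    """Merge technical replicates into one track by per-base SUM of values.

    Summing (rather than averaging) preserves total fragment counts, so
    downstream depth normalization sees the pooled library.
    """
    if not tracks:
        raise ValueError("need at least one replicate")
    if len(tracks) == 1:
        out = tracks[0].copy()
        out.label = label or tracks[0].label
        return out
    chrom_sets = [set(t.chroms()) for t in tracks]
    all_chroms = set().union(*chrom_sets)
    totals = [t.total_fragments for t in tracks]
    total = sum(t for t in totals if t is not None) if any(
        t is not None for t in totals
    ) else None
    out = CoverageTrack(total, label or tracks[0].label)
    for chrom in sorted(all_chroms):
        bounds_list = []
        for t in tracks:
            s, e, _ = t.runs(chrom)
            bounds_list.append(s)
            bounds_list.append(e)
        bounds = np.unique(np.concatenate(bounds_list))
        if bounds.size < 2:
            continue
        seg_starts = bounds[:-1]
        seg_ends = bounds[1:]
        vals = np.zeros(len(seg_starts), dtype=np.float64)
        for t in tracks:
            F = t._integral_at(chrom, bounds)
            vals += np.diff(F) / (seg_ends - seg_starts)
        keep = vals != 0
        s2, e2, v2 = _compact_runs(seg_starts[keep], seg_ends[keep], vals[keep])
        out.set_chrom(chrom, s2, e2, v2)
    return out


def _compact_runs(
    starts: np.ndarray, ends: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coalesce adjacent runs with equal values."""
    if starts.size == 0:
        return starts, ends, values
    out_s = [starts[0]]
    out_e = [ends[0]]
    out_v = [values[0]]
    for s, e, v in zip(starts[1:], ends[1:], values[1:]):
        if s == out_e[-1] and v == out_v[-1]:
            out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
            out_v.append(v)
    return (
        np.array(out_s, dtype=np.int64),
        np.array(out_e, dtype=np.int64),
        np.array(out_v, dtype=np.float64),
    )
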