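"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: a gene
annotation, per-sample ATAC fragment and peak files with planted
differential regions under negative-binomial replicate noise, strand-
specific 5'-end start-RNA counts with planted divergent TSS pairs,
unimodal/bimodal mark coverage tracks, a heavy-tailed enhancer-peak
signal landscape with planted super-enhancers, and a block-structured
tumor-cohort signal matrix. All generators are pure functions of
(config, seed) and emit files that round-trip through the package
readers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeAnnotation
from .coverage import CoverageTrack
from .intervals import GenomicInterval


@dataclass
class TssPairSpec:
    """One class of planted divergent TSS pairs.

    Distances are drawn log-normally, parameterized by the class MEDIAN
    (the reporting statistic for divergent distances) and a log-scale sd.
    """

    count: int = 300
    median: float = 200.0
    log_sd: float = 0.5
    signal: int = 50


@dataclass
class SeSpec:
    n_peaks: int = 200
    tail_exponent: float = 1.0
    n_super_true: int = 20
    base_scale: float = 1000.0


@dataclass
class CohortSpec:
    n_samples_per_subtype: int = 10
    n_clusters: int = 6
    block_effect: float = 3.0
    noise_sd: float = 1.0
    baseline: float = 10.0


@dataclass
class StateSpec:
    n_states: int = 15
    bin: int = 200


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults model a small two-condition accessibility experiment with
    three replicates per condition: ~30% of tested regions carry a
    planted |log2FC| of 2 (the study-scale fraction of differential
    regions at the late time point), negative-binomial dispersion 0.05,
    a 0.6 nucleosome-free fragment fraction, and divergent-pair distance
    medians of 188 (gain side) and 277 (lost side) bases.
    """

    seed: int = 0
    chrom_sizes: dict = field(
        default_factory=lambda: {
            "chr1": 2_000_000,
            "chr2": 1_500_000,
            "chr3": 1_000_000,
        }
    )
    n_genes: int = 150
    n_regions: int = 200
    frac_differential: float = 0.3
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    n_replicates: int = 3
    region_mean_fragments: float = 500.0
    reads_per_sample: int = 150_000
    nfr_fraction: float = 0.6
    region_width: tuple = (300, 700)
    category_fracs: tuple = (0.25, 0.35, 0.40)  # promoter, genic, intergenic
    tss_pair_spec: dict = field(
        default_factory=lambda: {
            "gain": TssPairSpec(count=300, median=188.0),
            "lost": TssPairSpec(count=300, median=277.0),
        }
    )
    tss_background_rate: float = 0.005  # Poisson rate per strand-base
    se_spec: SeSpec = field(default_factory=SeSpec)
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    state_spec: StateSpec = field(default_factory=StateSpec)

    def __post_init__(self) -> None:
        if not 0 <= self.frac_differential <= 1:
            raise ValueError("frac_differential must be in [0, 1]")
        if not 0 <= self.nfr_fraction <= 1:
            raise ValueError("nfr_fraction must be in [0, 1]")
        for name in ("n_genes", "n_regions", "n_replicates"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-derived generator so stages rerun independently."""
        return np.random.default_rng([int(self.seed) % (2**31), stage])


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside the synthetic inputs."""

    differential_regions: pd.DataFrame = field(default_factory=pd.DataFrame)
    tss_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    super_set: list = field(default_factory=list)
    cohort_clusters: Optional[np.ndarray] = None


# ----------------------------------------------------------------------
def gen_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Place non-overlapping genes with strands and biotypes.

    Genes are laid out in equal slots per chromosome with random offsets
    so bodies never overlap and gene deserts remain for intergenic
    placement. Raises when the requested genes cannot fit.
    """
    rng = config.rng(1)
    if not config.chrom_sizes:
        raise ValueError("chrom_sizes must be non-empty")
    if config.n_genes == 0:
        return GenomeAnnotation([], config.chrom_sizes)
    chroms = sorted(config.chrom_sizes)
    total = sum(config.chrom_sizes.values())
    genes: list[GeneModel] = []
    gid = 0
    remaining = config.n_genes
    for ci, chrom in enumerate(chroms):
        size = config.chrom_sizes[chrom]
        if ci == len(chroms) - 1:
            n_here = remaining
        else:
            n_here = int(round(config.n_genes * size / total))
            n_here = min(n_here, remaining)
        remaining -= n_here
        if n_here == 0:
            continue
        slot = size // n_here
        max_len = min(int(slot * 0.5), 30_000)
        if max_len < 2_000:
            raise ValueError(
                f"{n_here} genes cannot fit on {chrom} (length {size})"
            )
        for i in range(n_here):
            glen = int(rng.integers(max(2_000, max_len // 4), max_len))
            offset = int(rng.integers(0, slot - glen))
            start = i * slot + offset
            strand = "+" if rng.random() < 0.5 else "-"
            u = rng.random()
            biotype = (
                "protein_coding" if u < 0.8 else "non_coding" if u < 0.95 else "other"
            )
            genes.append(
                GeneModel(
                    gene_id=f"G{gid:05d}",
                    chrom=chrom,
                    strand=strand,
                    body_start=start,
                    body_end=start + glen,
                    biotype=biotype,
                )
            )
            gid += 1
    return GenomeAnnotation(genes, config.chrom_sizes)


# ----------------------------------------------------------------------
def _draw_fragment_lengths(rng: np.random.Generator, n: int, nfr_fraction: float) -> np.ndarray:
    """Two-component fragment-length mixture.

    Nucleosome-free component: uniform on [36, 99]; mono-nucleosome
    component: normal(190, 15) truncated to [150, 250].
    """
    is_nfr = rng.random(n) < nfr_fraction
    out = np.empty(n, dtype=np.int64)
    out[is_nfr] = rng.integers(36, 100, size=int(is_nfr.sum()))
    n_mono = int((~is_nfr).sum())
    mono = rng.normal(190.0, 15.0, size=n_mono)
    bad = (mono < 150) | (mono > 250)
    while bad.any():
        mono[bad] = rng.normal(190.0, 15.0, size=int(bad.sum()))
        bad = (mono < 150) | (mono > 250)
    out[~is_nfr] = np.round(mono).astype(np.int64)
    return out


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draws with mean ``mean`` and NB dispersion alpha."""
    mean = np.asarray(mean, dtype=np.float64)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _place_regions(
    rng: np.random.Generator,
    config: SimulationConfig,
    annotation: GenomeAnnotation,
) -> list[GenomicInterval]:
    """Place region intervals across promoter/genic/intergenic space."""
    fr_prom, fr_genic, _ = config.category_fracs
    n = config.n_regions
    n_prom = int(round(n * fr_prom))
    n_genic = int(round(n * fr_genic))
    n_inter = n - n_prom - n_genic
    chroms = sorted(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    genes = annotation.genes

    def in_gene(chrom: str, pos: int) -> bool:
        return any(
            g.body_start - 2_000 <= pos < g.body_end + 2_000
            for g in annotation.genes_on(chrom)
        )

    centers: list[tuple[str, int]] = []
    if genes:
        for _ in range(n_prom):
            g = genes[int(rng.integers(0, len(genes)))]
            off = int(rng.integers(-800, 300))
            pos = g.tss + (off if g.strand == "+" else -off)
            centers.append((g.chrom, pos))
        for _ in range(n_genic):
            g = genes[int(rng.integers(0, len(genes)))]
            lo = g.body_start + 1_600
            hi = g.body_end - 100
            if hi <= lo:
                lo, hi = g.body_start, g.body_end
            centers.append((g.chrom, int(rng.integers(lo, hi))))
    else:
        n_inter += n_prom + n_genic
    attempts = 0
    while len(centers) < n and attempts < 100_000:
        attempts += 1
        ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
        pos = int(rng.integers(5_000, sizes[ci] - 5_000))
        if not in_gene(chroms[ci], pos):
            centers.append((chroms[ci], pos))
    regions = []
    # enforce pairwise separation so merged OCRs stay 1:1 with truth
    used: dict[str, list[int]] = {c: [] for c in chroms}
    out_idx = 0
    for chrom, pos in centers:
        if any(abs(pos - p) < 2_500 for p in used[chrom]):
            continue
        used[chrom].append(pos)
        w = int(rng.integers(config.region_width[0], config.region_width[1]))
        start = max(pos - w // 2, 0)
        regions.append(
            GenomicInterval(chrom, start, start + w, name=f"R{out_idx:05d}")
        )
        out_idx += 1
    return regions


def gen_accessibility_experiment(
    config: SimulationConfig, annotation: GenomeAnnotation
) -> tuple[dict, dict, dict, SyntheticTruth]:
    """Per-sample ATAC fragments and peaks with planted differential regions.

    Returns ``(fragments, peaks, conditions, truth)`` where fragments and
    peaks map sample id -> list of intervals and conditions maps sample
    id -> 'control' / 'treated'. A fraction of regions carries a planted
    symmetric log2 fold change (half GAIN, half LOST); per-region
    per-sample fragment counts are negative-binomial around the
    condition-scaled mean, and fragment lengths come from the
    nucleosome-free / mono-nucleosome mixture. Per-sample peak files
    cover every planted region plus noise peaks.
    """
    rng = config.rng(2)
    regions = _place_regions(rng, config, annotation)
    n = len(regions)
    n_diff = int(round(n * config.frac_differential))
    lfc = np.zeros(n)
    if n_diff > 0:
        diff_idx = rng.choice(n, size=n_diff, replace=False)
        half = n_diff // 2
        lfc[diff_idx[:half]] = config.planted_log2fc
        lfc[diff_idx[half:]] = -config.planted_log2fc

    base_mean = config.region_mean_fragments * np.exp(
        rng.normal(0.0, 0.25, size=n)
    )
    sample_means = {
        "control": base_mean * 2.0 ** (-lfc / 2.0),
        "treated": base_mean * 2.0 ** (lfc / 2.0),
    }

    chroms = sorted(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    fragments: dict[str, list[GenomicInterval]] = {}
    peaks: dict[str, list[GenomicInterval]] = {}
    conditions: dict[str, str] = {}
    expected_region_frags = float(base_mean.sum())
    n_background = max(int(config.reads_per_sample - expected_region_frags), 0)
    if n_background == 0:
        warnings.warn(
            f"reads_per_sample={config.reads_per_sample} fully consumed by "
            f"regions (expected {expected_region_frags:.0f}); no background"
        )
    for cond in ("control", "treated"):
        for rep in range(config.n_replicates):
            sid = f"{cond}_{rep + 1}"
            conditions[sid] = cond
            frags: list[GenomicInterval] = []
            counts = _nb_counts(rng, sample_means[cond], config.nb_dispersion)
            for r, k in zip(regions, counts):
                if k == 0:
                    continue
                mids = rng.normal(r.center, len(r) / 4.0, size=k)
                mids = np.clip(mids, r.start + 5, r.end - 5).astype(np.int64)
                lens = _draw_fragment_lengths(rng, k, config.nfr_fraction)
                starts = np.maximum(mids - lens // 2, 0)
                for s, ln in zip(starts, lens):
                    frags.append(GenomicInterval(r.chrom, int(s), int(s + ln)))
            if n_background:
                ci = rng.choice(len(chroms), size=n_background, p=sizes / sizes.sum())
                lens = _draw_fragment_lengths(rng, n_background, config.nfr_fraction)
                for c, ln in zip(ci, lens):
                    s = int(rng.integers(0, sizes[c] - 300))
                    frags.append(GenomicInterval(chroms[c], s, s + int(ln)))
            fragments[sid] = frags
            # per-sample peaks: planted regions jittered + noise peaks
            ps: list[GenomicInterval] = []
            for r in regions:
                j1 = int(rng.integers(-20, 21))
                j2 = int(rng.integers(-20, 21))
                ps.append(
                    GenomicInterval(
                        r.chrom, max(r.start + j1, 0), max(r.end + j2, r.start + j1 + 50)
                    )
                )
            for _ in range(20):
                c = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
                s = int(rng.integers(0, sizes[c] - 400))
                ps.append(GenomicInterval(chroms[c], s, s + int(rng.integers(150, 400))))
            peaks[sid] = ps
    truth = SyntheticTruth(
        differential_regions=pd.DataFrame(
            {
                "region_id": [r.name for r in regions],
                "chrom": [r.chrom for r in regions],
                "start": [r.start for r in regions],
                "end": [r.end for r in regions],
                "log2fc": lfc,
                "is_differential": lfc != 0,
            }
        )
    )
    return fragments, peaks, conditions, truth


# ----------------------------------------------------------------------
def gen_startseq(
    config: SimulationConfig, annotation: GenomeAnnotation
) -> tuple[CoverageTrack, CoverageTrack, SyntheticTruth]:
    """Strand-specific 5'-end counts with planted divergent TSS pairs.

    For each pair class, sense TSSs are planted on the plus strand with
    an opposite-strand partner upstream at a log-normally drawn distance;
    reads stack at the exact base (count >= the class signal). A uniform
    Poisson background covers both strands. Pairs whose coordinates fall
    outside the chromosome are skipped with a warning.
    """
    rng = config.rng(3)
    chroms = sorted(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    plus: dict[str, dict[int, float]] = {c: {} for c in chroms}
    minus: dict[str, dict[int, float]] = {c: {} for c in chroms}
    rows = []
    # anchors on a coarse grid so same-strand cluster suppression cannot
    # merge two different planted pairs
    spacing = 4_000
    anchors = [
        (c, p)
        for c in chroms
        for p in range(3_000, config.chrom_sizes[c] - 3_000, spacing)
    ]
    rng.shuffle(anchors)
    ai = 0
    for cls in sorted(config.tss_pair_spec):
        spec = config.tss_pair_spec[cls]
        if spec.median <= 0:
            raise ValueError(f"class {cls}: distance median must be positive")
        for _ in range(spec.count):
            if ai >= len(anchors):
                warnings.warn("ran out of anchor positions; truncating pairs")
                break
            chrom, p = anchors[ai]
            ai += 1
            d = max(int(round(rng.lognormal(np.log(spec.median), spec.log_sd))), 1)
            q = p - d
            if q < 0:
                warnings.warn(f"pair at {chrom}:{p} distance {d} out of bounds; skipped")
                continue
            c_sense = spec.signal + int(rng.poisson(0.5))
            c_anti = spec.signal + int(rng.poisson(0.5))
            plus[chrom][p] = plus[chrom].get(p, 0) + c_sense
            minus[chrom][q] = minus[chrom].get(q, 0) + c_anti
            rows.append(
                {
                    "pair_class": cls,
                    "chrom": chrom,
                    "sense_pos": p,
                    "sense_strand": "+",
                    "antisense_pos": q,
                    "distance": d,
                }
            )
    lam = config.tss_background_rate
    if lam > 0:
        for counts in (plus, minus):
            for ci, chrom in enumerate(chroms):
                n_bg = rng.poisson(lam * sizes[ci])
                pos = rng.integers(0, sizes[ci], size=n_bg)
                for p in pos:
                    counts[chrom][int(p)] = counts[chrom].get(int(p), 0) + 1
    plus_track = CoverageTrack.from_base_counts(plus, label="startseq_plus")
    minus_track = CoverageTrack.from_base_counts(minus, label="startseq_minus")
    truth = SyntheticTruth(tss_pairs=pd.DataFrame(rows))
    return plus_track, minus_track, truth


# ----------------------------------------------------------------------
TRACK_NAMES = ("ATAC", "H3K27ac", "H3K4me1", "H3K4me3", "H3", "RNAPII", "input")


def gen_signal_tracks(
    config: SimulationConfig,
    regions: Sequence[GenomicInterval],
    shapes: Optional[Sequence[str]] = None,
    amplitude: float = 10.0,
    sigma: float = 150.0,
    bimodal_offset: int = 250,
    h3_baseline: float = 1.0,
    input_level: float = 0.5,
    window: int = 1500,
    total_fragments: int = 10_000_000,
) -> dict[str, CoverageTrack]:
    """Coverage tracks with unimodal or bimodal profiles at each region.

    Marks are the region shape added on top of the H3 baseline; the H3
    track is the flat baseline; input is flat at ``input_level``. Shapes
    default to alternating unimodal/bimodal. Profiles are rendered at
    single-base resolution within ``window`` bases of each center.
    """
    rng = config.rng(4)
    if shapes is None:
        shapes = ["unimodal" if i % 2 == 0 else "bimodal" for i in range(len(regions))]
    if len(shapes) != len(regions):
        raise ValueError("shapes length mismatch")

    def profile(x: np.ndarray, shape: str) -> np.ndarray:
        if shape == "unimodal":
            return amplitude * np.exp(-(x**2) / (2 * sigma**2))
        if shape == "bimodal":
            s2 = sigma / 1.5
            return amplitude * (
                np.exp(-((x - bimodal_offset) ** 2) / (2 * s2**2))
                + np.exp(-((x + bimodal_offset) ** 2) / (2 * s2**2))
            )
        raise ValueError(f"unknown shape {shape!r}")

    chroms = sorted(config.chrom_sizes)
    tracks = {}
    # flat tracks
    for name, level in (("H3", h3_baseline), ("input", input_level)):
        t = CoverageTrack(total_fragments, label=name)
        for c in chroms:
            t.set_chrom(
                c,
                np.array([0]),
                np.array([config.chrom_sizes[c]]),
                np.array([level]),
            )
        tracks[name] = t

    shaped = {"ATAC": 0.0, "H3K27ac": h3_baseline, "H3K4me1": h3_baseline,
              "H3K4me3": h3_baseline, "RNAPII": input_level}
    for name, baseline in shaped.items():
        t = CoverageTrack(total_fragments, label=name)
        for c in chroms:
            size = config.chrom_sizes[c]
            segs_s, segs_e, segs_v = [], [], []
            cursor = 0
            here = [
                (r, sh)
                for r, sh in zip(regions, shapes)
                if r.chrom == c
            ]
            here.sort(key=lambda t2: t2[0].start)
            for r, sh in here:
                a = max(r.center - window, 0, cursor)
                b = min(r.center + window, size)
                if b <= a:
                    continue
                if a > cursor and baseline != 0:
                    segs_s.append(cursor)
                    segs_e.append(a)
                    segs_v.append(baseline)
                x = np.arange(a, b) - r.center
                vals = baseline + profile(x.astype(float), sh)
                segs_s.append(np.arange(a, b))
                segs_e.append(np.arange(a + 1, b + 1))
                segs_v.append(vals)
                cursor = b
            if cursor < size and baseline != 0:
                segs_s.append(cursor)
                segs_e.append(size)
                segs_v.append(baseline)
            if segs_s:
                starts = np.concatenate([np.atleast_1d(s) for s in segs_s])
                ends = np.concatenate([np.atleast_1d(e) for e in segs_e])
                vals = np.concatenate([np.atleast_1d(v) for v in segs_v])
                t.set_chrom(c, starts, ends, vals)
        tracks[name] = t
    return tracks


# ----------------------------------------------------------------------
def gen_se_landscape(
    config: SimulationConfig, annotation: GenomeAnnotation
) -> tuple[list[GenomicInterval], dict[str, CoverageTrack], SyntheticTruth]:
    """Enhancer-peak landscape with a heavy-tailed score distribution.

    Peaks are placed away from annotated TSSs and farther apart than the
    stitching distance, so stitched regions correspond 1:1 to peaks.
    Background scores follow a Pareto-type law (convex scaled rank-signal
    curve); the planted ``n_super_true`` peaks sit above a clear score
    gap and form the truth set. A mark track encodes each peak's score
    as constant coverage (input is zero), so constituent-signal scoring
    recovers the planted scores. With tail exponent 0 all scores are
    equal and the truth set is empty.
    """
    rng = config.rng(5)
    spec = config.se_spec
    if spec.n_super_true >= spec.n_peaks:
        raise ValueError("n_super_true must be smaller than n_peaks")
    chroms = sorted(config.chrom_sizes)
    min_gap = 14_000  # > default stitch distance so peaks stay separate
    tss_positions = {
        c: np.array([t.position for t in annotation.tss_sites(c)]) for c in chroms
    }
    peaks: list[GenomicInterval] = []
    pi = 0
    for c in chroms:
        size = config.chrom_sizes[c]
        pos = 10_000
        while pos < size - 10_000 and len(peaks) < spec.n_peaks:
            tssp = tss_positions[c]
            center = pos + 500
            if tssp.size == 0 or np.min(np.abs(tssp - center)) > 3_000:
                width = int(rng.integers(600, 1_400))
                peaks.append(
                    GenomicInterval(c, center - width // 2, center + width // 2,
                                    name=f"E{pi:05d}")
                )
                pi += 1
            pos += min_gap + int(rng.integers(0, 2_000))
    if len(peaks) < spec.n_peaks:
        warnings.warn(
            f"placed only {len(peaks)} of {spec.n_peaks} requested peaks"
        )
    n = len(peaks)
    if spec.tail_exponent == 0:
        scores = np.full(n, spec.base_scale)
        truth_names: list[str] = []
    else:
        u = rng.random(n)
        scores = spec.base_scale * (1.0 - u) ** (-spec.tail_exponent)
        order = np.argsort(scores)
        top = order[-spec.n_super_true :]
        gap_floor = 4.0 * scores[order[-spec.n_super_true - 1]]
        scores[top] = gap_floor * (1.0 + rng.random(spec.n_super_true))
        truth_names = sorted(peaks[i].name for i in top)
    peaks = [
        GenomicInterval(p.chrom, p.start, p.end, p.strand, p.name, float(s))
        for p, s in zip(peaks, scores)
    ]
    mark = CoverageTrack(total_fragments=10_000_000, label="H3K27ac_SE")
    by_chrom: dict[str, list] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for c, ps in by_chrom.items():
        ps.sort(key=lambda p: p.start)
        mark.set_chrom(
            c,
            np.array([p.start for p in ps]),
            np.array([p.end for p in ps]),
            np.array([p.score / len(p) for p in ps]),
        )
    truth = SyntheticTruth(super_set=truth_names)
    return peaks, {"mark": mark}, truth


# ----------------------------------------------------------------------
def gen_cohort(
    config: SimulationConfig, regions: Sequence[GenomicInterval]
) -> tuple[dict[str, CoverageTrack], dict[str, str], SyntheticTruth]:
    """Block-structured cohort signal at fixed regions.

    Regions fall into ``n_clusters`` contiguous truth blocks; each
    cluster carries an opposite-signed basal vs non-basal block mean
    (spaced by the block effect size) plus Gaussian noise, on top of a
    positive baseline. Row-centering removes the baseline, leaving the
    subtype-interaction signature that separates clusters.
    """
    rng = config.rng(6)
    spec = config.cohort_spec
    n = len(regions)
    k = spec.n_clusters
    if k > n:
        raise ValueError(f"n_clusters={k} exceeds number of regions {n}")
    clusters = np.array([i * k // n for i in range(n)]) + 1  # 1..k blocks
    offsets = (np.arange(k) - (k - 1) / 2.0) * spec.block_effect
    samples: dict[str, CoverageTrack] = {}
    subtypes: dict[str, str] = {}
    for subtype, sign in (("basal", 1.0), ("non_basal", -1.0)):
        for s in range(spec.n_samples_per_subtype):
            sid = f"{subtype}_{s + 1:02d}"
            subtypes[sid] = subtype
            vals = (
                spec.baseline
                + sign * offsets[clusters - 1] / 2.0
                + rng.normal(0.0, spec.noise_sd, size=n)
            )
            track = CoverageTrack(total_fragments=10_000_000, label=sid)
            by_chrom: dict[str, list] = {}
            for r, v in zip(regions, vals):
                by_chrom.setdefault(r.chrom, []).append((r.start, r.end, v))
            for c, rows in by_chrom.items():
                rows.sort()
                arr = np.array(rows, dtype=np.float64)
                track.set_chrom(
                    c,
                    arr[:, 0].astype(np.int64),
                    arr[:, 1].astype(np.int64),
                    arr[:, 2],
                )
            samples[sid] = track
    truth = SyntheticTruth(cohort_clusters=clusters)
    return samples, subtypes, truth


# ----------------------------------------------------------------------
def gen_state_scores(
    config: SimulationConfig,
) -> pd.DataFrame:
    """Random chromatin-state score table in fixed-width bins.

    Scores are exponential draws per state per bin; the consensus state
    is simply the per-bin argmax downstream.
    """
    rng = config.rng(7)
    spec = config.state_spec
    rows = []
    for chrom in sorted(config.chrom_sizes):
        size = config.chrom_sizes[chrom]
        starts = np.arange(0, size, spec.bin)
        scores = rng.exponential(1.0, size=(len(starts), spec.n_states))
        for s, sc in zip(starts, scores):
            rows.append([chrom, int(s), int(min(s + spec.bin, size)), *sc])
    cols = ["chrom", "start", "end"] + [f"state{i + 1}" for i in range(spec.n_states)]
    return pd.DataFrame(rows, columns=cols)
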