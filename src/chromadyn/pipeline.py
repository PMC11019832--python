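"""End-to-end pipeline orchestration over a synthetic experiment.

Stages run in dependency order (simulate -> docr -> tss -> signal -> se
-> cohort -> expr); every stage writes plain-text outputs plus a manifest
entry with parameter echo and file checksums, so a run is reproducible
from its manifest. A single seed fans out to per-stage derived seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .annotation import GenomeAnnotation
from .coverage import CoverageTrack
from .docr import (
    ChromatinStateTable,
    DocrConfig,
    DocrRecord,
    annotate_docrs,
    build_global_ocrs,
    call_docrs,
    count_fragments,
    docrs_to_frame,
    extract_nucleosome_free,
    summarize_docrs,
)
from .integration import cohort_cluster, rna_at_docrs
from .intervals import GenomicInterval
from .matrix import (
    MatrixSpec,
    difference_matrix,
    metaplot,
    normalize_depth,
    region_matrix,
    sort_rows,
)
from .nb import CountMatrix, nb_differential
from .simulate import (
    SimulationConfig,
    gen_accessibility_experiment,
    gen_annotation,
    gen_cohort,
    gen_se_landscape,
    gen_signal_tracks,
    gen_startseq,
    gen_state_scores,
    _nb_counts,
)
from .superenhancer import SeConfig, compare_se_sets, rank_and_cutoff, stitch_peaks
from .tss import (
    TssConfig,
    call_tss,
    classify_tss,
    divergent_distance_stats,
    pair_divergent,
    tss_docr_overlap,
)

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "docr", "tss", "signal", "se", "cohort", "expr")
_DEPENDS = {
    "simulate": (),
    "docr": ("simulate",),
    "tss": ("simulate", "docr"),
    "signal": ("simulate", "docr"),
    "se": ("simulate", "docr"),
    "cohort": ("simulate", "se"),
    "expr": ("simulate", "docr"),
}


class DependencyError(RuntimeError):
    """A requested stage is missing an upstream stage's outputs."""


@dataclass
class RunConfig:
    """All parameters of an end-to-end run."""

    outdir: Path
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    docr: DocrConfig = field(default_factory=DocrConfig)
    tss: TssConfig = field(default_factory=TssConfig)
    se: SeConfig = field(default_factory=SeConfig)
    matrix: MatrixSpec = field(default_factory=MatrixSpec)
    cohort_k: int = 6

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        self.sim.seed = self.seed


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(
    config: RunConfig, stages: Optional[Sequence[str]] = None
) -> dict:
    """Execute the requested stages and return the output manifest.

    Stages always execute in dependency order; requesting a stage whose
    upstream outputs are absent (neither requested nor already on disk)
    raises :class:`DependencyError` naming the stage.
    """
    stages = list(stages) if stages is not None else list(ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest: dict = {"seed": config.seed, "stages": {}}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())

    def done(stage: str) -> bool:
        return stage in stages or stage in manifest["stages"]

    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        for dep in _DEPENDS[stage]:
            if not done(dep):
                raise DependencyError(
                    f"stage {stage!r} requires outputs of {dep!r}"
                )

    ordered = [s for s in ALL_STAGES if s in stages]
    for stage in ordered:
        files = _STAGE_FN[stage](config, outdir)
        manifest["stages"][stage] = {
            "params": _stage_params(config, stage),
            "files": {
                name: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
                for name, p in files.items()
            },
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_params(config: RunConfig, stage: str) -> dict:
    mapping = {
        "simulate": config.sim,
        "docr": config.docr,
        "tss": config.tss,
        "se": config.se,
        "signal": config.matrix,
    }
    obj = mapping.get(stage)
    if obj is None:
        return {"cohort_k": config.cohort_k}
    d = asdict(obj)
    return json.loads(json.dumps(d, default=str))


# ----------------------------------------------------------------------
def _stage_simulate(config: RunConfig, outdir: Path) -> dict[str, Path]:
    sim = config.sim
    files: dict[str, Path] = {}
    annotation = gen_annotation(sim)
    files["gtf"] = outdir / "annotation.gtf"
    cio.write_gtf(annotation, files["gtf"])
    files["chrom_sizes"] = outdir / "genome.chrom.sizes"
    cio.write_chrom_sizes(sim.chrom_sizes, files["chrom_sizes"])

    fragments, peaks, conditions, truth = gen_accessibility_experiment(sim, annotation)
    for sid in sorted(fragments):
        p = outdir / f"fragments_{sid}.bed"
        cio.write_bed(fragments[sid], p)
        files[f"fragments_{sid}"] = p
        p = outdir / f"peaks_{sid}.bed"
        cio.write_bed(peaks[sid], p)
        files[f"peaks_{sid}"] = p
    files["conditions"] = outdir / "conditions.tsv"
    _write_tsv(
        pd.DataFrame(
            {"sample": sorted(conditions), "condition": [conditions[s] for s in sorted(conditions)]}
        ),
        files["conditions"],
    )
    files["truth_regions"] = outdir / "truth_regions.tsv"
    _write_tsv(truth.differential_regions, files["truth_regions"])

    plus, minus, tss_truth = gen_startseq(sim, annotation)
    files["startseq_plus"] = outdir / "startseq_plus.bedGraph"
    cio.write_bedgraph(plus, files["startseq_plus"])
    files["startseq_minus"] = outdir / "startseq_minus.bedGraph"
    cio.write_bedgraph(minus, files["startseq_minus"])
    files["truth_tss_pairs"] = outdir / "truth_tss_pairs.tsv"
    _write_tsv(tss_truth.tss_pairs, files["truth_tss_pairs"])

    regions = [
        GenomicInterval(r.chrom, r.start, r.end, name=r.region_id)
        for r in truth.differential_regions.itertuples(index=False)
    ]
    tracks = gen_signal_tracks(sim, regions)
    for name, track in tracks.items():
        p = outdir / f"track_{name}.bedGraph"
        cio.write_bedgraph(track, p)
        files[f"track_{name}"] = p

    se_peaks, se_tracks, se_truth = gen_se_landscape(sim, annotation)
    files["se_peaks"] = outdir / "se_peaks.narrowPeak"
    cio.write_narrowpeak(se_peaks, files["se_peaks"])
    files["se_mark"] = outdir / "se_mark.bedGraph"
    cio.write_bedgraph(se_tracks["mark"], files["se_mark"])
    files["truth_super"] = outdir / "truth_super.tsv"
    _write_tsv(pd.DataFrame({"peak_id": se_truth.super_set}), files["truth_super"])

    diff_regions = [
        r
        for r, t in zip(regions, truth.differential_regions.itertuples(index=False))
        if t.is_differential
    ] or regions[: max(sim.cohort_spec.n_clusters, 1)]
    samples, subtypes, cohort_truth = gen_cohort(sim, diff_regions)
    for sid in sorted(samples):
        p = outdir / f"cohort_{sid}.bedGraph"
        cio.write_bedgraph(samples[sid], p)
        files[f"cohort_{sid}"] = p
    files["cohort_labels"] = outdir / "cohort_labels.tsv"
    _write_tsv(
        pd.DataFrame(
            {"sample": sorted(subtypes), "subtype": [subtypes[s] for s in sorted(subtypes)]}
        ),
        files["cohort_labels"],
    )
    files["truth_cohort"] = outdir / "truth_cohort_clusters.tsv"
    _write_tsv(
        pd.DataFrame(
            {
                "region_id": [r.name for r in diff_regions],
                "cluster": cohort_truth.cohort_clusters,
            }
        ),
        files["truth_cohort"],
    )

    files["states"] = outdir / "chromatin_states.tsv"
    _write_tsv(gen_state_scores(sim), files["states"])
    return files


def _load_samples(outdir: Path) -> tuple[dict, dict, dict]:
    cond = pd.read_csv(outdir / "conditions.tsv", sep="\t")
    conditions = dict(zip(cond["sample"], cond["condition"]))
    fragments = {
        s: cio.read_bed(outdir / f"fragments_{s}.bed") for s in conditions
    }
    peaks = {s: cio.read_bed(outdir / f"peaks_{s}.bed") for s in conditions}
    return fragments, peaks, conditions


def _stage_docr(config: RunConfig, outdir: Path) -> dict[str, Path]:
    fragments, peaks, conditions = _load_samples(outdir)
    annotation = cio.read_gtf(
        outdir / "annotation.gtf", cio.read_chrom_sizes(outdir / "genome.chrom.sizes")
    )
    states = ChromatinStateTable.read_tsv(
        outdir / "chromatin_states.tsv",
        bin_size=config.docr.state_bin,
        n_states=config.docr.n_states,
    )
    nfr = {
        s: extract_nucleosome_free(f, config.docr.nfr_max_len)
        for s, f in fragments.items()
    }
    ocrs = build_global_ocrs(list(peaks.values()), config.docr.merge_gap)
    matrix = count_fragments(ocrs, nfr, conditions)
    docrs, results = call_docrs(ocrs, matrix, ("treated", "control"), config.docr)
    annotate_docrs(docrs, annotation, states, config.docr)

    files: dict[str, Path] = {}
    files["docrs"] = outdir / "docr_results.tsv"
    _write_tsv(docrs_to_frame(docrs), files["docrs"])
    files["test_results"] = outdir / "ocr_test_results.tsv"
    _write_tsv(results.reset_index(), files["test_results"])
    files["summary"] = outdir / "docr_summary.tsv"
    _write_tsv(summarize_docrs(docrs), files["summary"])
    meta = {
        "n_peaks_in": sum(len(p) for p in peaks.values()),
        "n_ocrs": len(ocrs),
        "n_testable": results.attrs["n_testable"],
        "n_docrs": len(docrs),
        "n_gain": sum(d.direction == "GAIN" for d in docrs),
        "n_lost": sum(d.direction == "LOST" for d in docrs),
    }
    files["docr_meta"] = outdir / "docr_meta.json"
    files["docr_meta"].write_text(json.dumps(meta, indent=2, sort_keys=True))
    return files


def _load_docrs(outdir: Path) -> list[DocrRecord]:
    path = outdir / "docr_results.tsv"
    if not path.exists():
        raise DependencyError("docr stage outputs missing (docr_results.tsv)")
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        out.append(
            DocrRecord(
                interval=GenomicInterval(r.chrom, int(r.start), int(r.end)),
                center=int(r.center),
                log2fc=float(r.log2fc),
                pvalue=float(r.pvalue),
                fdr=float(r.fdr),
                direction=r.direction,
                category=r.category if isinstance(r.category, str) else None,
                chromatin_state=int(r.state) if pd.notna(r.state) else None,
            )
        )
    return out


def _stage_tss(config: RunConfig, outdir: Path) -> dict[str, Path]:
    plus = cio.read_bedgraph(outdir / "startseq_plus.bedGraph")
    minus = cio.read_bedgraph(outdir / "startseq_minus.bedGraph")
    sizes = cio.read_chrom_sizes(outdir / "genome.chrom.sizes")
    annotation = cio.read_gtf(outdir / "annotation.gtf", sizes)
    docrs = _load_docrs(outdir)

    calls = call_tss(plus, minus, config.tss, genome_size=sum(sizes.values()))
    classify_tss(calls, annotation, config.tss)
    pairs = pair_divergent(calls, config.tss)
    overlap = tss_docr_overlap(calls, docrs)

    files: dict[str, Path] = {}
    files["tss_calls"] = outdir / "tss_calls.tsv"
    _write_tsv(
        pd.DataFrame(
            {
                "chrom": [c.chrom for c in calls],
                "position": [c.position for c in calls],
                "strand": [c.strand for c in calls],
                "read_count": [c.read_count for c in calls],
                "tss_class": [c.tss_class for c in calls],
                "associated_gene": [c.associated_gene for c in calls],
                "utss_subclass": [c.utss_subclass for c in calls],
                "divergent_class": [c.divergent_class for c in calls],
            }
        ),
        files["tss_calls"],
    )
    files["pairs"] = outdir / "tss_pairs.tsv"
    _write_tsv(
        pd.DataFrame(
            {
                "chrom": [p.sense.chrom for p in pairs],
                "sense_pos": [p.sense.position for p in pairs],
                "sense_strand": [p.sense.strand for p in pairs],
                "sense_gene": [p.sense.associated_gene for p in pairs],
                "antisense_pos": [p.antisense.position for p in pairs],
                "distance": [p.distance for p in pairs],
                "pair_class": [p.pair_class for p in pairs],
            }
        ),
        files["pairs"],
    )
    counts = {k: len(v) for k, v in overlap.items()}
    files["tss_meta"] = outdir / "tss_meta.json"
    files["tss_meta"].write_text(json.dumps(counts, indent=2, sort_keys=True))
    return files


def _stage_signal(config: RunConfig, outdir: Path) -> dict[str, Path]:
    docrs = _load_docrs(outdir)
    regions = [d.interval for d in docrs]
    keys = [abs(d.log2fc) for d in docrs]
    files: dict[str, Path] = {}
    if not regions:
        files["signal_meta"] = outdir / "signal_meta.json"
        files["signal_meta"].write_text(json.dumps({"n_regions": 0}))
        return files
    atac = normalize_depth(cio.read_bedgraph(outdir / "track_ATAC.bedGraph"))
    h3 = normalize_depth(cio.read_bedgraph(outdir / "track_H3.bedGraph"))
    mark = normalize_depth(cio.read_bedgraph(outdir / "track_H3K27ac.bedGraph"))
    spec = config.matrix
    m_atac = sort_rows(region_matrix(atac, regions, spec), keys, descending=True)
    m_mark = region_matrix(mark, regions, spec)
    m_h3 = region_matrix(h3, regions, spec)
    from .matrix import subtract_control

    m_marksub = subtract_control(m_mark, m_h3, "H3")
    for name, m in (("atac", m_atac), ("h3k27ac_minus_h3", m_marksub)):
        p = outdir / f"matrix_{name}.tsv"
        m.to_frame().to_csv(p, sep="\t", float_format="%.6g")
        files[f"matrix_{name}"] = p
        mp = metaplot(m)
        p2 = outdir / f"metaplot_{name}.tsv"
        pd.DataFrame({"bin": np.arange(1, len(mp) + 1), "mean": mp}).to_csv(
            p2, sep="\t", index=False, float_format="%.6g"
        )
        files[f"metaplot_{name}"] = p2
    return files


def _stage_se(config: RunConfig, outdir: Path) -> dict[str, Path]:
    peaks = cio.read_narrowpeak(outdir / "se_peaks.narrowPeak")
    sizes = cio.read_chrom_sizes(outdir / "genome.chrom.sizes")
    annotation = cio.read_gtf(outdir / "annotation.gtf", sizes)
    mark = cio.read_bedgraph(outdir / "se_mark.bedGraph")
    docrs = _load_docrs(outdir)
    regions = stitch_peaks(peaks, annotation, config.se)
    regions, y_cut = rank_and_cutoff(regions, mark_track=mark, config=config.se)
    supers = [r for r in regions if r.is_super]
    files: dict[str, Path] = {}
    files["stitched"] = outdir / "se_stitched.tsv"
    _write_tsv(
        pd.DataFrame(
            {
                "chrom": [r.interval.chrom for r in regions],
                "start": [r.interval.start for r in regions],
                "end": [r.interval.end for r in regions],
                "constituents": [
                    ",".join(p.name or "" for p in r.constituents) for r in regions
                ],
                "score": [r.score for r in regions],
                "rank": [r.rank for r in regions],
                "is_super": [r.is_super for r in regions],
            }
        ),
        files["stitched"],
    )
    cmp = compare_se_sets(supers, supers, docrs)
    meta = {
        "n_stitched": len(regions),
        "n_super": len(supers),
        "y_cutoff": y_cut,
        "n_super_overlapping_docr": sum(
            1 for ov in cmp["docr_overlaps"]["a"] if ov
        ),
    }
    files["se_meta"] = outdir / "se_meta.json"
    files["se_meta"].write_text(json.dumps(meta, indent=2, sort_keys=True))
    return files


def _stage_cohort(config: RunConfig, outdir: Path) -> dict[str, Path]:
    labels = pd.read_csv(outdir / "cohort_labels.tsv", sep="\t")
    subtypes = dict(zip(labels["sample"], labels["subtype"]))
    tracks = {
        s: cio.read_bedgraph(outdir / f"cohort_{s}.bedGraph") for s in subtypes
    }
    truth = pd.read_csv(outdir / "truth_cohort_clusters.tsv", sep="\t")
    region_df = pd.read_csv(outdir / "truth_regions.tsv", sep="\t").set_index(
        "region_id"
    )
    regions = [
        GenomicInterval(
            region_df.loc[rid, "chrom"],
            int(region_df.loc[rid, "start"]),
            int(region_df.loc[rid, "end"]),
            name=rid,
        )
        for rid in truth["region_id"]
    ]
    cm = cohort_cluster(tracks, subtypes, regions, k=config.cohort_k)
    files: dict[str, Path] = {}
    files["cohort_matrix"] = outdir / "cohort_matrix.tsv"
    pd.DataFrame(cm.values, index=cm.region_ids, columns=cm.sample_ids).to_csv(
        files["cohort_matrix"], sep="\t", float_format="%.6g"
    )
    files["cohort_clusters"] = outdir / "cohort_clusters.tsv"
    _write_tsv(
        pd.DataFrame({"region_id": cm.region_ids, "cluster": cm.clusters}),
        files["cohort_clusters"],
    )
    files["cohort_chrom_table"] = outdir / "cohort_chrom_table.tsv"
    cm.chrom_table.to_csv(files["cohort_chrom_table"], sep="\t")
    return files


def _stage_expr(config: RunConfig, outdir: Path) -> dict[str, Path]:
    sizes = cio.read_chrom_sizes(outdir / "genome.chrom.sizes")
    annotation = cio.read_gtf(outdir / "annotation.gtf", sizes)
    docrs = _load_docrs(outdir)
    # synthetic gene-level counts through the shared NB engine
    rng = config.sim.rng(8)
    genes = [g.gene_id for g in annotation.genes]
    n = len(genes)
    base = rng.uniform(100, 2000, size=n)
    lfc = np.zeros(n)
    n_de = max(n // 10, 1)
    de_idx = rng.choice(n, size=n_de, replace=False)
    lfc[de_idx] = rng.choice([-2.0, 2.0], size=n_de)
    cols, conds = [], []
    counts = []
    for cond, scalefc in (("control", -0.5), ("treated", 0.5)):
        for rep in range(3):
            cols.append(f"{cond}_{rep + 1}")
            conds.append(cond)
            counts.append(_nb_counts(rng, base * 2.0 ** (lfc * scalefc), 0.05))
    matrix = CountMatrix(
        counts=np.column_stack(counts),
        feature_ids=genes,
        sample_ids=cols,
        conditions=conds,
    )
    gene_results = nb_differential(matrix, ("treated", "control"))
    rna_fragments = cio.read_bed(outdir / "fragments_treated_1.bed")
    join = rna_at_docrs(docrs, rna_fragments, gene_results, annotation)
    files: dict[str, Path] = {}
    files["gene_results"] = outdir / "gene_results.tsv"
    _write_tsv(gene_results.reset_index(), files["gene_results"])
    files["expression_join"] = outdir / "expression_join.tsv"
    _write_tsv(join, files["expression_join"])
    return files


_STAGE_FN = {
    "simulate": _stage_simulate,
    "docr": _stage_docr,
    "tss": _stage_tss,
    "signal": _stage_signal,
    "se": _stage_se,
    "cohort": _stage_cohort,
    "expr": _stage_expr,
}
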