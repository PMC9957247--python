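"""End-to-end orchestration: read -> filter -> merge -> views -> summaries
-> copy-number matrix -> VST -> selection -> PCA/tree -> annotation.

Every stage writes a plain TSV/BED/Newick file under the output
directory, so any stage can be rerun independently from its
predecessor's outputs with identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from . import annotate as ann
from . import io as cio
from . import popgen, regions
from .filters import FilterConfig, filter_calls

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    manifest: str
    genome: str
    outdir: str
    genes: str | None = None
    qtls: str | None = None
    gene2term: str | None = None
    filter: FilterConfig = dc_field(default_factory=FilterConfig)
    fractions: tuple[float, ...] = (0.10, 0.01)
    round_cn: bool = False
    e_value_index: int = 0
    min_overlap_bp: int = 1
    min_jaccard: float = 0.0


@dataclass
class PipelineResult:
    outdir: Path
    genome: cio.GenomeDef
    manifest: cio.SampleManifest
    n_raw_calls: int
    filter_report: dict
    views: dict[str, list[regions.Cnvr]]
    summary: pd.DataFrame
    matrix: popgen.CopyNumberMatrix
    vst: pd.DataFrame
    thresholds: dict[float, float]
    pca_coords: pd.DataFrame | None = None
    pca_var: list[float] | None = None
    newick: str | None = None
    gene_hits: list[ann.OverlapHit] | None = None
    qtl_hits: list[ann.OverlapHit] | None = None
    enrichment: pd.DataFrame | None = None

    def selected(self, fraction: float) -> pd.DataFrame:
        flag = popgen._flag_name(fraction)
        return self.vst[self.vst[flag]]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = cio.read_genome(config.genome)
    manifest = cio.read_manifest(config.manifest)
    if len(manifest.populations) != 2:
        raise ValueError(
            "VST stage requires exactly 2 populations; manifest declares "
            f"{len(manifest.populations)}: {manifest.populations}"
        )

    raw = cio.read_calls_for_manifest(manifest, genome, config.e_value_index)
    logger.info("read %d raw calls from %d samples", len(raw), len(manifest.sample_ids))

    kept, report = filter_calls(raw, config.filter)
    logger.info("filter kept %d / %d calls", report.kept, report.total)
    pd.DataFrame([report.as_dict()]).pipe(cio.write_table, outdir / "filter_report.tsv")

    views = regions.population_views(regions.build_cnvrs(kept, genome), manifest, genome)
    for name, view in views.items():
        logger.info("view %s: %d CNVRs", name, len(view))
        cio.write_table(regions.cnvr_frame(view, manifest), outdir / f"cnvrs_{name}.tsv")

    summary = regions.summarize(views["all"], genome)
    cio.write_table(summary, outdir / "summary_all.tsv")

    matrix = popgen.build_cn_matrix(views["all"], manifest, round_cn=config.round_cn)
    vst_df = popgen.vst_table(matrix)
    vst_df, thresholds = popgen.select_top(vst_df, config.fractions)
    cio.write_vst_table(vst_df, outdir / "vst.tsv")

    result = PipelineResult(
        outdir=outdir,
        genome=genome,
        manifest=manifest,
        n_raw_calls=len(raw),
        filter_report=report.as_dict(),
        views=views,
        summary=summary,
        matrix=matrix,
        vst=vst_df,
        thresholds=thresholds,
    )

    by_id = {r.cnvr_id: r for r in views["all"]}
    top_frac = min(config.fractions)
    selected = [by_id[i] for i in result.selected(top_frac)["cnvr_id"]]
    cio.write_selected_bed(selected, outdir / "selected_cnvrs.bed")

    if len(manifest.sample_ids) >= 2:
        coords, var = popgen.pca(matrix)
        cio.write_table(coords.reset_index(), outdir / "pca_coordinates.tsv")
        result.pca_coords = coords
        result.pca_var = list(var)
        result.newick = popgen.upgma_tree(matrix)
        (outdir / "samples.nwk").write_text(result.newick + "\n")

    if config.genes:
        genes = cio.read_bed(config.genes, "gene")
        result.gene_hits = ann.overlap(selected, genes, config.min_overlap_bp, config.min_jaccard)
        cio.write_table(ann.overlap_frame(result.gene_hits), outdir / "gene_overlap.tsv")
        if config.gene2term:
            g2t = pd.read_csv(config.gene2term, sep="\t", dtype=str)
            universe = {g.feature_id for g in genes}
            hit_genes = {h.feature_id for h in result.gene_hits}
            result.enrichment = ann.enrich(hit_genes, g2t, universe)
            cio.write_table(result.enrichment, outdir / "enrichment.tsv")
    if config.qtls:
        qtls = cio.read_bed(config.qtls, "qtl")
        result.qtl_hits = ann.overlap(selected, qtls, config.min_overlap_bp, config.min_jaccard)
        cio.write_table(ann.overlap_frame(result.qtl_hits), outdir / "qtl_overlap.tsv")

    _write_run_manifest(config, outdir)
    return result


def run_synthetic_trial(sim_config, fraction: float = 0.01) -> dict:
    """Simulate one two-population study in memory, run the call-to-selection
    pipeline, and score recovery of the planted differentiated regions.

    Returns the pieces downstream checks need: the selection's
    sensitivity/FDR against truth, the copy-number matrix, the VST table
    and the selected CNVR intervals.
    """
    from .simulate import score_recovery, simulate

    sim = simulate(sim_config)
    kept, _ = filter_calls(sim.calls, FilterConfig())
    cnvrs = regions.build_cnvrs(kept, sim.genome)
    matrix = popgen.build_cn_matrix(cnvrs, sim.manifest)
    vst_df, thresholds = popgen.select_top(popgen.vst_table(matrix), (0.10, fraction))
    flag = popgen._flag_name(fraction)
    by_id = {r.cnvr_id: r for r in cnvrs}
    selected = [
        (by_id[i].chrom, by_id[i].start, by_id[i].end)
        for i in vst_df.loc[vst_df[flag], "cnvr_id"]
    ]
    sensitivity, fdr = score_recovery(sim.truth, selected)
    return {
        "sim": sim,
        "cnvrs": cnvrs,
        "matrix": matrix,
        "vst": vst_df,
        "thresholds": thresholds,
        "selected": selected,
        "sensitivity": sensitivity,
        "fdr": fdr,
    }


def _write_run_manifest(config: PipelineConfig, outdir: Path) -> None:
    from . import __version__

    checksums = {}
    for key in ("manifest", "genome", "genes", "qtls", "gene2term"):
        p = getattr(config, key)
        if p and Path(p).exists():
            checksums[key] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    payload = {
        "cnvpop_version": __version__,
        "config": {
            "manifest": config.manifest,
            "genome": config.genome,
            "genes": config.genes,
            "qtls": config.qtls,
            "gene2term": config.gene2term,
            "filter": config.filter.__dict__,
            "fractions": list(config.fractions),
            "round_cn": config.round_cn,
            "e_value_index": config.e_value_index,
        },
        "input_sha256": checksums,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(payload, indent=2) + "\n")
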