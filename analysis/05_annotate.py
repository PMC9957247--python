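"""Annotate the selected CNVRs against gene and QTL intervals and test
the overlapping genes for term over-representation.
"""

import argparse
from pathlib import Path

import pandas as pd

from cnvpop import enrich, overlap, read_bed
from cnvpop.annotate import overlap_frame
from cnvpop.io import write_table
from cnvpop.regions import Cnvr


def selected_as_regions(bed_path: Path) -> list[Cnvr]:
    return [
        Cnvr(f.feature_id, f.chrom, f.start, f.end, "BOTH", ())
        for f in read_bed(bed_path)
    ]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", default="results/sim_inputs")
    ap.add_argument("--outdir", default="results/pipeline")
    args = ap.parse_args()
    indir, outdir = Path(args.indir), Path(args.outdir)

    selected = selected_as_regions(outdir / "selected_cnvrs.bed")
    genes = read_bed(indir / "genes.bed", "gene")
    qtls = read_bed(indir / "qtls.bed", "qtl")

    gene_hits = overlap(selected, genes)
    qtl_hits = overlap(selected, qtls)
    write_table(overlap_frame(gene_hits), outdir / "gene_overlap.tsv")
    write_table(overlap_frame(qtl_hits), outdir / "qtl_overlap.tsv")
    print(f"selected CNVRs: {len(selected)}; gene overlaps: {len(gene_hits)}; "
          f"QTL overlaps: {len(qtl_hits)}")

    g2t = pd.read_csv(indir / "gene2term.tsv", sep="\t", dtype=str)
    universe = {g.feature_id for g in genes}
    hit_genes = {h.feature_id for h in gene_hits}
    result = enrich(hit_genes, g2t, universe)
    write_table(result, outdir / "enrichment.tsv")
    if len(result):
        top = result.iloc[0]
        print(f"most enriched term: {top.term_id} "
              f"(k={top.k_selected}/{top.K_term}, p={top.p_value:.3g}, "
              f"q={top.q_value:.3g})")
    else:
        print("no terms with selected genes")


if __name__ == "__main__":
    main()
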