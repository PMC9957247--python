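"""Score population differentiation per CNVR with VST and select the top
percentiles; check sample structure with PCA and a UPGMA tree; score
recovery of the planted differentiated regions.
"""

import argparse
from pathlib import Path

import pandas as pd

from cnvpop import (
    build_cn_matrix,
    build_cnvrs,
    pca,
    read_genome,
    read_manifest,
    score_recovery,
    select_top,
    upgma_tree,
    vst_table,
)
from cnvpop.io import read_calls_table, write_selected_bed, write_table, write_vst_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", default="results/sim_inputs")
    ap.add_argument("--outdir", default="results/pipeline")
    args = ap.parse_args()
    indir, outdir = Path(args.indir), Path(args.outdir)

    genome = read_genome(indir / "genome.tsv")
    manifest = read_manifest(indir / "manifest.tsv")
    calls = read_calls_table(outdir / "filtered_calls.tsv")
    cnvrs = build_cnvrs(calls, genome)

    matrix = build_cn_matrix(cnvrs, manifest)
    vst, thresholds = select_top(vst_table(matrix), (0.10, 0.01))
    write_vst_table(vst, outdir / "vst.tsv")
    print(f"VST over {len(vst)} CNVRs; thresholds: "
          f"top-10% >= {thresholds[0.10]:.3f}, top-1% >= {thresholds[0.01]:.3f}")
    print(f"selected: {int(vst.top10pct.sum())} (top 10%), "
          f"{int(vst.top1pct.sum())} (top 1%)")

    by_id = {r.cnvr_id: r for r in cnvrs}
    selected = [by_id[i] for i in vst.loc[vst.top1pct, "cnvr_id"]]
    write_selected_bed(selected, outdir / "selected_cnvrs.bed")

    truth = pd.read_csv(indir / "truth.tsv", sep="\t", dtype={"chrom": str})
    sens, fdr = score_recovery(truth, [(r.chrom, r.start, r.end) for r in selected])
    print(f"top-1% recovery of planted differentiated regions: "
          f"sensitivity {sens:.2f}, FDR {fdr:.2f}")

    coords, var = pca(matrix)
    write_table(coords.reset_index(), outdir / "pca_coordinates.tsv")
    print(f"PCA variance explained: PC1 {100 * var[0]:.2f}%, PC2 {100 * var[1]:.2f}%")
    newick = upgma_tree(matrix)
    (outdir / "samples.nwk").write_text(newick + "\n")
    print(f"UPGMA tree written ({len(matrix.sample_ids)} leaves)")


if __name__ == "__main__":
    main()
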