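"""Apply the four high-confidence CNV filters to the raw calls.

Keeps calls with e-value < 0.01, deletion RD < 0.7 / duplication
RD > 1.3, and length > 1 kb; writes the surviving calls as one flat
table plus a per-rule rejection report.
"""

import argparse
from pathlib import Path

from cnvpop import filter_calls, read_calls_for_manifest, read_genome, read_manifest
from cnvpop.io import write_calls_table, write_table
import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", default="results/sim_inputs")
    ap.add_argument("--outdir", default="results/pipeline")
    args = ap.parse_args()
    indir, outdir = Path(args.indir), Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = read_genome(indir / "genome.tsv")
    manifest = read_manifest(indir / "manifest.tsv")
    raw = read_calls_for_manifest(manifest, genome)
    kept, report = filter_calls(raw)

    write_calls_table(kept, outdir / "filtered_calls.tsv")
    write_table(pd.DataFrame([report.as_dict()]), outdir / "filter_report.tsv")
    print(f"raw calls: {report.total}")
    print(f"kept: {report.kept} "
          f"(rejected by e-value {report.rejected_e_value}, "
          f"RD {report.rejected_rd}, length {report.rejected_length})")


if __name__ == "__main__":
    main()
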