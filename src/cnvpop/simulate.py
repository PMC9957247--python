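"""Two-population CNV call simulator with known ground truth.

The generator emulates the inputs of a two-population pig resequencing
CNV study at desk scale: CNVnator-dialect per-sample call files for an
unbalanced design (24 domestic-breed samples vs 6 wild-boar samples by
default), on a genome that preserves the relative lengths of the 18 pig
autosomes scaled down by a constant factor.

Planted regions come in two classes:

* ``shared`` background regions — carriers drawn at the same frequency
  in both populations, single-copy changes (CN 1 or 3); these create a
  genuine low-VST background.
* ``differentiated`` regions — carrier frequency high in population 1
  and low in population 2 (0.9 / 0.1 by default), strong copy states
  (CN 0 or 4); these are the recoverable selection signal.

Non-carriers are diploid.  Carrier calls get multiplicative lognormal
read-depth noise, uniform boundary jitter, and small e-values.  On top,
false-positive calls are scattered at a per-sample rate per Mb with read
depths straddling the filter thresholds and a fraction of
above-threshold ("junk") e-values, so the high-confidence filters have
real work to do.

Fixing the seed makes every artifact byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    DEL,
    DUP,
    AnnotationInterval,
    CnvCall,
    GenomeDef,
    SampleManifest,
    load_pig_cnvr_counts,
)

DIFFERENTIATED = "differentiated"
SHARED = "shared"


def scaled_pig_autosomes(scale: float = 0.02) -> GenomeDef:
    """The 18 pig autosome lengths scaled by ``scale`` (bp)."""
    counts = load_pig_cnvr_counts()
    chroms = tuple(
        (str(row.chrom), int(round(row.length_mb * 1e6 * scale)))
        for row in counts.itertuples(index=False)
    )
    return GenomeDef(chromosomes=chroms)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    genome_scale: float = 0.02
    genome: GenomeDef | None = None  # default: scaled pig autosomes
    n_pop1: int = 24
    n_pop2: int = 6
    pop1_name: str = "AQ"
    pop2_name: str = "SS"
    n_shared_cnvrs: int = 500
    n_diff_cnvrs: int = 20
    carrier_freq_shared: float = 0.5
    diff_freqs: tuple[float, float] = (0.9, 0.1)
    shared_cn_states: tuple[int, ...] = (1, 3)
    diff_cn_states: tuple[int, ...] = (0, 4)
    region_length_range: tuple[int, int] = (3000, 12000)
    rd_noise_sd: float = 0.05
    boundary_jitter_bp: int = 200
    fp_rate_per_mb: float = 4.0
    fp_length_range: tuple[int, int] = (600, 4000)
    junk_e_value_frac: float = 0.3
    n_background_genes: int = 200
    n_qtls: int = 12

    def __post_init__(self) -> None:
        for f in (self.carrier_freq_shared, *self.diff_freqs):
            if not 0.0 <= f <= 1.0:
                raise ValueError("carrier frequencies must be in [0,1]")
        if self.boundary_jitter_bp * 2 >= self.region_length_range[0]:
            raise ValueError("jitter must be < half the minimum region length")

    def resolved_genome(self) -> GenomeDef:
        return self.genome if self.genome is not None else scaled_pig_autosomes(self.genome_scale)


@dataclass
class SimResult:
    config: SimConfig
    genome: GenomeDef
    sample_populations: list[tuple[str, str]]  # (sample_id, population)
    calls: list[CnvCall]
    truth: pd.DataFrame  # region_id, chrom, start, end, klass, cn_state, carriers
    carriers: pd.DataFrame  # region_id, sample_id, cn
    genes: list[AnnotationInterval]
    qtls: list[AnnotationInterval]
    gene2term: pd.DataFrame  # gene_id, term_id, term_name
    diff_gene_ids: set[str]

    @property
    def manifest(self) -> SampleManifest:
        return SampleManifest(
            entries=tuple(
                (sid, pop, f"calls/{sid}.tsv") for sid, pop in self.sample_populations
            )
        )


def simulate(config: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Generate a full synthetic input set; optionally write it to disk."""
    rng = np.random.default_rng(config.seed)
    genome = config.resolved_genome()

    samples = [(f"{config.pop1_name}_{i + 1:02d}", config.pop1_name) for i in range(config.n_pop1)]
    samples += [(f"{config.pop2_name}_{i + 1:02d}", config.pop2_name) for i in range(config.n_pop2)]

    regions = _place_regions(config, genome, rng)
    truth = pd.DataFrame(regions)

    calls, carrier_rows = _emit_carrier_calls(config, rng, regions, samples)
    calls += _emit_false_positives(config, genome, rng, samples)
    order = {name: i for i, name in enumerate(genome.names)}
    calls.sort(key=lambda c: (c.sample_id, order[c.chrom], c.start, c.end))

    genes, diff_gene_ids = _place_genes(config, genome, rng, regions)
    qtls = _place_qtls(config, genome, rng, regions)
    gene2term = _assign_terms(rng, genes, diff_gene_ids)

    result = SimResult(
        config=config,
        genome=genome,
        sample_populations=samples,
        calls=calls,
        truth=truth,
        carriers=pd.DataFrame(carrier_rows, columns=["region_id", "sample_id", "cn"]),
        genes=genes,
        qtls=qtls,
        gene2term=gene2term,
        diff_gene_ids=diff_gene_ids,
    )
    if outdir is not None:
        write_inputs(result, outdir)
    return result


# ---------------------------------------------------------------------------
# placement and emission


def _place_regions(config: SimConfig, genome: GenomeDef, rng: np.random.Generator) -> list[dict]:
    """Place shared+differentiated regions non-overlapping, proportional to
    chromosome length, with a guard gap so jittered calls cannot bridge
    neighbouring regions."""
    n_total = config.n_shared_cnvrs + config.n_diff_cnvrs
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    raw = n_total * lengths / lengths.sum()
    counts = np.floor(raw).astype(int)
    # hand out the remainder by largest fractional part (stable order)
    rem = n_total - counts.sum()
    frac_order = np.argsort(-(raw - counts), kind="stable")
    for i in frac_order[:rem]:
        counts[i] += 1

    guard = 2 * config.boundary_jitter_bp + 2
    lo, hi = config.region_length_range
    regions: list[dict] = []
    serial = 0
    for (chrom, chrom_len), k in zip(genome.chromosomes, counts):
        if k == 0:
            continue
        reg_lens = rng.integers(lo, hi + 1, size=k)
        free = chrom_len - int(reg_lens.sum()) - (k + 1) * guard
        if free < 0:
            raise ValueError(
                f"planted regions cannot fit on chromosome {chrom} "
                f"({k} regions, {chrom_len} bp)"
            )
        gaps = rng.multinomial(free, [1.0 / (k + 1)] * (k + 1))
        pos = 1
        for j in range(k):
            pos += guard + int(gaps[j])
            start = pos
            end = start + int(reg_lens[j]) - 1
            pos = end + 1
            serial += 1
            regions.append(
                {"region_id": f"sim_{serial:04d}", "chrom": chrom, "start": start, "end": end}
            )
    # assign classes by permutation so differentiated regions spread over chroms
    idx = rng.permutation(n_total)
    diff_set = set(idx[: config.n_diff_cnvrs])
    for i, reg in enumerate(regions):
        is_diff = i in diff_set
        reg["klass"] = DIFFERENTIATED if is_diff else SHARED
        states = config.diff_cn_states if is_diff else config.shared_cn_states
        reg["cn_state"] = int(rng.choice(states))
    return regions


def _emit_carrier_calls(
    config: SimConfig,
    rng: np.random.Generator,
    regions: list[dict],
    samples: list[tuple[str, str]],
) -> tuple[list[CnvCall], list[tuple[str, str, int]]]:
    f1, f2 = config.diff_freqs
    calls: list[CnvCall] = []
    carrier_rows: list[tuple[str, str, int]] = []
    for reg in regions:
        cn = reg["cn_state"]
        cnv_type = DEL if cn < 2 else DUP
        for sample_id, pop in samples:
            if reg["klass"] == DIFFERENTIATED:
                freq = f1 if pop == config.pop1_name else f2
            else:
                freq = config.carrier_freq_shared
            if rng.random() >= freq:
                continue
            jitter = config.boundary_jitter_bp
            if jitter > 0:
                ds = int(rng.integers(-jitter, jitter + 1))
                de = int(rng.integers(-jitter, jitter + 1))
            else:
                ds = de = 0
            start = max(1, reg["start"] + ds)
            end = reg["end"] + de
            rd = (cn / 2.0) * float(rng.lognormal(0.0, config.rd_noise_sd))
            e_value = float(rng.uniform(0.0, 0.005))
            calls.append(
                CnvCall(sample_id, reg["chrom"], start, end, cnv_type, rd, e_value)
            )
            carrier_rows.append((reg["region_id"], sample_id, cn))
    return calls, carrier_rows


def _emit_false_positives(
    config: SimConfig,
    genome: GenomeDef,
    rng: np.random.Generator,
    samples: list[tuple[str, str]],
) -> list[CnvCall]:
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    genome_mb = genome.total_bp / 1e6
    lo, hi = config.fp_length_range
    calls: list[CnvCall] = []
    for sample_id, _pop in samples:
        n_fp = int(rng.poisson(config.fp_rate_per_mb * genome_mb))
        for _ in range(n_fp):
            ci = int(rng.choice(len(probs), p=probs))
            chrom, chrom_len = genome.chromosomes[ci]
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(1, max(2, chrom_len - length + 1)))
            end = start + length - 1
            if rng.random() < 0.5:
                rd = float(rng.uniform(0.6, 0.8))
            else:
                rd = float(rng.uniform(1.25, 1.4))
            if rng.random() < config.junk_e_value_frac:
                e_value = float(rng.uniform(0.02, 0.5))
            else:
                e_value = float(rng.uniform(0.0, 0.005))
            cnv_type = DEL if rd < 1.0 else DUP
            calls.append(CnvCall(sample_id, chrom, start, end, cnv_type, rd, e_value))
    return calls


def _place_genes(
    config: SimConfig,
    genome: GenomeDef,
    rng: np.random.Generator,
    regions: list[dict],
) -> tuple[list[AnnotationInterval], set[str]]:
    genes: list[AnnotationInterval] = []
    diff_ids: set[str] = set()
    serial = 0
    # one gene inside every differentiated region, so annotation has a
    # guaranteed signal to find
    for reg in regions:
        if reg["klass"] != DIFFERENTIATED:
            continue
        serial += 1
        gid = f"gene_{serial:04d}"
        mid = (reg["start"] + reg["end"]) // 2
        half = min(800, (reg["end"] - reg["start"]) // 4)
        genes.append(AnnotationInterval(reg["chrom"], mid - half, mid + half, gid, "gene"))
        diff_ids.add(gid)
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    for _ in range(config.n_background_genes):
        serial += 1
        gid = f"gene_{serial:04d}"
        ci = int(rng.choice(len(probs), p=probs))
        chrom, chrom_len = genome.chromosomes[ci]
        glen = int(rng.integers(500, 3001))
        start = int(rng.integers(1, max(2, chrom_len - glen + 1)))
        genes.append(AnnotationInterval(chrom, start, start + glen - 1, gid, "gene"))
    return genes, diff_ids


def _place_qtls(
    config: SimConfig,
    genome: GenomeDef,
    rng: np.random.Generator,
    regions: list[dict],
) -> list[AnnotationInterval]:
    qtls: list[AnnotationInterval] = []
    diff_regions = [r for r in regions if r["klass"] == DIFFERENTIATED]
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    for i in range(config.n_qtls):
        qid = f"QTL_{i + 1:03d}"
        qlen = int(rng.integers(50_000, 200_001))
        if i < min(3, len(diff_regions)):  # a few QTLs straddle signal regions
            reg = diff_regions[i]
            chrom = reg["chrom"]
            chrom_len = genome.lengths[chrom]
            start = max(1, reg["start"] - qlen // 2)
        else:
            ci = int(rng.choice(len(probs), p=probs))
            chrom, chrom_len = genome.chromosomes[ci]
            start = int(rng.integers(1, max(2, chrom_len - qlen + 1)))
        end = min(chrom_len, start + qlen - 1)
        qtls.append(AnnotationInterval(chrom, start, end, qid, "qtl"))
    return qtls


def _assign_terms(
    rng: np.random.Generator,
    genes: list[AnnotationInterval],
    diff_gene_ids: set[str],
) -> pd.DataFrame:
    rows = []
    gene_ids = [g.feature_id for g in genes]
    # a term concentrated on signal genes plus a sprinkling of background
    for gid in gene_ids:
        if gid in diff_gene_ids or rng.random() < 0.05:
            rows.append((gid, "T_signal", "synthetic differentiated-region term"))
    for t in range(20):
        term = f"T_{t + 1:03d}"
        for gid in gene_ids:
            if rng.random() < 0.08:
                rows.append((gid, term, f"synthetic background term {t + 1}"))
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"])


# ---------------------------------------------------------------------------
# serialization


def format_cnvnator_row(call: CnvCall) -> str:
    kind = "deletion" if call.cnv_type == DEL else "duplication"
    e = f"{call.e_value:.6g}"
    return (
        f"{kind}\t{call.chrom}:{call.start}-{call.end}\t{call.length_bp}\t"
        f"{call.rd:.6g}\t{e}\t{e}\t{e}\t{e}\t0"
    )


def write_inputs(result: SimResult, outdir: str | Path) -> Path:
    """Write a ready-to-run input directory:
    calls/, manifest.tsv, genome.tsv, genes.bed, qtls.bed, gene2term.tsv,
    truth.tsv.  Byte-identical for a fixed config."""
    outdir = Path(outdir)
    (outdir / "calls").mkdir(parents=True, exist_ok=True)

    by_sample: dict[str, list[CnvCall]] = {sid: [] for sid, _ in result.sample_populations}
    for call in result.calls:
        by_sample[call.sample_id].append(call)
    for sid, _pop in result.sample_populations:
        with open(outdir / "calls" / f"{sid}.tsv", "w") as fh:
            for call in by_sample[sid]:
                fh.write(format_cnvnator_row(call) + "\n")

    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("sample_id\tpopulation\tcall_file\n")
        for sid, pop in result.sample_populations:
            fh.write(f"{sid}\t{pop}\tcalls/{sid}.tsv\n")

    with open(outdir / "genome.tsv", "w") as fh:
        for chrom, length in result.genome.chromosomes:
            fh.write(f"{chrom}\t{length}\n")

    for fname, feats in (("genes.bed", result.genes), ("qtls.bed", result.qtls)):
        with open(outdir / fname, "w") as fh:
            for f in feats:
                fh.write(f"{f.chrom}\t{f.start - 1}\t{f.end}\t{f.feature_id}\n")

    result.gene2term.to_csv(outdir / "gene2term.tsv", sep="\t", index=False)
    result.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return outdir


# ---------------------------------------------------------------------------
# scoring


def score_recovery(
    truth: pd.DataFrame, selected: list[tuple[str, int, int]] | pd.DataFrame
) -> tuple[float, float]:
    """Sensitivity and false-discovery rate of a CNVR selection against
    the planted differentiated regions.

    ``selected`` holds (chrom, start, end) intervals (1-based inclusive).
    Sensitivity = fraction of differentiated truth regions overlapped
    (>=1 bp) by a selected interval; FDR = fraction of selected intervals
    overlapping no differentiated truth region.
    """
    if isinstance(selected, pd.DataFrame):
        selected = list(zip(selected["chrom"], selected["start"], selected["end"]))
    diff = truth[truth["klass"] == DIFFERENTIATED]
    n_diff = len(diff)
    if not selected:
        return (0.0 if n_diff else float("nan")), float("nan")
    hit_regions = 0
    for reg in diff.itertuples(index=False):
        if any(c == reg.chrom and s <= reg.end and e >= reg.start for c, s, e in selected):
            hit_regions += 1
    true_sel = sum(
        any(
            reg.chrom == c and reg.start <= e and reg.end >= s
            for reg in diff.itertuples(index=False)
        )
        for c, s, e in selected
    )
    sensitivity = hit_regions / n_diff if n_diff else float("nan")
    fdr = 1.0 - true_sel / len(selected)
    return sensitivity, fdr


def noise_free(config: SimConfig) -> SimConfig:
    """A copy of the config with RD noise, jitter and false positives off."""
    return replace(config, rd_noise_sd=0.0, boundary_jitter_bp=0, fp_rate_per_mb=0.0)
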