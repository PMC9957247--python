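"""CNVR construction and per-chromosome summary statistics.

Filtered per-sample CNV calls are merged into copy-number-variable
regions (CNVRs): the connected components of the graph whose nodes are
calls and whose edges join any two calls sharing at least 1 bp
(single-linkage, transitive).  On 1-based inclusive coordinates two
calls overlap iff ``start2 <= end1`` after sorting, so components are
maximal runs in a start-sorted sweep and their envelopes are pairwise
disjoint.

A CNVR is classified DEL if every member call is a deletion, DUP if
every member is a duplication, and BOTH otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BOTH, DEL, DUP, CnvCall, GenomeDef, SampleManifest


@dataclass(frozen=True)
class Cnvr:
    cnvr_id: str
    chrom: str
    start: int
    end: int
    cnvr_type: str  # DEL, DUP or BOTH
    member_calls: tuple[CnvCall, ...]

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def samples_by_population(self) -> dict[str, set[str]]:
        # populated lazily by callers that know the manifest; kept here as
        # a convenience over member sample ids only
        return {}

    @property
    def sample_ids(self) -> set[str]:
        return {c.sample_id for c in self.member_calls}


def _classify(calls: tuple[CnvCall, ...]) -> str:
    types = {c.cnv_type for c in calls}
    if types == {DEL}:
        return DEL
    if types == {DUP}:
        return DUP
    return BOTH


def build_cnvrs(calls: list[CnvCall], genome: GenomeDef) -> list[Cnvr]:
    """Merge calls into CNVRs (>=1 bp transitive overlap), sorted by
    genome chromosome order then start; ids CNVR_<chrom>_<serial>."""
    for c in calls:
        if c.chrom not in genome:
            raise ValueError(f"call on unknown chromosome {c.chrom!r}")
    by_chrom: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)

    cnvrs: list[Cnvr] = []
    for chrom in genome.names:
        chrom_calls = by_chrom.get(chrom)
        if not chrom_calls:
            continue
        chrom_calls.sort(key=lambda c: (c.start, c.end, c.sample_id, c.cnv_type))
        serial = 0
        component: list[CnvCall] = []
        env_end = -1
        for call in chrom_calls:
            if component and call.start > env_end:
                serial += 1
                cnvrs.append(_make_cnvr(chrom, serial, component))
                component = []
                env_end = -1
            component.append(call)
            env_end = max(env_end, call.end)
        if component:
            serial += 1
            cnvrs.append(_make_cnvr(chrom, serial, component))
    return cnvrs


def _make_cnvr(chrom: str, serial: int, component: list[CnvCall]) -> Cnvr:
    start = min(c.start for c in component)
    end = max(c.end for c in component)
    return Cnvr(
        cnvr_id=f"CNVR_{chrom}_{serial}",
        chrom=chrom,
        start=start,
        end=end,
        cnvr_type=_classify(tuple(component)),
        member_calls=tuple(component),
    )


def population_views(
    cnvrs: list[Cnvr], manifest: SampleManifest, genome: GenomeDef
) -> dict[str, list[Cnvr]]:
    """Joint view plus one view per population, each re-merged from that
    population's calls only (envelopes differ between views)."""
    pop_of = manifest.population_of
    views: dict[str, list[Cnvr]] = {"all": cnvrs}
    all_calls = [c for r in cnvrs for c in r.member_calls]
    for pop in manifest.populations:
        if not manifest.samples_in(pop):
            raise ValueError(f"population {pop} has no samples")
        pop_calls = [c for c in all_calls if pop_of.get(c.sample_id) == pop]
        views[pop] = build_cnvrs(pop_calls, genome)
    return views


# ---------------------------------------------------------------------------
# summaries


def _union_bp(intervals: list[tuple[int, int]]) -> int:
    """Total bp covered by the union of 1-based inclusive intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    covered = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return covered + (cur_e - cur_s + 1)


def summarize(cnvrs: list[Cnvr], genome: GenomeDef) -> pd.DataFrame:
    """Per-chromosome CNVR summary: counts by class, density (CNVRs/Mb),
    covered bp, coverage fraction, median and mean CNVR length.

    Chromosomes with no CNVRs report density/coverage 0 and median/mean 0
    with ``empty=True``.
    """
    rows = []
    by_chrom: dict[str, list[Cnvr]] = {}
    for r in cnvrs:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, length_bp in genome.chromosomes:
        rs = by_chrom.get(chrom, [])
        lengths = [r.length_bp for r in rs]
        n_dup = sum(r.cnvr_type == DUP for r in rs)
        n_del = sum(r.cnvr_type == DEL for r in rs)
        n_both = sum(r.cnvr_type == BOTH for r in rs)
        covered = _union_bp([(r.start, r.end) for r in rs])
        length_mb = length_bp / 1e6
        rows.append(
            {
                "chrom": chrom,
                "length_mb": length_mb,
                "n_total": len(rs),
                "n_dup": n_dup,
                "n_del": n_del,
                "n_both": n_both,
                "density_per_mb": len(rs) / length_mb,
                "covered_bp": covered,
                "coverage_fraction": covered / length_bp,
                "total_cnvr_mb": sum(lengths) / 1e6,
                "median_length_bp": float(np.median(lengths)) if lengths else 0.0,
                "mean_length_bp": float(np.mean(lengths)) if lengths else 0.0,
                "empty": not rs,
            }
        )
    return pd.DataFrame(rows)


def aggregate_summary(per_chrom: pd.DataFrame) -> dict[str, float]:
    """Genome-wide totals from a per-chromosome summary table.

    Works on any table with ``length_mb`` and ``n_total`` columns (and
    optionally ``n_dup``/``n_del``), so it applies both to summaries
    computed from CNVR objects and to externally reported count tables.
    Genome density is total count over total Mb.
    """
    total_mb = float(per_chrom["length_mb"].sum())
    out = {
        "n_total": int(per_chrom["n_total"].sum()),
        "length_mb": total_mb,
        "density_per_mb": float(per_chrom["n_total"].sum() / total_mb),
    }
    for col in ("n_dup", "n_del", "n_both", "covered_bp"):
        if col in per_chrom:
            out[col] = int(per_chrom[col].sum())
    return out


def dup_del_ratio(summary: pd.DataFrame | dict[str, float]) -> float:
    """DUP/DEL CNVR count ratio (mixed BOTH regions excluded).

    Returns NaN when there are no DEL regions.
    """
    if isinstance(summary, pd.DataFrame):
        summary = aggregate_summary(summary)
    n_del = summary["n_del"]
    if n_del == 0:
        return float("nan")
    return summary["n_dup"] / n_del


def length_count_correlation(per_chrom: pd.DataFrame) -> tuple[float, float]:
    """Pearson r between chromosome length and (a) CNVR count,
    (b) summed CNVR length, over chromosomes.

    Requires >=3 chromosomes.  The second value is NaN when the table
    carries no per-chromosome summed CNVR length.  Zero variance in a
    vector yields NaN for that correlation.
    """
    if len(per_chrom) < 3:
        raise ValueError("need >=3 chromosomes for a correlation")
    x = per_chrom["length_mb"].to_numpy(dtype=float)
    y = per_chrom["n_total"].to_numpy(dtype=float)
    r_count = _pearson(x, y)
    if "total_cnvr_mb" in per_chrom:
        r_length = _pearson(x, per_chrom["total_cnvr_mb"].to_numpy(dtype=float))
    else:
        r_length = float("nan")
    return r_count, r_length


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def cnvr_frame(cnvrs: list[Cnvr], manifest: SampleManifest | None = None) -> pd.DataFrame:
    """Tabular CNVR view for output files."""
    pop_of = manifest.population_of if manifest else {}
    rows = []
    for r in cnvrs:
        row = {
            "cnvr_id": r.cnvr_id,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "length_bp": r.length_bp,
            "cnvr_type": r.cnvr_type,
            "n_calls": len(r.member_calls),
            "n_samples": len(r.sample_ids),
        }
        if manifest:
            for pop in manifest.populations:
                row[f"n_samples_{pop}"] = len(
                    {c.sample_id for c in r.member_calls if pop_of.get(c.sample_id) == pop}
                )
        rows.append(row)
    cols = [
        "cnvr_id", "chrom", "start", "end", "length_bp", "cnvr_type",
        "n_calls", "n_samples",
    ]
    if manifest:
        cols += [f"n_samples_{pop}" for pop in manifest.populations]
    return pd.DataFrame(rows, columns=cols)
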