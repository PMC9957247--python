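"""Readers and writers for the external formats the pipeline touches.

All other modules see one internal coordinate convention: 1-based, fully
inclusive intervals (the CNVnator dialect).  BED input/output is converted
at this boundary; GFF3 is already 1-based inclusive and passes through
unshifted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

DEL = "DEL"
DUP = "DUP"
BOTH = "BOTH"


class CnvParseError(ValueError):
    """Raised for malformed rows in an input file; carries the line number."""


@dataclass(frozen=True)
class GenomeDef:
    """Ordered chromosome names and lengths (bp); the coordinate authority.

    The insertion order of ``chromosomes`` is the reporting order used by
    every downstream table.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome definition")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def order(self, chrom: str) -> int:
        return self.names.index(chrom)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass(frozen=True)
class CnvCall:
    """A single per-sample CNV call (1-based inclusive coordinates)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str  # DEL or DUP
    rd: float  # normalized read depth, diploid ~ 1.0
    e_value: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"call start {self.start} > end {self.end}")
        if self.cnv_type not in (DEL, DUP):
            raise ValueError(f"unknown CNV type {self.cnv_type!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AnnotationInterval:
    """A gene/QTL/other feature interval, internal 1-based inclusive."""

    chrom: str
    start: int
    end: int
    feature_id: str
    feature_class: str = "other"
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.feature_id}: start > end")
        if not self.feature_id:
            raise ValueError("feature_id must be non-empty")


@dataclass(frozen=True)
class SampleManifest:
    """Maps samples to populations and to their call files."""

    entries: tuple[tuple[str, str, str], ...]  # (sample_id, population_id, call_file)

    def __post_init__(self) -> None:
        ids = [s for s, _, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in manifest")
        for pop, n in self.population_sizes.items():
            if n < 1:
                raise ValueError(f"population {pop} has no samples")

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _, _ in self.entries]

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for _, pop, _ in self.entries:
            if pop not in seen:
                seen.append(pop)
        return seen

    @property
    def population_of(self) -> dict[str, str]:
        return {s: p for s, p, _ in self.entries}

    @property
    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for _, pop, _ in self.entries:
            sizes[pop] = sizes.get(pop, 0) + 1
        return sizes

    def samples_in(self, population_id: str) -> list[str]:
        return [s for s, p, _ in self.entries if p == population_id]


# ---------------------------------------------------------------------------
# readers


def read_genome(path: str | Path) -> GenomeDef:
    """Read a chromosome-sizes table (fai-like: name <tab> length_bp)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    chroms = tuple((str(r[0]), int(r[1])) for r in df.itertuples(index=False))
    return GenomeDef(chromosomes=chroms)


def read_manifest(path: str | Path) -> SampleManifest:
    """Read a sample manifest TSV: sample_id, population, call_file path.

    Relative call-file paths are resolved against the manifest's directory.
    """
    base = Path(path).parent
    df = pd.read_csv(path, sep="\t", dtype=str)
    entries = []
    for _, row in df.iterrows():
        sample_id, pop, call_file = row.iloc[0], row.iloc[1], row.iloc[2]
        p = Path(call_file)
        if not p.is_absolute():
            p = base / p
        entries.append((str(sample_id), str(pop), str(p)))
    return SampleManifest(entries=tuple(entries))


def _parse_coord_token(token: str, lineno: int) -> tuple[str, int, int]:
    try:
        chrom, span = token.rsplit(":", 1)
        s, e = span.split("-", 1)
        return chrom, int(s), int(e)
    except ValueError as exc:
        raise CnvParseError(
            f"line {lineno}: malformed coordinate token {token!r}"
        ) from exc


def read_cnvnator_calls(
    path: str | Path,
    sample_id: str,
    genome: GenomeDef | None = None,
    e_value_index: int = 0,
) -> list[CnvCall]:
    """Parse a CNVnator-dialect call file into :class:`CnvCall` records.

    Expected columns (whitespace-delimited, >=5):
    type ("deletion"/"duplication"), chrom:start-end, size, normalized RD,
    then one or more e-value columns.  ``e_value_index`` selects which of
    the e-value columns to carry (0 = the first, CNVnator's primary
    t-test e-value).
    """
    calls: list[CnvCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise CnvParseError(f"line {lineno}: expected >=5 columns, got {len(fields)}")
            kind = fields[0].lower()
            if "deletion" in kind:
                cnv_type = DEL
            elif "duplication" in kind:
                cnv_type = DUP
            else:
                raise CnvParseError(f"line {lineno}: unknown CNV type keyword {fields[0]!r}")
            chrom, start, end = _parse_coord_token(fields[1], lineno)
            if genome is not None and chrom not in genome:
                raise CnvParseError(
                    f"line {lineno}: chromosome {chrom!r} not in genome definition"
                )
            rd = float(fields[3])
            e_cols = fields[4:]
            if e_value_index >= len(e_cols):
                raise CnvParseError(
                    f"line {lineno}: e-value column {e_value_index} absent "
                    f"({len(e_cols)} e-value columns)"
                )
            e_value = float(e_cols[e_value_index])
            calls.append(
                CnvCall(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    cnv_type=cnv_type,
                    rd=rd,
                    e_value=e_value,
                )
            )
    return calls


def read_calls_for_manifest(
    manifest: SampleManifest,
    genome: GenomeDef | None = None,
    e_value_index: int = 0,
) -> list[CnvCall]:
    """Read every sample's call file listed in the manifest."""
    calls: list[CnvCall] = []
    for sample_id, _pop, path in manifest.entries:
        calls.extend(read_cnvnator_calls(path, sample_id, genome, e_value_index))
    return calls


def read_bed(path: str | Path, feature_class: str = "other") -> list[AnnotationInterval]:
    """Read BED3+ (0-based half-open) into internal 1-based inclusive intervals.

    Column 4 becomes the feature id when present; otherwise an id is
    synthesized from the internal coordinates.
    """
    out: list[AnnotationInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CnvParseError(f"line {lineno}: BED needs >=3 columns")
            chrom = fields[0]
            try:
                bed_start, bed_end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise CnvParseError(f"line {lineno}: non-integer BED coordinates") from exc
            start, end = bed_start + 1, bed_end
            if end < start:
                raise CnvParseError(f"line {lineno}: empty/negative BED interval")
            fid = fields[3] if len(fields) > 3 and fields[3] else f"{chrom}:{start}-{end}"
            out.append(AnnotationInterval(chrom, start, end, fid, feature_class))
    return out


def read_gff3(
    path: str | Path,
    feature_types: Iterable[str] = ("gene",),
    feature_class: str = "gene",
) -> list[AnnotationInterval]:
    """Read GFF3 intervals of the requested column-3 types (no coordinate shift)."""
    keep = set(feature_types)
    out: list[AnnotationInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise CnvParseError(f"line {lineno}: GFF3 needs 9 columns")
            if fields[2] not in keep:
                continue
            chrom, start, end = fields[0], int(fields[3]), int(fields[4])
            attrs = {}
            for item in fields[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k.strip()] = v.strip()
            fid = attrs.get("ID") or attrs.get("Name")
            if fid is None:
                fid = f"{chrom}:{start}-{end}"
                logger.warning("line %d: GFF3 record lacks ID/Name; synthesized %s", lineno, fid)
            out.append(AnnotationInterval(chrom, start, end, fid, feature_class, attrs))
    return out


def load_pig_cnvr_counts() -> pd.DataFrame:
    """Reported per-autosome CNVR counts for the Anqingliubai (AQ) domestic pig
    vs Asian wild boar (SS) comparison, with chromosome lengths in Mb.

    DUP + DEL under-sum each Total column; the remainder are mixed (BOTH)
    regions.
    """
    with resources.files("cnvpop.data").joinpath("pig_cnvr_chrom_counts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    return df


def read_calls_table(path: str | Path) -> list[CnvCall]:
    """Read the internal flat call TSV written by :func:`write_calls_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    return [
        CnvCall(r.sample_id, r.chrom, int(r.start), int(r.end), r.cnv_type,
                float(r.rd), float(r.e_value))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# writers

_FLOAT_FMT = "%.6g"


def write_calls_table(calls: Iterable[CnvCall], path: str | Path) -> None:
    """Flat TSV of calls (one row per call, sample column included)."""
    df = pd.DataFrame(
        [
            (c.sample_id, c.chrom, c.start, c.end, c.cnv_type, c.rd, c.e_value)
            for c in calls
        ],
        columns=["sample_id", "chrom", "start", "end", "cnv_type", "rd", "e_value"],
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with header, stable column order, floats at 6 sig digits."""
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_cnvr_table(cnvrs, path: str | Path) -> None:
    from .regions import cnvr_frame  # local import to avoid a cycle

    write_table(cnvr_frame(cnvrs), path)


def write_vst_table(vst_df: pd.DataFrame, path: str | Path) -> None:
    write_table(vst_df, path)


def write_selected_bed(records: Iterable, path: str | Path) -> None:
    """Write intervals as BED (back to 0-based half-open)."""
    with open(path, "w") as fh:
        for rec in records:
            name = getattr(rec, "cnvr_id", None) or getattr(rec, "feature_id", "")
            fh.write(f"{rec.chrom}\t{rec.start - 1}\t{rec.end}\t{name}\n")
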