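"""High-confidence CNV call filtering.

A call is kept only if it passes all four criteria (all comparisons
strict): e-value below the cutoff, read depth below ``del_rd_max`` for
deletions / above ``dup_rd_min`` for duplications, and length above
``min_length_bp``.  Boundary values (e.g. RD exactly 0.7 on a deletion,
length exactly 1000 bp) are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import DEL, DUP, CnvCall


@dataclass(frozen=True)
class FilterConfig:
    max_e_value: float = 0.01
    del_rd_max: float = 0.7
    dup_rd_min: float = 1.3
    min_length_bp: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.del_rd_max < self.dup_rd_min):
            raise ValueError("need 0 < del_rd_max < dup_rd_min")
        if not (0 < self.max_e_value <= 1):
            raise ValueError("max_e_value must be in (0, 1]")
        if self.min_length_bp < 0:
            raise ValueError("min_length_bp must be >= 0")


@dataclass
class FilterReport:
    """Per-rule rejection counts; a call failing k rules increments k counters."""

    total: int = 0
    kept: int = 0
    rejected_e_value: int = 0
    rejected_rd: int = 0
    rejected_length: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def passes(call: CnvCall, config: FilterConfig) -> bool:
    """Direct predicate form of the four filter rules."""
    if not call.e_value < config.max_e_value:
        return False
    if not call.length_bp > config.min_length_bp:
        return False
    if call.cnv_type == DEL and not call.rd < config.del_rd_max:
        return False
    if call.cnv_type == DUP and not call.rd > config.dup_rd_min:
        return False
    return True


def filter_calls(
    calls: list[CnvCall], config: FilterConfig | None = None
) -> tuple[list[CnvCall], FilterReport]:
    """Apply the four high-confidence filters; pure function of its inputs."""
    config = config or FilterConfig()
    report = FilterReport(total=len(calls))
    kept: list[CnvCall] = []
    for call in calls:
        ok = True
        if not call.e_value < config.max_e_value:
            report.rejected_e_value += 1
            ok = False
        if not call.length_bp > config.min_length_bp:
            report.rejected_length += 1
            ok = False
        rd_ok = call.rd < config.del_rd_max if call.cnv_type == DEL else call.rd > config.dup_rd_min
        if not rd_ok:
            report.rejected_rd += 1
            ok = False
        if ok:
            kept.append(call)
    report.kept = len(kept)
    return kept, report
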