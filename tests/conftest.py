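from __future__ import annotations

import pytest

from cnvpop import CnvCall, GenomeDef, SampleManifest


@pytest.fixture
def toy_genome() -> GenomeDef:
    return GenomeDef(chromosomes=(("1", 1_000_000), ("2", 500_000)))


@pytest.fixture
def two_pop_manifest() -> SampleManifest:
    entries = [(f"A{i}", "popA", f"calls/A{i}.tsv") for i in range(1, 5)]
    entries += [(f"B{i}", "popB", f"calls/B{i}.tsv") for i in range(1, 5)]
    return SampleManifest(entries=tuple(entries))


def make_call(
    sample="s1",
    chrom="1",
    start=100,
    end=200,
    cnv_type="DEL",
    rd=0.5,
    e_value=1e-4,
) -> CnvCall:
    return CnvCall(sample, chrom, start, end, cnv_type, rd, e_value)


@pytest.fixture
def call_factory():
    return make_call
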