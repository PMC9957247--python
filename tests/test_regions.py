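import random

import numpy as np
import pandas as pd
import pytest

from cnvpop import (
    GenomeDef,
    SampleManifest,
    aggregate_summary,
    build_cnvrs,
    dup_del_ratio,
    length_count_correlation,
    population_views,
    summarize,
)
from conftest import make_call
from oracles import bp_set_components, pearson_from_definition, union_bp_bitmap


def intervals_of(cnvrs):
    return [(r.start, r.end) for r in cnvrs]


def test_single_call_is_its_own_cnvr(toy_genome):
    (r,) = build_cnvrs([make_call(start=100, end=200)], toy_genome)
    assert (r.start, r.end, r.cnvr_type) == (100, 200, "DEL")
    assert r.cnvr_id == "CNVR_1_1"


def test_one_bp_intersection_merges_and_touching_does_not(toy_genome):
    a = make_call(sample="A", start=100, end=200)
    b = make_call(sample="B", start=200, end=300)
    (merged,) = build_cnvrs([a, b], toy_genome)
    assert (merged.start, merged.end, merged.cnvr_type) == (100, 300, "DEL")
    # inclusive coordinates: [100,200] and [201,300] share no bp
    c = make_call(sample="B", start=201, end=300)
    assert intervals_of(build_cnvrs([a, c], toy_genome)) == [(100, 200), (201, 300)]


def test_mixed_membership_classifies_both(toy_genome):
    a = make_call(sample="A", start=100, end=200, cnv_type="DEL")
    b = make_call(sample="B", start=150, end=400, cnv_type="DUP", rd=1.6)
    (r,) = build_cnvrs([a, b], toy_genome)
    assert (r.start, r.end, r.cnvr_type) == (100, 400, "BOTH")


def random_calls(rng, n, span=100_000):
    calls = []
    for i in range(n):
        start = rng.randrange(1, span)
        length = rng.randrange(1, 400)
        calls.append(
            make_call(
                sample=f"s{rng.randrange(5)}",
                start=start,
                end=min(span, start + length),
                cnv_type=rng.choice(["DEL", "DUP"]),
            )
        )
    return calls


def test_merge_equals_bitmap_oracle_on_random_sets(toy_genome):
    rng = random.Random(7)
    for _ in range(50):
        calls = random_calls(rng, rng.randrange(0, 40))
        got = intervals_of(build_cnvrs(calls, toy_genome))
        assert got == bp_set_components([(c.start, c.end) for c in calls])


def test_merge_is_order_invariant_and_conserves_calls(toy_genome):
    rng = random.Random(11)
    calls = random_calls(rng, 60)
    ref = build_cnvrs(calls, toy_genome)
    shuffled = calls[:]
    rng.shuffle(shuffled)
    alt = build_cnvrs(shuffled, toy_genome)
    assert intervals_of(ref) == intervals_of(alt)
    assert [r.cnvr_type for r in ref] == [r.cnvr_type for r in alt]
    # every call lands in exactly one CNVR
    assert sum(len(r.member_calls) for r in ref) == len(calls)


def test_unknown_chromosome_is_rejected(toy_genome):
    with pytest.raises(ValueError, match="chromosome"):
        build_cnvrs([make_call(chrom="99")], toy_genome)


def test_population_views_rebuild_per_population(toy_genome):
    manifest = SampleManifest(
        entries=(("A1", "popA", "x"), ("A2", "popA", "x"), ("B1", "popB", "x"))
    )
    calls = [
        make_call(sample="A1", start=100, end=200),
        make_call(sample="B1", start=180, end=400),
        make_call(sample="A2", start=350, end=500),  # bridges only via B1
        make_call(sample="A1", start=10_000, end=11_000),  # popA-only region
    ]
    views = population_views(build_cnvrs(calls, toy_genome), manifest, toy_genome)
    assert intervals_of(views["all"]) == [(100, 500), (10_000, 11_000)]
    # without B1's bridge, popA splits into two regions
    assert intervals_of(views["popA"]) == [(100, 200), (350, 500), (10_000, 11_000)]
    assert intervals_of(views["popB"]) == [(180, 400)]
    # per-population views equal a brute-force re-merge of the subset
    pa = [c for c in calls if c.sample_id.startswith("A")]
    assert intervals_of(views["popA"]) == intervals_of(build_cnvrs(pa, toy_genome))


def test_summarize_counts_density_and_coverage(toy_genome):
    calls = [
        make_call(sample="A", start=1, end=100_000),
        make_call(sample="B", start=200_001, end=300_000, cnv_type="DUP", rd=1.6),
        make_call(sample="A", start=250_000, end=260_000),
    ]
    cnvrs = build_cnvrs(calls, toy_genome)
    df = summarize(cnvrs, toy_genome)
    row1 = df[df.chrom == "1"].iloc[0]
    assert row1.n_total == 2 and row1.n_del == 1 and row1.n_both == 1
    assert row1.density_per_mb == pytest.approx(2 / 1.0)
    assert row1.covered_bp == union_bp_bitmap([(r.start, r.end) for r in cnvrs])
    assert row1.coverage_fraction == pytest.approx(row1.covered_bp / 1_000_000)
    row2 = df[df.chrom == "2"].iloc[0]
    assert row2.n_total == 0 and row2.density_per_mb == 0 and bool(row2["empty"])
    assert row2.median_length_bp == 0.0
    totals = aggregate_summary(df)
    assert totals["n_total"] == 2
    assert totals["density_per_mb"] == pytest.approx(2 / 1.5)


def test_dup_del_ratio_counts_and_degenerate_case():
    df = pd.DataFrame({"length_mb": [1, 1], "n_total": [4, 4],
                       "n_dup": [2, 2], "n_del": [2, 2]})
    assert dup_del_ratio(df) == 1.0
    no_del = pd.DataFrame({"length_mb": [1], "n_total": [2], "n_dup": [2], "n_del": [0]})
    assert np.isnan(dup_del_ratio(no_del))


def test_dup_del_ratio_matches_direct_count(toy_genome):
    rng = random.Random(3)
    calls = random_calls(rng, 40)
    cnvrs = build_cnvrs(calls, toy_genome)
    df = summarize(cnvrs, toy_genome)
    n_dup = sum(r.cnvr_type == "DUP" for r in cnvrs)
    n_del = sum(r.cnvr_type == "DEL" for r in cnvrs)
    if n_del:
        assert dup_del_ratio(df) == pytest.approx(n_dup / n_del)


def test_length_count_correlation_against_sum_formula():
    df = pd.DataFrame(
        {
            "length_mb": [10.0, 20.0, 30.0, 40.0],
            "n_total": [20, 40, 60, 80],
            "total_cnvr_mb": [1.0, 1.5, 3.1, 3.9],
        }
    )
    r_count, r_length = length_count_correlation(df)
    assert r_count == pytest.approx(1.0)  # exactly proportional
    assert r_length == pytest.approx(
        pearson_from_definition(df.length_mb.tolist(), df.total_cnvr_mb.tolist())
    )
    rng = np.random.default_rng(5)
    rnd = pd.DataFrame(
        {"length_mb": rng.uniform(10, 300, 12), "n_total": rng.integers(10, 900, 12)}
    )
    r_count, _ = length_count_correlation(rnd)
    assert r_count == pytest.approx(
        pearson_from_definition(rnd.length_mb.tolist(), rnd.n_total.tolist())
    )


def test_correlation_needs_three_chromosomes():
    df = pd.DataFrame({"length_mb": [1.0, 2.0], "n_total": [1, 2]})
    with pytest.raises(ValueError):
        length_count_correlation(df)
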