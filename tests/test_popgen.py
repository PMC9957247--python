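import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dendropy

from cnvpop import (
    CopyNumberMatrix,
    SampleManifest,
    build_cn_matrix,
    build_cnvrs,
    compute_vst,
    pca,
    select_top,
    upgma_tree,
    vst_from_values,
    vst_table,
)
from conftest import make_call
from oracles import vst_by_hand


def matrix_from(values, sample_ids, pops, cnvr_ids=None):
    values = np.asarray(values, dtype=float)
    return CopyNumberMatrix(
        cnvr_ids=cnvr_ids or [f"r{i}" for i in range(values.shape[0])],
        sample_ids=list(sample_ids),
        values=values,
        population_of=dict(zip(sample_ids, pops)),
    )


# ---------------------------------------------------------------------------
# copy-number matrix


def test_cn_matrix_from_call_read_depths(toy_genome):
    manifest = SampleManifest(
        entries=(("A1", "popA", "x"), ("A2", "popA", "x"), ("B1", "popB", "x"))
    )
    calls = [
        # A1's duplication covers the whole region -> CN = 2 * 1.5
        make_call(sample="A1", start=1, end=10_000, cnv_type="DUP", rd=1.5),
        # A2's deletion covers half of it -> mean RD (0.5*5000 + 1*5000)/10000
        make_call(sample="A2", start=1, end=5_000, cnv_type="DEL", rd=0.5),
    ]
    cnvrs = build_cnvrs(calls, toy_genome)
    m = build_cn_matrix(cnvrs, manifest)
    assert m.values.shape == (1, 3)
    assert m.row("CNVR_1_1")[0] == pytest.approx(3.0)
    assert m.row("CNVR_1_1")[1] == pytest.approx(1.5)
    assert m.row("CNVR_1_1")[2] == 2.0  # no call -> diploid default


def test_cn_matrix_rounding_switch(toy_genome):
    manifest = SampleManifest(entries=(("A1", "popA", "x"), ("B1", "popB", "x")))
    calls = [make_call(sample="A1", start=1, end=2000, cnv_type="DUP", rd=1.4)]
    cnvrs = build_cnvrs(calls, toy_genome)
    assert build_cn_matrix(cnvrs, manifest).values[0, 0] == pytest.approx(2.8)
    assert build_cn_matrix(cnvrs, manifest, round_cn=True).values[0, 0] == 3.0


# ---------------------------------------------------------------------------
# VST


def test_vst_worked_values():
    # hand arithmetic, denominator-N variances:
    # v1=1, v2=0, v_total=0.75, within=(1*4+0*4)/8=0.5 -> (0.75-0.5)/0.75
    vst, vt, v1, v2, degen, _ = vst_from_values([2, 2, 4, 4], [2, 2, 2, 2])
    assert (v1, v2, vt) == (1.0, 0.0, 0.75)
    assert vst == pytest.approx(1 / 3)
    assert not degen
    # zero within-population variance with between-population difference
    assert vst_from_values([4, 4, 4], [2, 2, 2])[0] == pytest.approx(1.0)
    # no variation at all -> degenerate, defined as 0
    vst, *_rest, degen, _cl = vst_from_values([2, 2], [2, 2])
    assert vst == 0.0 and degen


def test_compute_vst_requires_two_populations():
    m = matrix_from([[2, 2, 2]], ["a", "b", "c"], ["p1", "p2", "p3"])
    with pytest.raises(ValueError, match="2 populations"):
        compute_vst(m, "r0")


def test_vst_table_agrees_with_scalar_path():
    rng = np.random.default_rng(0)
    values = rng.uniform(0, 5, size=(30, 10))
    pops = ["p1"] * 6 + ["p2"] * 4
    m = matrix_from(values, [f"s{i}" for i in range(10)], pops)
    table = vst_table(m)
    for i, cnvr_id in enumerate(m.cnvr_ids):
        rec = compute_vst(m, cnvr_id)
        assert table.loc[i, "vst"] == pytest.approx(rec.vst)
        assert rec.n_pop1 == 6 and rec.n_pop2 == 4 and rec.n_total == 10


# quarter-integer copy numbers: representative of the estimator's range
# without the catastrophic-cancellation corner cases of raw floats
vectors = st.lists(
    st.integers(0, 32).map(lambda i: i / 4.0), min_size=1, max_size=12
)


@settings(deadline=None, derandomize=True)
@given(vectors, vectors)
def test_vst_properties(pop1, pop2):
    vst, *_ = vst_from_values(pop1, pop2)
    assert 0.0 <= vst <= 1.0
    assert vst == pytest.approx(vst_by_hand(pop1, pop2), abs=1e-9)
    # symmetric under population relabeling
    assert vst == pytest.approx(vst_from_values(pop2, pop1)[0], abs=1e-12)
    # invariant to adding a constant and to scaling by c != 0
    shifted = vst_from_values([x + 3 for x in pop1], [x + 3 for x in pop2])[0]
    scaled = vst_from_values([x * 2.5 for x in pop1], [x * 2.5 for x in pop2])[0]
    assert vst == pytest.approx(shifted, abs=1e-9)
    assert vst == pytest.approx(scaled, abs=1e-9)


def test_vst_is_one_iff_no_within_variance():
    vst, vt, v1, v2, *_ = vst_from_values([4.0, 4.0], [2.0, 2.0, 2.0])
    assert vst == 1.0 and v1 == v2 == 0.0 and vt > 0


# ---------------------------------------------------------------------------
# top-percentile selection


def _vst_frame(values):
    return pd.DataFrame(
        {"cnvr_id": [f"r{i}" for i in range(len(values))],
         "vst": values,
         "degenerate": [False] * len(values)}
    )


def test_nearest_rank_selection_with_ties_included():
    df = _vst_frame([round(i * 0.01, 2) for i in range(100)])
    out, thr = select_top(df, fractions=(0.10, 0.01))
    assert thr[0.01] == pytest.approx(0.98)  # rank ceil(0.99*100) = 99
    assert out["top1pct"].sum() == 2  # 0.98 and 0.99
    assert thr[0.10] == pytest.approx(0.89)
    assert out["top10pct"].sum() == 11
    assert thr[0.01] >= thr[0.10]


def test_selection_edge_cases():
    all_equal = _vst_frame([0.4] * 7)
    out, thr = select_top(all_equal)
    assert out["top1pct"].all() and out["top10pct"].all()
    single = _vst_frame([0.2])
    out, _ = select_top(single)
    assert out["top1pct"].all()
    degenerate = _vst_frame([0.0, 0.0])
    degenerate["degenerate"] = True
    out, thr = select_top(degenerate)
    assert not out["top1pct"].any() and np.isnan(thr[0.01])


# ---------------------------------------------------------------------------
# PCA


def test_pca_rank_one_and_constant_matrices():
    base = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]])
    m = matrix_from(base, list("abcd"), ["p1", "p1", "p2", "p2"])
    coords, var = pca(m)
    assert var[0] == pytest.approx(1.0)
    assert np.abs(var[1:]).max() < 1e-12
    const = matrix_from(np.full((3, 4), 2.0), list("abcd"), ["p1", "p1", "p2", "p2"])
    _, var = pca(const)
    assert np.isnan(var).all()


def test_pca_variance_fractions_sum_to_one():
    rng = np.random.default_rng(1)
    m = matrix_from(rng.uniform(0, 4, (20, 8)), [f"s{i}" for i in range(8)],
                    ["p1"] * 4 + ["p2"] * 4)
    coords, var = pca(m)
    assert var.sum() == pytest.approx(1.0)
    assert list(coords.index) == m.sample_ids


def test_pca_needs_two_samples():
    m = matrix_from([[2.0]], ["only"], ["p1"])
    with pytest.raises(ValueError):
        pca(m)


# ---------------------------------------------------------------------------
# UPGMA tree


def test_upgma_three_leaf_topology_and_ultrametric_lengths():
    # d(A,B)=1, d(A,C)=d(B,C)=4 -> ((A,B),C) with heights 0.5 and 2
    coords = {"A": (0.0, 0.0), "B": (1.0, 0.0), "C": (0.5, np.sqrt(16 - 0.25))}
    values = np.array([coords[s] for s in "ABC"]).T  # 2 features x 3 samples
    m = matrix_from(values, list("ABC"), ["p1", "p1", "p2"])
    newick = upgma_tree(m)
    tree = dendropy.Tree.get(
        data=newick, schema="newick", rooting="force-rooted",
        preserve_underscores=True,
    )
    taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    assert taxa == {"A", "B", "C"}
    dist = tree.phylogenetic_distance_matrix()
    t = {x.label: x for x in tree.taxon_namespace}
    assert dist.distance(t["A"], t["B"]) == pytest.approx(1.0)
    assert dist.distance(t["A"], t["C"]) == pytest.approx(4.0, rel=1e-6)
    # cherry (A,B) exists
    ab = tree.mrca(taxa=[t["A"], t["B"]])
    assert {leaf.taxon.label for leaf in ab.leaf_iter()} == {"A", "B"}


def test_upgma_two_samples_is_a_cherry():
    m = matrix_from([[2.0, 4.0]], ["x", "y"], ["p1", "p2"])
    assert upgma_tree(m) == "(x:1,y:1);"


def test_upgma_rejects_duplicate_ids():
    m = CopyNumberMatrix(["r0"], ["a", "a"], np.array([[2.0, 2.0]]), {"a": "p1"})
    with pytest.raises(ValueError, match="duplicate"):
        upgma_tree(m)
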