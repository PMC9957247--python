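"""Interval annotation of CNVRs and hypergeometric term enrichment.

Overlap uses the same >=1 bp criterion as CNVR merging.  Enrichment is
the standard over-representation test: for a term carried by K of the N
universe genes, with n genes selected and k of them carrying the term,
p = P(X >= k) under Hypergeometric(N, K, n), Benjamini-Hochberg adjusted
across the tested terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import AnnotationInterval
from .regions import Cnvr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapHit:
    cnvr_id: str
    feature_id: str
    feature_class: str
    overlap_bp: int
    jaccard: float


def overlap(
    cnvrs: Iterable[Cnvr],
    features: Iterable[AnnotationInterval],
    min_overlap_bp: int = 1,
    min_jaccard: float = 0.0,
) -> list[OverlapHit]:
    """All (CNVR, feature) pairs sharing >= ``min_overlap_bp`` bp.

    Features on chromosomes with no CNVR are simply never hit; a feature
    whose chromosome is absent from the CNVR set produces no warning, but
    callers validating against a genome should do so upstream.  Overlap
    and jaccard are computed on 1-based inclusive coordinates.
    """
    trees: dict[str, IntervalTree] = {}
    for r in cnvrs:
        # IntervalTree is half-open; end+1 makes inclusive ends queryable
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, r)
    hits: list[OverlapHit] = []
    for f in features:
        tree = trees.get(f.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(f.start, f.end + 1)):
            r: Cnvr = iv.data
            ov = min(r.end, f.end) - max(r.start, f.start) + 1
            if ov < min_overlap_bp:
                continue
            union = r.length_bp + (f.end - f.start + 1) - ov
            jac = ov / union
            if jac < min_jaccard:
                continue
            hits.append(OverlapHit(r.cnvr_id, f.feature_id, f.feature_class, ov, jac))
    hits.sort(key=lambda h: (h.cnvr_id, h.feature_id))
    return hits


def overlap_frame(hits: list[OverlapHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [h.__dict__ for h in hits],
        columns=["cnvr_id", "feature_id", "feature_class", "overlap_bp", "jaccard"],
    )


def enrich(
    selected_genes: set[str],
    gene2term: Mapping[str, set[str]] | pd.DataFrame,
    universe: set[str],
    term_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of terms among selected genes.

    ``gene2term`` maps gene -> set of term ids, or is a DataFrame with
    columns (gene_id, term_id[, term_name]).  Terms with no selected
    gene (k = 0) are skipped.  Returns a DataFrame sorted by p-value with
    Benjamini-Hochberg q-values.
    """
    if not universe:
        raise ValueError("empty gene universe")
    extra = selected_genes - universe
    if extra:
        raise ValueError(f"selected genes outside universe: {sorted(extra)[:5]}")
    if isinstance(gene2term, pd.DataFrame):
        names = {}
        mapping: dict[str, set[str]] = {}
        for row in gene2term.itertuples(index=False):
            mapping.setdefault(str(row.gene_id), set()).add(str(row.term_id))
            if hasattr(row, "term_name"):
                names[str(row.term_id)] = str(row.term_name)
        gene2term = mapping
        term_names = term_names or names
    term_names = term_names or {}

    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        for term in gene2term.get(gene, ()):  # type: ignore[union-attr]
            term_genes.setdefault(term, set()).add(gene)

    n_universe = len(universe)
    n_selected = len(selected_genes)
    rows = []
    for term, genes in sorted(term_genes.items()):
        k = len(genes & selected_genes)
        if k == 0:
            continue
        big_k = len(genes)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n_selected))
        rows.append(
            {
                "term_id": term,
                "term_name": term_names.get(term, ""),
                "k_selected": k,
                "K_term": big_k,
                "n_selected": n_selected,
                "N_universe": n_universe,
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "k_selected", "K_term",
            "n_selected", "N_universe", "p_value",
        ],
    )
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df
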