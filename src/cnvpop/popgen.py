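"""Copy-number matrix, VST differentiation statistic, top-percentile
selection, PCA and sample clustering.

VST is the copy-number analogue of FST: for one region,

    VST = (V_total - (V_pop1 * N_pop1 + V_pop2 * N_pop2) / N_total) / V_total

where V_total is the variance of the pooled copy numbers and V_pop1,
V_pop2 are the within-population variances.  Variances use the
population (denominator N) convention: with it the sample-size-weighted
within-group term is exactly the pooled within-group sum of squares over
N_total, so VST is the between-group fraction of total variance and lies
in [0, 1] up to floating point.  With no copy-number variation at all
(V_total = 0) VST is defined as 0 and flagged degenerate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .io import SampleManifest
from .regions import Cnvr

logger = logging.getLogger(__name__)


@dataclass
class CopyNumberMatrix:
    """CNVR x sample estimated copy numbers (diploid = 2.0), dense."""

    cnvr_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_cnvrs, n_samples)
    population_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.cnvr_ids), len(self.sample_ids)):
            raise ValueError("matrix shape inconsistent with id lists")

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            p = self.population_of[s]
            if p not in seen:
                seen.append(p)
        return seen

    def sample_mask(self, population_id: str) -> np.ndarray:
        return np.array([self.population_of[s] == population_id for s in self.sample_ids])

    def row(self, cnvr_id: str) -> np.ndarray:
        return self.values[self.cnvr_ids.index(cnvr_id)]


@dataclass(frozen=True)
class VstRecord:
    cnvr_id: str
    vst: float
    v_total: float
    v_pop1: float
    v_pop2: float
    n_pop1: int
    n_pop2: int
    degenerate: bool = False
    clamped: bool = False

    @property
    def n_total(self) -> int:
        return self.n_pop1 + self.n_pop2


def build_cn_matrix(
    cnvrs: list[Cnvr],
    manifest: SampleManifest,
    round_cn: bool = False,
) -> CopyNumberMatrix:
    """Estimate per-sample copy number over each CNVR from call read depths.

    Cell (r, s) = 2 x length-weighted mean RD across CNVR r for sample s:
    bp covered by s's member calls contribute the call RD, uncovered bp
    contribute the diploid RD 1.0.  A sample with no call in the region
    gets exactly 2.0.  Where a sample's calls overlap each other inside
    the region, each bp takes the mean RD of its covering calls.
    """
    sample_ids = list(manifest.sample_ids)
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    values = np.full((len(cnvrs), len(sample_ids)), 2.0)
    for ri, region in enumerate(cnvrs):
        by_sample: dict[str, list] = {}
        for call in region.member_calls:
            by_sample.setdefault(call.sample_id, []).append(call)
        span = region.length_bp
        for sid, calls in by_sample.items():
            si = sample_index.get(sid)
            if si is None:
                continue
            mean_rd = _weighted_mean_rd(calls, region.start, region.end, span)
            values[ri, si] = 2.0 * mean_rd
    if round_cn:
        values = np.rint(values)
    return CopyNumberMatrix(
        cnvr_ids=[r.cnvr_id for r in cnvrs],
        sample_ids=sample_ids,
        values=values,
        population_of=manifest.population_of,
    )


def _weighted_mean_rd(calls, start: int, end: int, span: int) -> float:
    # elementary-segment walk: handles same-sample calls that overlap
    pts = {start, end + 1}
    clipped = []
    for c in calls:
        s, e = max(c.start, start), min(c.end, end)
        if s > e:
            continue
        clipped.append((s, e, c.rd))
        pts.add(s)
        pts.add(e + 1)
    if not clipped:
        return 1.0
    cuts = sorted(pts)
    total = 0.0
    for a, b in zip(cuts[:-1], cuts[1:]):
        seg = b - a  # [a, b) in cut space == seg bp
        rds = [rd for s, e, rd in clipped if s <= a <= e]
        total += seg * (sum(rds) / len(rds) if rds else 1.0)
    return total / span


# ---------------------------------------------------------------------------
# VST


def vst_from_values(pop1: np.ndarray, pop2: np.ndarray) -> tuple[float, float, float, float, bool, bool]:
    """Core VST arithmetic on two copy-number vectors.

    Returns (vst, v_total, v_pop1, v_pop2, degenerate, clamped).
    """
    pop1 = np.asarray(pop1, dtype=float)
    pop2 = np.asarray(pop2, dtype=float)
    if pop1.size == 0 or pop2.size == 0:
        raise ValueError("both populations need >=1 sample")
    n1, n2 = pop1.size, pop2.size
    v1 = float(np.var(pop1))  # denominator N
    v2 = float(np.var(pop2))
    v_total = float(np.var(np.concatenate([pop1, pop2])))
    if v_total == 0.0:
        return 0.0, v_total, v1, v2, True, False
    vst = (v_total - (v1 * n1 + v2 * n2) / (n1 + n2)) / v_total
    clamped = False
    if vst < 0.0 or vst > 1.0:
        # only floating-point noise can leave [0,1] under the N convention
        logger.debug("VST %.17g clamped to [0,1]", vst)
        vst = min(max(vst, 0.0), 1.0)
        clamped = True
    return vst, v_total, v1, v2, False, clamped


def compute_vst(matrix: CopyNumberMatrix, cnvr_id: str) -> VstRecord:
    """VST for one region of the matrix (exactly two populations required)."""
    pops = matrix.populations
    if len(pops) != 2:
        raise ValueError(f"VST requires exactly 2 populations, got {len(pops)}: {pops}")
    row = matrix.row(cnvr_id)
    m1, m2 = matrix.sample_mask(pops[0]), matrix.sample_mask(pops[1])
    vst, vt, v1, v2, degen, clamped = vst_from_values(row[m1], row[m2])
    return VstRecord(cnvr_id, vst, vt, v1, v2, int(m1.sum()), int(m2.sum()), degen, clamped)


def vst_table(matrix: CopyNumberMatrix) -> pd.DataFrame:
    """Vectorized VST for every region; one row per CNVR."""
    pops = matrix.populations
    if len(pops) != 2:
        raise ValueError(f"VST requires exactly 2 populations, got {len(pops)}: {pops}")
    m1, m2 = matrix.sample_mask(pops[0]), matrix.sample_mask(pops[1])
    x1, x2 = matrix.values[:, m1], matrix.values[:, m2]
    n1, n2 = x1.shape[1], x2.shape[1]
    v1 = x1.var(axis=1)
    v2 = x2.var(axis=1)
    v_total = matrix.values.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vst = (v_total - (v1 * n1 + v2 * n2) / (n1 + n2)) / v_total
    degenerate = v_total == 0.0
    vst = np.where(degenerate, 0.0, vst)
    clamped = (vst < 0.0) | (vst > 1.0)
    vst = np.clip(vst, 0.0, 1.0)
    return pd.DataFrame(
        {
            "cnvr_id": matrix.cnvr_ids,
            "vst": vst,
            "v_total": v_total,
            "v_pop1": v1,
            "v_pop2": v2,
            "n_pop1": n1,
            "n_pop2": n2,
            "degenerate": degenerate,
            "clamped": clamped,
        }
    )


def select_top(
    vst_df: pd.DataFrame, fractions: tuple[float, ...] = (0.10, 0.01)
) -> tuple[pd.DataFrame, dict[float, float]]:
    """Flag records in the top fraction of the VST distribution.

    The threshold for fraction f is the nearest-rank order statistic at
    rank ceil((1 - f) * M) of the M sorted values; a record is selected
    iff vst >= threshold, so ties at the threshold are all included.
    """
    vals = np.sort(vst_df["vst"].to_numpy(dtype=float))
    m = vals.size
    if m == 0 or bool(vst_df["degenerate"].all()):
        logger.warning("all VST values degenerate; empty selection")
        out = vst_df.copy()
        for f in fractions:
            out[_flag_name(f)] = False
        return out, {f: float("nan") for f in fractions}
    out = vst_df.copy()
    thresholds: dict[float, float] = {}
    for f in fractions:
        rank = max(1, math.ceil((1.0 - f) * m))  # 1-based
        thr = float(vals[rank - 1])
        thresholds[f] = thr
        out[_flag_name(f)] = out["vst"] >= thr
    return out, thresholds


def _flag_name(fraction: float) -> str:
    pct = fraction * 100
    label = f"{pct:g}".replace(".", "_")
    return f"top{label}pct"


# ---------------------------------------------------------------------------
# PCA and sample tree


def pca(matrix: CopyNumberMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of samples from the column-centered
    sample x CNVR matrix, by singular value decomposition.

    Returns (coordinates as a sample-indexed DataFrame, variance
    explained per component).  Sign convention: the largest-magnitude
    loading of each component is positive.  A constant matrix (zero
    total variance) yields NaN variance fractions.
    """
    if len(matrix.sample_ids) < 2:
        raise ValueError("PCA needs >=2 samples")
    x = matrix.values.T.astype(float)  # samples x cnvrs
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # fix signs from loadings
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    coords = u * s
    total = float((s**2).sum())
    if total == 0.0:
        var_explained = np.full(s.shape, np.nan)
    else:
        var_explained = s**2 / total
    df = pd.DataFrame(
        coords,
        index=pd.Index(matrix.sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return df, var_explained


def upgma_tree(matrix: CopyNumberMatrix, metric: str = "euclidean") -> str:
    """UPGMA clustering of samples on pairwise copy-number distances,
    returned as a Newick string with ultrametric branch lengths.

    Samples are processed in lexicographic id order so equal-distance
    merges resolve deterministically.  Leaf-to-root distance equals half
    the cophenetic distance at each merge.
    """
    ids = sorted(matrix.sample_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sample ids")
    if len(ids) < 2:
        raise ValueError("need >=2 samples for a tree")
    order = [matrix.sample_ids.index(s) for s in ids]
    x = matrix.values.T[order].astype(float)
    z = linkage(pdist(x, metric=metric), method="average")
    return _linkage_to_newick(z, ids)


def _linkage_to_newick(z: np.ndarray, leaf_names: list[str]) -> str:
    n = len(leaf_names)
    # node -> (newick fragment, height of node)
    nodes: dict[int, tuple[str, float]] = {i: (leaf_names[i], 0.0) for i in range(n)}
    for k, (a, b, dist, _count) in enumerate(z):
        a, b = int(a), int(b)
        height = dist / 2.0
        fa, ha = nodes.pop(a)
        fb, hb = nodes.pop(b)
        frag = f"({fa}:{height - ha:.10g},{fb}:{height - hb:.10g})"
        nodes[n + k] = (frag, height)
    (frag, _h), = nodes.values()
    return frag + ";"
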