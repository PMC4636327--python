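"""Diversity statistics: rarefaction, representative tree, generalized
UniFrac, PCoA, and composition profiles with display conventions.

The generalized UniFrac distance between two relative-abundance profiles
p and q on the leaves of a rooted tree with branch lengths b_i is

    d_alpha(p, q) = sum_i b_i (p_i + q_i)^alpha |p_i - q_i| / (p_i + q_i)
                    / sum_i b_i (p_i + q_i)^alpha

where p_i, q_i are the summed leaf proportions below branch i and branches
with p_i + q_i = 0 are skipped. alpha tunes the weight of abundant
lineages: alpha = 1 recovers the weighted-normalized form, small alpha
upweights rare lineages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj

from .classify import RANKS, UNCLASSIFIED
from .otucluster import DistanceMatrix, OTUTable, distance_matrix as _distmat

OTHER_CATEGORY = "other (<0.5%)"

#: alpha presets mirroring the figure conventions: dilution/negative-control
#: comparisons use 0.6, tissue ordinations 0.2
ALPHA_PRESETS = {"dilution": 0.6, "tissue": 0.2}


@dataclass
class RarefactionCurve:
    depths: np.ndarray
    mean_otu_count: np.ndarray
    resamples: int


def rarefaction(
    counts: dict[str, int] | np.ndarray,
    step: int = 100,
    resamples: int = 1000,
    seed: int | np.random.Generator = 0,
) -> RarefactionCurve:
    """Mean observed OTU richness under subsampling without replacement.

    Depths run step, 2*step, ... up to the sample total; the final point at
    the full depth (observed richness, exactly) is always included.
    """
    vec = (
        np.array(list(counts.values()), dtype=np.int64)
        if isinstance(counts, dict)
        else np.asarray(counts, dtype=np.int64)
    )
    vec = vec[vec > 0]
    total = int(vec.sum())
    if total < step:
        raise ValueError(f"sample total {total} is below the step size {step}")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    depths = list(range(step, total, step)) + [total]
    means = []
    for depth in depths:
        if depth == total:
            means.append(float(len(vec)))
            continue
        draws = rng.multivariate_hypergeometric(vec, depth, size=resamples)
        means.append(float((draws > 0).sum(axis=1).mean()))
    return RarefactionCurve(np.array(depths), np.array(means), resamples)


def rarefaction_expectation(counts: np.ndarray | dict, depth: int) -> float:
    """Closed-form expected richness at a depth (hypergeometric)."""
    vec = (
        np.array(list(counts.values()), dtype=np.int64)
        if isinstance(counts, dict)
        else np.asarray(counts, dtype=np.int64)
    )
    vec = vec[vec > 0]
    total = int(vec.sum())

    def logcomb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = 0.0
    for c in vec:
        if total - c < depth:
            out += 1.0
        else:
            out += 1.0 - np.exp(logcomb(total - c, depth) - logcomb(total, depth))
    return float(out)


def build_representative_tree(representatives: list) -> TreeNode:
    """Neighbor-joining tree over OTU representatives, midpoint-rooted,
    negative branch lengths clamped to zero.

    ``representatives`` are blunt AlignedSequence objects (>= 2)."""
    if len(representatives) < 2:
        raise ValueError("need at least 2 representatives")
    dm = _distmat(representatives)
    return tree_from_distance_matrix(dm)


def tree_from_distance_matrix(dm: DistanceMatrix) -> TreeNode:
    if len(dm.ids) == 2:
        half = dm.d[0, 1] / 2
        a, b = dm.ids
        return TreeNode.read([f"({a}:{half},{b}:{half});"])
    sk = SkbioDM(dm.d, ids=dm.ids)
    tree = nj(sk)
    tree = tree.root_at_midpoint()
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def _branch_table(tree: TreeNode, leaf_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(branch lengths, leaf-membership matrix) for every non-root node."""
    idx = {name: i for i, name in enumerate(leaf_ids)}
    lengths = []
    member = []
    for node in tree.postorder(include_self=False):
        if node.length is None:
            continue
        row = np.zeros(len(leaf_ids))
        for tip in node.tips(include_self=True):
            row[idx[tip.name]] = 1.0
        lengths.append(node.length)
        member.append(row)
    return np.array(lengths), np.array(member)


def generalized_unifrac(
    tree: TreeNode,
    p: dict[str, float] | np.ndarray,
    q: dict[str, float] | np.ndarray,
    alpha: float = 0.6,
    leaf_ids: list[str] | None = None,
) -> float:
    """Generalized UniFrac distance between two leaf-proportion profiles."""
    if leaf_ids is None:
        leaf_ids = sorted(t.name for t in tree.tips())
    pv = np.array([p[k] for k in leaf_ids]) if isinstance(p, dict) else np.asarray(p, float)
    qv = np.array([q[k] for k in leaf_ids]) if isinstance(q, dict) else np.asarray(q, float)
    for v, name in ((pv, "p"), (qv, "q")):
        if v.min() < 0 or not np.isclose(v.sum(), 1.0, atol=1e-8):
            raise ValueError(f"{name} must be non-negative and sum to 1")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    b, member = _branch_table(tree, leaf_ids)
    pi = member @ pv
    qi = member @ qv
    tot = pi + qi
    keep = tot > 0
    if not np.any(keep):
        return 0.0
    w = b[keep] * tot[keep] ** alpha
    num = float((w * np.abs(pi[keep] - qi[keep]) / tot[keep]).sum())
    den = float(w.sum())
    return num / den if den > 0 else 0.0


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (may be negative)
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis via Gower double-centering.

    Axes for negative eigenvalues are dropped from the coordinates but the
    eigenvalues themselves are reported. Axis signs are fixed so the
    largest-magnitude loading on each axis is positive.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 samples")
    d2 = dm.d**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    pos = evals > 1e-12
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] *= -1
    pos_sum = evals[pos].sum()
    prop = evals / pos_sum if pos_sum > 0 else np.zeros_like(evals)
    df = pd.DataFrame(
        coords, index=dm.ids, columns=[f"PC{j+1}" for j in range(coords.shape[1])]
    )
    return OrdinationResult(df, evals, prop)


@dataclass
class CompositionProfile:
    """Per-sample relative abundances at one rank, with the low-abundance
    pool and the unclassified category."""

    rank: str
    proportions: pd.DataFrame  # rows = taxa (incl. special), columns = samples

    def sample(self, sample_id: str) -> pd.Series:
        return self.proportions[sample_id]


def composition_profile(
    table: OTUTable, rank: str, other_threshold: float = 0.005
) -> CompositionProfile:
    """Aggregate the OTU table to a rank; taxa whose cross-sample mean
    proportion falls below the threshold are pooled into "other (<0.5%)",
    and sub-cutoff assignments feed "unclassified"."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if table.is_empty or table.counts.empty:
        raise ValueError("empty OTU table")
    labels = {
        otu: table.lineages.get(otu, {}).get(rank, (UNCLASSIFIED, 0.0))[0]
        for otu in table.counts.index
    }
    grouped = table.counts.groupby(labels).sum()
    props = grouped / grouped.sum(axis=0)
    props = props.fillna(0.0)
    mean_prop = props.mean(axis=1)
    low = [
        t for t in props.index if t != UNCLASSIFIED and mean_prop[t] < other_threshold
    ]
    keep = [t for t in props.index if t not in low and t != UNCLASSIFIED]
    rows = {t: props.loc[t] for t in sorted(keep)}
    rows[OTHER_CATEGORY] = (
        props.loc[low].sum(axis=0) if low else pd.Series(0.0, index=props.columns)
    )
    rows[UNCLASSIFIED] = (
        props.loc[UNCLASSIFIED]
        if UNCLASSIFIED in props.index
        else pd.Series(0.0, index=props.columns)
    )
    out = pd.DataFrame(rows).T
    return CompositionProfile(rank, out)


def log10_transform(profile: CompositionProfile) -> pd.DataFrame:
    """Heatmap export convention: log10(proportion + eps) with eps = smallest
    nonzero proportion / 10."""
    vals = profile.proportions.to_numpy()
    nonzero = vals[vals > 0]
    eps = nonzero.min() / 10 if nonzero.size else 1e-6
    return np.log10(profile.proportions + eps)
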