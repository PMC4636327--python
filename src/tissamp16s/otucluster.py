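"""Step 5 — pairwise distances, average-neighbor clustering, OTU tables.

Distances are computed over the blunt alignment columns with gap-run
compression: a contiguous run of gaps in one sequence aligned to bases in
the other counts as a single difference (one indel event), while every
substitution counts one. Clustering is agglomerative average linkage
(UPGMA merge criterion weighted by cluster member counts), merging while
the smallest inter-cluster average distance stays at or below the cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import RANKS, UNCLASSIFIED, TaxonomicAssignment
from .screenalign import AlignedSequence

DEFAULT_OTU_CUTOFF = 0.03
DEFAULT_CONSENSUS_CUTOFF = 51.0


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if self.d.min() < 0 or self.d.max() > 1:
            raise ValueError("distances must lie in [0, 1]")

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{x:.6f}" for x in self.d[i])
                fh.write(f"{name}\t{row}\n")


@dataclass
class OTU:
    otu_id: str
    members: dict[str, int]  # seq_id -> total count
    representative_id: str
    consensus_lineage: dict[str, tuple[str, float]] | None = None

    @property
    def total_count(self) -> int:
        return sum(self.members.values())


@dataclass
class OTUTable:
    counts: pd.DataFrame  # rows = OTU ids, columns = sample ids
    lineages: dict[str, dict[str, tuple[str, float]]]
    is_empty: bool = False

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        df = self.counts.copy()
        df["lineage"] = [
            ";".join(self.lineages.get(o, {}).get(r, (UNCLASSIFIED, 0.0))[0] for r in RANKS)
            for o in df.index
        ]
        df.to_csv(path, sep="\t", index_label="otu_id")


def _gap_runs(row: np.ndarray) -> np.ndarray:
    """Label contiguous gap runs; 0 for bases, run number for gap columns."""
    gap = row == ord("-")
    starts = gap & ~np.concatenate(([False], gap[:-1]))
    return np.where(gap, np.cumsum(starts), 0)


def pairwise_distance(a: AlignedSequence | str, b: AlignedSequence | str) -> float:
    """Run-compressed distance over the shared blunt columns."""
    sa = a.gapped if isinstance(a, AlignedSequence) else a
    sb = b.gapped if isinstance(b, AlignedSequence) else b
    if len(sa) != len(sb):
        raise ValueError("aligned length mismatch")
    ra = np.frombuffer(sa.upper().replace(".", "-").encode(), dtype=np.uint8)
    rb = np.frombuffer(sb.upper().replace(".", "-").encode(), dtype=np.uint8)
    gap_a = ra == ord("-")
    gap_b = rb == ord("-")
    both = gap_a & gap_b
    compared = int((~both).sum())
    if compared == 0:
        return 0.0
    subs = int(((ra != rb) & ~gap_a & ~gap_b).sum())
    # one difference per maximal run of gap-vs-base columns
    runs_a = _gap_runs(ra)
    runs_b = _gap_runs(rb)
    indel_events = len(set(runs_a[(gap_a & ~gap_b)])) + len(set(runs_b[(gap_b & ~gap_a)]))
    return (subs + indel_events) / compared


def distance_matrix(aligned: list[AlignedSequence]) -> DistanceMatrix:
    n = len(aligned)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(aligned[i], aligned[j])
    return DistanceMatrix([a.unique.seq_id for a in aligned], d)


def cluster_average_neighbor(
    dm: DistanceMatrix,
    cutoff: float = DEFAULT_OTU_CUTOFF,
    counts: dict[str, int] | None = None,
) -> list[list[str]]:
    """Average-linkage agglomeration up to the distance cutoff.

    Returns the partition as lists of seq_ids. ``counts`` (read counts per
    sequence) only affects output ordering, not the linkage, which weights
    clusters by their number of member sequences (standard UPGMA).
    """
    if cutoff < 0.005 and cutoff > 0:
        warnings.warn(
            f"cutoff {cutoff} is unusually small; the conventional OTU "
            "threshold is a fractional distance (e.g. 0.03 for 97% identity)",
            stacklevel=2,
        )
    n = len(dm.ids)
    clusters: list[list[int]] = [[i] for i in range(n)]
    labels: list[str] = list(dm.ids)  # lexicographic tie-break labels
    avg = dm.d.astype(float).copy()
    sizes = np.ones(n)
    active = list(range(n))
    while len(active) > 1:
        best: tuple[float, str, str, int, int] | None = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                la, lb = sorted((labels[i], labels[j]))
                key = (avg[i, j], la, lb)
                if best is None or key < best[:3]:
                    best = (avg[i, j], la, lb, i, j)
        if best is None or best[0] > cutoff:
            break
        _, _, _, i, j = best
        # weighted average linkage update
        wi, wj = sizes[i], sizes[j]
        for kk in active:
            if kk in (i, j):
                continue
            avg[i, kk] = avg[kk, i] = (wi * avg[i, kk] + wj * avg[j, kk]) / (wi + wj)
        clusters[i] = clusters[i] + clusters[j]
        labels[i] = min(labels[i], labels[j])
        sizes[i] = wi + wj
        active.remove(j)
    parts = [sorted(dm.ids[m] for m in clusters[i]) for i in active]
    if counts:
        parts.sort(key=lambda p: (-sum(counts.get(s, 0) for s in p), p))
    else:
        parts.sort(key=lambda p: p)
    return parts


def make_otus(
    partition: list[list[str]], counts: dict[str, int]
) -> list[OTU]:
    otus = []
    for k, members in enumerate(partition, start=1):
        mem = {s: counts.get(s, 0) for s in members}
        rep = min(mem, key=lambda s: (-mem[s], s))
        otus.append(OTU(f"OTU{k:04d}", mem, rep))
    return otus


def consensus_taxonomy(
    otu: OTU,
    assignments: dict[str, TaxonomicAssignment],
    cutoff: float = DEFAULT_CONSENSUS_CUTOFF,
) -> dict[str, tuple[str, float]]:
    """Abundance-weighted per-rank vote over member assignments.

    The winning label is kept iff its share (in percent) reaches the cutoff;
    below that the rank and everything beneath it become "unclassified".
    """
    total = otu.total_count
    lineage: dict[str, tuple[str, float]] = {}
    parent_ok = True
    for rank in RANKS:
        votes: dict[str, int] = {}
        for sid, cnt in otu.members.items():
            votes[assignments[sid].label(rank)] = (
                votes.get(assignments[sid].label(rank), 0) + cnt
            )
        label, top = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        share = 100.0 * top / total
        if parent_ok and share >= cutoff and label != UNCLASSIFIED:
            lineage[rank] = (label, share)
        else:
            lineage[rank] = (UNCLASSIFIED, share)
            parent_ok = False
    return lineage


def build_otu_table(
    otus: list[OTU], per_sample_counts: dict[str, dict[str, int]]
) -> OTUTable:
    """Samples x OTUs count table; ``per_sample_counts`` maps seq_id to its
    per-sample counts."""
    if not otus:
        return OTUTable(pd.DataFrame(), {}, is_empty=True)
    samples = sorted({s for c in per_sample_counts.values() for s in c})
    data = np.zeros((len(otus), len(samples)), dtype=np.int64)
    sidx = {s: j for j, s in enumerate(samples)}
    for i, otu in enumerate(otus):
        for sid in otu.members:
            for s, c in per_sample_counts.get(sid, {}).items():
                data[i, sidx[s]] += c
    df = pd.DataFrame(data, index=[o.otu_id for o in otus], columns=samples)
    lineages = {
        o.otu_id: o.consensus_lineage for o in otus if o.consensus_lineage is not None
    }
    return OTUTable(df, lineages)
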