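"""Step 1 — dereplication, template-based alignment, culling, blunt trimming.

Each unique sequence is recruited to the reference template sharing the most
8-mers, globally aligned to that template's ungapped sequence, and projected
into the reference column space (insertions relative to the template are
dropped, NAST-style). Sequences that fail an identity or coverage floor are
treated as non-specific amplification and culled. Finally all survivors are
truncated to the common covered column interval so downstream clustering
compares homologous positions only.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import Align, SeqIO

from .readprep import JoinedSequence

GAP_CHARS = frozenset("-.")

DEFAULT_MIN_IDENTITY = 0.60
DEFAULT_MIN_COVERAGE = 0.50
# substitution-only fast path: same-length query at or above this identity
# is projected by the identity map without dynamic programming
_FAST_PATH_IDENTITY = 0.90


@dataclass
class UniqueSequence:
    """A dereplicated sequence with its total and per-sample counts."""

    seq_id: str
    sequence: str
    per_sample_counts: dict[str, int]
    total_count: int = field(init=False)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        self.total_count = sum(self.per_sample_counts.values())
        if self.total_count <= 0:
            raise ValueError("total count must be positive")


@dataclass
class ReferenceAlignment:
    """A gapped multiple alignment of reference 16S templates."""

    templates: list[tuple[str, str]]
    column_count: int = field(init=False)

    def __post_init__(self):
        if not self.templates:
            raise ValueError("empty reference alignment")
        lengths = {len(s) for _, s in self.templates}
        if len(lengths) != 1:
            raise ValueError("reference sequences have differing column counts")
        self.column_count = lengths.pop()

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceAlignment":
        recs = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
        return cls(recs)


@dataclass
class AlignedSequence:
    """A unique sequence projected into reference alignment columns."""

    unique: UniqueSequence
    gapped: str
    start_col: int  # 1-based inclusive
    end_col: int
    template_id: str
    identity_to_template: float
    dropped_insertions: int = 0

    def ungapped_span(self) -> str:
        return "".join(
            c for c in self.gapped[self.start_col - 1 : self.end_col] if c not in GAP_CHARS
        )


@dataclass
class NonAlignable:
    unique: UniqueSequence
    reason: str
    identity: float = 0.0


def dereplicate(joined: Iterable[JoinedSequence]) -> list[UniqueSequence]:
    """Collapse identical (case-folded) sequences into counted uniques.

    Output is sorted by total count descending, ties by sequence.
    """
    counts: dict[str, Counter] = defaultdict(Counter)
    for js in joined:
        counts[js.sequence.upper()][js.sample_id] += 1
    uniques = [
        UniqueSequence(f"U{i}", seq, dict(counts[seq]))
        for i, seq in enumerate(counts)
    ]
    uniques.sort(key=lambda u: (-u.total_count, u.sequence))
    for i, u in enumerate(uniques):
        u.seq_id = f"U{i+1}"
    return uniques


class _TemplateIndex:
    """k-mer recruitment index plus per-template column bookkeeping."""

    def __init__(self, ref: ReferenceAlignment, k: int = 8):
        self.k = k
        self.ref = ref
        self.ungapped: list[str] = []
        self.col_of_base: list[np.ndarray] = []  # ungapped position -> 0-based column
        self.kmer_map: dict[str, list[int]] = defaultdict(list)
        for ti, (tid, gapped) in enumerate(ref.templates):
            cols = [i for i, c in enumerate(gapped) if c not in GAP_CHARS]
            seq = "".join(gapped[i] for i in cols)
            self.ungapped.append(seq)
            self.col_of_base.append(np.array(cols, dtype=np.int64))
            for j in range(len(seq) - k + 1):
                self.kmer_map[seq[j : j + k]].append(ti)

    def best_template(self, seq: str) -> int:
        """Template index sharing the most distinct k-mers with seq;
        ties go to the lexicographically smallest template id."""
        scores = np.zeros(len(self.ungapped), dtype=np.int64)
        seen = set()
        for j in range(len(seq) - self.k + 1):
            w = seq[j : j + self.k]
            if w in seen:
                continue
            seen.add(w)
            for ti in set(self.kmer_map.get(w, ())):
                scores[ti] += 1
        best = scores.max()
        tied = [i for i in np.flatnonzero(scores == best)]
        return min(tied, key=lambda i: self.ref.templates[i][0])


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    # free end gaps: partial-span queries pay nothing for overhangs
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aligner.end_gap_score = 0
    return aligner


def align_to_reference(
    u: UniqueSequence,
    ref: ReferenceAlignment | _TemplateIndex,
    k: int = 8,
    *,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> AlignedSequence | NonAlignable:
    """Align one unique sequence into reference columns or rule it out."""
    index = ref if isinstance(ref, _TemplateIndex) else _TemplateIndex(ref, k)
    seq = u.sequence.upper()
    ti = index.best_template(seq)
    tid, gapped_t = index.ref.templates[ti]
    tseq = index.ungapped[ti]
    cols = index.col_of_base[ti]

    pairs: list[tuple[int, int]]  # (template ungapped pos, query pos) matches
    dropped = 0
    if len(seq) == len(tseq):
        arr_q = np.frombuffer(seq.encode(), dtype=np.uint8)
        arr_t = np.frombuffer(tseq.encode(), dtype=np.uint8)
        ident = float((arr_q == arr_t).mean())
        if ident >= _FAST_PATH_IDENTITY:
            return _project_identity(u, index, ti, ident)
    pairs, dropped = _dp_align(seq, tseq)
    if not pairs:
        return NonAlignable(u, "no-alignment")
    matched = sum(1 for tp, qp in pairs if tseq[tp] == seq[qp])
    # identity over alignment columns, internal gaps included: the number of
    # aligned pairs plus every in-span base of either sequence left unpaired
    qspan = pairs[-1][1] - pairs[0][1] + 1
    tspan = pairs[-1][0] - pairs[0][0] + 1
    columns = len(pairs) + (qspan - len(pairs)) + (tspan - len(pairs))
    identity = matched / columns
    coverage = len(pairs) / len(seq)
    if identity < min_identity or coverage < min_coverage:
        return NonAlignable(u, "low-identity", identity)
    start_col = int(cols[pairs[0][0]])
    end_col = int(cols[pairs[-1][0]])
    out = ["-"] * index.ref.column_count
    for tp, qp in pairs:
        out[cols[tp]] = seq[qp]
    return AlignedSequence(
        u, "".join(out), start_col + 1, end_col + 1, tid, identity, dropped
    )


def _project_identity(
    u: UniqueSequence, index: _TemplateIndex, ti: int, identity: float
) -> AlignedSequence:
    tid, _ = index.ref.templates[ti]
    cols = index.col_of_base[ti]
    out = ["-"] * index.ref.column_count
    for pos, col in enumerate(cols):
        out[col] = u.sequence[pos].upper()
    return AlignedSequence(
        u, "".join(out), int(cols[0]) + 1, int(cols[-1]) + 1, tid, identity, 0
    )


def _dp_align(query: str, template: str) -> tuple[list[tuple[int, int]], int]:
    """Global alignment; returns aligned (template_pos, query_pos) pairs and
    the count of query bases inserted relative to the template (dropped)."""
    aligner = _make_aligner()
    try:
        aln = next(iter(aligner.align(template, query)))
    except StopIteration:
        return [], 0
    pairs: list[tuple[int, int]] = []
    covered_q = 0
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        for off in range(te - ts):
            pairs.append((ts + off, qs + off))
        covered_q += qe - qs
    if not pairs:
        return [], 0
    qfirst, qlast = pairs[0][1], pairs[-1][1]
    dropped = (qlast - qfirst + 1) - covered_q
    return pairs, max(dropped, 0)


def cull_nonspecific(
    results: Iterable[AlignedSequence | NonAlignable],
) -> tuple[list[AlignedSequence], int]:
    kept = [r for r in results if isinstance(r, AlignedSequence)]
    culled = sum(1 for r in results if isinstance(r, NonAlignable))
    return kept, culled


def trim_blunt(kept: list[AlignedSequence]) -> tuple[list[AlignedSequence], int]:
    """Truncate every sequence to the common covered column interval.

    Sequences not spanning the common interval are removed; the removed
    count is returned alongside.
    """
    if not kept:
        raise ValueError("nothing to trim")
    L = max(a.start_col for a in kept)
    R = min(a.end_col for a in kept)
    if R < L:
        raise ValueError("aligned sequences share no common column span")
    out: list[AlignedSequence] = []
    removed = 0
    width = len(kept[0].gapped)
    for a in kept:
        if a.start_col > L or a.end_col < R:
            removed += 1
            continue
        gapped = "-" * (L - 1) + a.gapped[L - 1 : R] + "-" * (width - R)
        out.append(
            AlignedSequence(
                a.unique,
                gapped,
                L,
                R,
                a.template_id,
                a.identity_to_template,
                a.dropped_insertions,
            )
        )
    return out, removed


def blunt_matrix(aligned: list[AlignedSequence]) -> tuple[np.ndarray, list[str]]:
    """Byte matrix of the shared blunt span (rows follow input order).

    All inputs must share identical start/end columns (i.e. be blunt)."""
    spans = {(a.start_col, a.end_col) for a in aligned}
    if len(spans) != 1:
        raise ValueError("sequences are not blunt (differing spans)")
    (L, R) = spans.pop()
    rows = [a.gapped[L - 1 : R].replace(".", "-") for a in aligned]
    mat = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(
        len(rows), R - L + 1
    )
    return mat.copy(), [a.unique.seq_id for a in aligned]
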