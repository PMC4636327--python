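"""Steps 2-3 — sequencing-error reduction and de novo chimera removal.

Pre-clustering exploits the error structure of the MiSeq chemistry:
substitutions are rare (~0.1%/base) and land at random positions, so reads
carrying errors form low-abundance satellites within a few differences of an
abundant true sequence. A single pass over the working set in decreasing
abundance order merges each sequence into the most abundant earlier sequence
within ``max_diffs`` column differences. Surviving singletons are withdrawn.

Chimeras are screened de novo: more abundant sequences serve as the
candidate parent pool for each query (abundance skew >= 2x), and a query is
flagged when a two-parent model with a single crossover at a chunk boundary
explains its columns markedly better than any single parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .screenalign import AlignedSequence, blunt_matrix

GAP = ord("-")


@dataclass
class PreclusterResult:
    merged: list[AlignedSequence]
    merge_map: dict[str, str]
    singletons_removed: int


@dataclass
class ChimeraVerdict:
    query_id: str
    parent_a_id: str | None
    parent_b_id: str | None
    score: float
    is_chimera: bool


def _order(aligned: list[AlignedSequence]) -> list[int]:
    """Decreasing abundance, ties by aligned sequence lexicographic."""
    return sorted(
        range(len(aligned)),
        key=lambda i: (-aligned[i].unique.total_count, aligned[i].gapped),
    )


def precluster(
    aligned: list[AlignedSequence], max_diffs: int = 3, *, remove_singletons: bool = True
) -> PreclusterResult:
    """Abundance-ranked merging of near-identical sequences.

    A difference is any column where the two rows disagree; a gap aligned to
    a base counts one, gap against gap counts zero (rows are blunt so gaps
    only occur inside deletions). Merging is single-pass: ranks are fixed at
    entry and merged counts do not promote a sequence mid-pass.
    """
    if not aligned:
        return PreclusterResult([], {}, 0)
    mat, ids = blunt_matrix(aligned)
    order = _order(aligned)
    retained: list[int] = []
    merge_map: dict[str, str] = {}
    absorbed_counts: dict[int, dict[str, int]] = {}
    for i in order:
        if retained:
            rows = mat[retained]
            diffs = (rows != mat[i]).sum(axis=1)
            hits = np.flatnonzero(diffs <= max_diffs)
            if hits.size:
                # retained is in decreasing-abundance order; first hit wins
                target = retained[int(hits[0])]
                merge_map[ids[i]] = ids[target]
                tgt_counts = absorbed_counts.setdefault(target, {})
                for s, c in aligned[i].unique.per_sample_counts.items():
                    tgt_counts[s] = tgt_counts.get(s, 0) + c
                continue
        retained.append(i)

    merged: list[AlignedSequence] = []
    singletons = 0
    for i in retained:
        a = aligned[i]
        extra = absorbed_counts.get(i)
        if extra:
            u = a.unique
            new_counts = dict(u.per_sample_counts)
            for s, c in extra.items():
                new_counts[s] = new_counts.get(s, 0) + c
            a = AlignedSequence(
                type(u)(u.seq_id, u.sequence, new_counts),
                a.gapped,
                a.start_col,
                a.end_col,
                a.template_id,
                a.identity_to_template,
                a.dropped_insertions,
            )
        if remove_singletons and a.unique.total_count == 1:
            singletons += 1
            continue
        merged.append(a)
    merged.sort(key=lambda a: (-a.unique.total_count, a.gapped))
    return PreclusterResult(merged, merge_map, singletons)


def screen_chimeras(
    aligned: list[AlignedSequence],
    chunks: int = 4,
    skew: float = 2.0,
    score_threshold: float = 0.28,
    *,
    beta: float = 8.0,
    epsilon: float = 0.5,
    min_parent_diffs: int = 3,
) -> list[ChimeraVerdict]:
    """Chunked two-parent crossover screen, processed in increasing abundance.

    For each query the candidate parents are the retained (not yet flagged)
    sequences with abundance >= skew x the query's. The query is cut into
    ``chunks`` equal column blocks; the two-parent model picks the best left
    parent and best right parent over every block-boundary crossover. If the
    model matches strictly more columns than the best single parent, the
    score (Y / (Y + beta*N + epsilon), with Y = columns only the model
    explains and N = columns only the single parent explains) decides, and
    flagged queries never serve as parents.
    """
    if not aligned:
        return []
    mat, ids = blunt_matrix(aligned)
    counts = np.array([a.unique.total_count for a in aligned])
    ncols = mat.shape[1]
    bounds = [round(b * ncols / chunks) for b in range(1, chunks)]
    # increasing abundance; ties by sequence for determinism
    order = sorted(range(len(aligned)), key=lambda i: (counts[i], aligned[i].gapped))
    flagged: set[int] = set()
    verdicts_by_idx: dict[int, ChimeraVerdict] = {}
    for qi in order:
        cand = [
            j
            for j in range(len(aligned))
            if j != qi and j not in flagged and counts[j] >= skew * counts[qi]
        ]
        if len(cand) < 2:
            verdicts_by_idx[qi] = ChimeraVerdict(ids[qi], None, None, 0.0, False)
            continue
        q = mat[qi]
        P = mat[cand]
        match = P == q  # (n_cand, ncols)
        totals = match.sum(axis=1)
        best_single = int(totals.argmax())
        single_cols = match[best_single]
        cum = np.cumsum(match, axis=1)
        best_model = None  # (model_cols, a_idx, b_idx)
        for b in bounds:
            left = cum[:, b - 1]
            right = totals - left
            ai = int(left.argmax())
            bi = int(right.argmax())
            model_cols = np.concatenate([match[ai, :b], match[bi, b:]])
            n_model = int(model_cols.sum())
            if best_model is None or n_model > best_model[0]:
                best_model = (n_model, ai, bi, model_cols)
        n_model, ai, bi, model_cols = best_model
        if n_model <= totals[best_single] or ai == bi:
            verdicts_by_idx[qi] = ChimeraVerdict(ids[qi], None, None, 0.0, False)
            continue
        y = int((model_cols & ~single_cols).sum())
        n = int((single_cols & ~model_cols).sum())
        score = y / (y + beta * n + epsilon)
        pa, pb = cand[ai], cand[bi]
        diffs_ok = (
            int((mat[pa] != q).sum()) >= min_parent_diffs
            and int((mat[pb] != q).sum()) >= min_parent_diffs
        )
        is_chim = score >= score_threshold and diffs_ok
        if is_chim:
            flagged.add(qi)
        verdicts_by_idx[qi] = ChimeraVerdict(ids[qi], ids[pa], ids[pb], score, is_chim)
    return [verdicts_by_idx[i] for i in range(len(aligned))]


def apply_verdicts(
    aligned: list[AlignedSequence], verdicts: list[ChimeraVerdict]
) -> tuple[list[AlignedSequence], list[AlignedSequence]]:
    """Split the working set into (kept, removed-as-chimera)."""
    flagged = {v.query_id for v in verdicts if v.is_chimera}
    kept = [a for a in aligned if a.unique.seq_id not in flagged]
    removed = [a for a in aligned if a.unique.seq_id in flagged]
    return kept, removed
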