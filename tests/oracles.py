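"""Independent brute-force oracles, written separately from the library
implementations they check. Each favors clarity over speed and uses a
different algorithmic route than the code under test."""

from __future__ import annotations

import itertools

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def hamming_loop(a: str, b: str) -> int:
    assert len(a) == len(b)
    count = 0
    for i in range(len(a)):
        if a[i] != b[i]:
            count += 1
    return count


def complement_loop(s: str) -> str:
    return "".join(_COMP[c] for c in s)


def greedy_candidate_oracle() -> list[str]:
    """Exhaustive greedy scan of all 4096 hexamers, rule by rule."""
    accepted: list[str] = []
    for combo in itertools.product("ACGT", repeat=6):
        cand = "".join(combo)
        ok = True
        for prev in accepted:
            if hamming_loop(prev, cand) < 2:
                ok = False
                break
            if cand == complement_loop(prev):
                ok = False
                break
            if cand == complement_loop(prev)[::-1]:
                ok = False
                break
        if ok:
            accepted.append(cand)
    return accepted


def pairwise_diffs(a: str, b: str) -> int:
    """Column-wise differences: any disagreement counts one, gap-gap zero."""
    n = 0
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            continue
        if x != y:
            n += 1
    return n


def precluster_oracle(seqs: list[tuple[str, str, int]], max_diffs: int = 3):
    """Single-pass abundance-ranked merging; seqs = (id, aligned, count).

    Returns (kept ids -> merged count, merge_map)."""
    order = sorted(seqs, key=lambda t: (-t[2], t[1]))
    retained: list[list] = []  # [id, aligned, count]
    merge_map = {}
    for sid, aln, cnt in order:
        target = None
        for r in retained:  # retained is already in decreasing entry order
            if pairwise_diffs(r[1], aln) <= max_diffs:
                target = r
                break
        if target is None:
            retained.append([sid, aln, cnt])
        else:
            merge_map[sid] = target[0]
            target[2] += cnt
    return {r[0]: r[2] for r in retained}, merge_map


def run_compressed_distance(a: str, b: str) -> float:
    """Column walk implementing the one-difference-per-gap-run rule."""
    diffs = 0
    compared = 0
    in_gap_a = in_gap_b = False
    for x, y in zip(a, b):
        ga, gb = x == "-", y == "-"
        if ga and gb:
            in_gap_a = in_gap_b = False
            continue
        compared += 1
        if ga:
            if not in_gap_a:
                diffs += 1
            in_gap_a, in_gap_b = True, False
        elif gb:
            if not in_gap_b:
                diffs += 1
            in_gap_b, in_gap_a = True, False
        else:
            in_gap_a = in_gap_b = False
            if x != y:
                diffs += 1
    return diffs / compared if compared else 0.0


def average_linkage_oracle(ids, d, cutoff):
    """Brute-force weighted average-linkage agglomeration: recompute every
    inter-cluster average from the original matrix each round."""
    clusters = [[i] for i in range(len(ids))]

    def avg(ca, cb):
        return float(np.mean([d[i, j] for i in ca for j in cb]))

    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                la = min(ids[i] for i in clusters[x])
                lb = min(ids[i] for i in clusters[y])
                key = (avg(clusters[x], clusters[y]), *sorted((la, lb)))
                if best is None or key < best[0]:
                    best = (key, x, y)
        if best[0][0] > cutoff:
            break
        _, x, y = best
        clusters[x] = clusters[x] + clusters[y]
        del clusters[y]
    return sorted(sorted(ids[i] for i in c) for c in clusters)


def chimera_oracle(
    query: str,
    parents: list[str],
    chunks: int = 4,
    beta: float = 8.0,
    epsilon: float = 0.5,
    score_threshold: float = 0.28,
    min_parent_diffs: int = 3,
):
    """Chunk-boundary two-parent crossover search by explicit loops.

    Returns (score, a_index, b_index, is_chimera) or None when fewer than
    two parents are available."""
    if len(parents) < 2:
        return None
    ncols = len(query)
    bounds = [round(b * ncols / chunks) for b in range(1, chunks)]
    n_par = len(parents)
    single_scores = [
        sum(1 for c in range(ncols) if parents[p][c] == query[c]) for p in range(n_par)
    ]
    best_single = max(range(n_par), key=lambda p: single_scores[p])
    best = None
    for b in bounds:
        left_scores = [
            sum(1 for c in range(b) if parents[p][c] == query[c]) for p in range(n_par)
        ]
        right_scores = [
            sum(1 for c in range(b, ncols) if parents[p][c] == query[c])
            for p in range(n_par)
        ]
        ai = max(range(n_par), key=lambda p: left_scores[p])
        bi = max(range(n_par), key=lambda p: right_scores[p])
        total = left_scores[ai] + right_scores[bi]
        if best is None or total > best[0]:
            best = (total, ai, bi, b)
    total, ai, bi, b = best
    if total <= single_scores[best_single] or ai == bi:
        return (0.0, None, None, False)
    y = n = 0
    for c in range(ncols):
        model_base = parents[ai][c] if c < b else parents[bi][c]
        model_match = model_base == query[c]
        single_match = parents[best_single][c] == query[c]
        if model_match and not single_match:
            y += 1
        if single_match and not model_match:
            n += 1
    score = y / (y + beta * n + epsilon)
    diffs_ok = (
        hamming_loop(parents[ai], query) >= min_parent_diffs
        and hamming_loop(parents[bi], query) >= min_parent_diffs
    )
    return (score, ai, bi, score >= score_threshold and diffs_ok)


def unifrac_oracle(tree, p: dict, q: dict, alpha: float) -> float:
    """Per-branch summation using explicit leaf-set computation (preorder,
    sets of tip names) rather than matrix algebra."""
    num = 0.0
    den = 0.0
    for node in tree.preorder(include_self=False):
        if node.length is None:
            continue
        tips = {t.name for t in node.tips(include_self=True)}
        pi = sum(p.get(t, 0.0) for t in tips)
        qi = sum(q.get(t, 0.0) for t in tips)
        tot = pi + qi
        if tot == 0:
            continue
        w = node.length * tot**alpha
        num += w * abs(pi - qi) / tot
        den += w
    return num / den if den else 0.0
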