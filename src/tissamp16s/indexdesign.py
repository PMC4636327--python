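"""Design of 6-base multiplex indexes for single-index MiSeq runs.

Two-step procedure: (1) exhaustive greedy generation of hexamer candidates
under pairwise rules — every accepted pair differs at >= 2 positions and no
accepted index is the complement or reverse complement of another; (2)
selection of a fixed-size panel whose per-position base composition is close
to uniform and whose A/C (red laser) vs G/T (green laser) channel split is
close to 50/50 at every cycle, so the instrument's colour calibration stays
valid for the index read.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._seq import complement, hamming, reverse_complement, validate_dna

INDEX_LENGTH = 6
BASES = "ACGT"
DEFAULT_PANEL_SIZE = 320
DEFAULT_BALANCE_TOL = 0.15

# subset sizes up to this are solved by exact enumeration instead of swaps
_EXACT_ENUMERATION_LIMIT = 5000


class InfeasiblePanelError(ValueError):
    """Requested panel size cannot be met; carries the achievable size."""

    def __init__(self, requested: int, achievable: int):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"panel of {requested} indexes is infeasible; "
            f"largest achievable size is {achievable}"
        )


@dataclass(frozen=True)
class MultiplexIndex:
    """A 6-mer sample index over {A,C,G,T}."""

    sequence: str

    def __post_init__(self):
        s = validate_dna(self.sequence)
        if len(s) != INDEX_LENGTH:
            raise ValueError(f"index length must be {INDEX_LENGTH}, got {len(s)}")
        object.__setattr__(self, "sequence", s)


@dataclass
class IndexPanel:
    """A selected set of multiplex indexes with composition diagnostics.

    ``per_position_base_fraction`` is a (6, 4) array over A/C/G/T;
    ``channel_balance`` is the per-position fraction of A-or-C bases.
    """

    indexes: list[MultiplexIndex]
    per_position_base_fraction: np.ndarray = field(init=False)
    channel_balance: np.ndarray = field(init=False)

    def __post_init__(self):
        self.per_position_base_fraction = _base_fractions(
            [ix.sequence for ix in self.indexes]
        )
        # A and C are read on the same excitation channel
        self.channel_balance = self.per_position_base_fraction[:, :2].sum(axis=1)

    def __len__(self) -> int:
        return len(self.indexes)

    def objective(self) -> float:
        return balance_objective(self.per_position_base_fraction)

    def validate(self, *, balance_tol: float | None = DEFAULT_BALANCE_TOL) -> None:
        """Raise if any pairwise or composition invariant is violated.

        Pass ``balance_tol=None`` to skip the composition band (tiny panels
        cannot meaningfully satisfy it).
        """
        seqs = [ix.sequence for ix in self.indexes]
        for a, b in itertools.combinations(seqs, 2):
            if not is_compatible_pair(a, b):
                raise ValueError(f"incompatible index pair: {a} / {b}")
        rowsums = self.per_position_base_fraction.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-12):
            raise ValueError("base fractions do not sum to 1")
        if balance_tol is not None:
            dev = np.abs(self.channel_balance - 0.5)
            if np.any(dev > balance_tol):
                raise ValueError(
                    f"channel balance outside +/-{balance_tol} band: "
                    f"{self.channel_balance}"
                )


def _base_fractions(seqs: list[str]) -> np.ndarray:
    frac = np.zeros((INDEX_LENGTH, 4), dtype=float)
    if not seqs:
        return frac
    for s in seqs:
        for pos, base in enumerate(s):
            frac[pos, BASES.index(base)] += 1
    return frac / len(seqs)


def balance_objective(fractions: np.ndarray) -> float:
    """Sum over positions of |A/C channel fraction - 0.5| plus the squared
    deviation of each base fraction from 0.25. Lower is better-balanced."""
    channel = fractions[:, :2].sum(axis=1)
    return float(
        np.abs(channel - 0.5).sum() + ((fractions - 0.25) ** 2).sum()
    )


def is_compatible_pair(a: str | MultiplexIndex, b: str | MultiplexIndex) -> bool:
    """True iff the pair satisfies all three candidate rules: Hamming
    distance >= 2, b is not the complement of a, and b is not the reverse
    complement of a."""
    sa = a.sequence if isinstance(a, MultiplexIndex) else validate_dna(a)
    sb = b.sequence if isinstance(b, MultiplexIndex) else validate_dna(b)
    if hamming(sa, sb) < 2:
        return False
    if sb == complement(sa) or sb == reverse_complement(sa):
        return False
    return True


def generate_candidates() -> list[MultiplexIndex]:
    """Greedy scan of all 4^6 hexamers in lexicographic order; a hexamer is
    accepted iff it is compatible with every previously accepted one.
    Deterministic; output order is acceptance order."""
    accepted: list[str] = []
    for combo in itertools.product(BASES, repeat=INDEX_LENGTH):
        cand = "".join(combo)
        if all(is_compatible_pair(prev, cand) for prev in accepted):
            accepted.append(cand)
    return [MultiplexIndex(s) for s in accepted]


def _compat_matrix(seqs: list[str]) -> np.ndarray:
    n = len(seqs)
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, INDEX_LENGTH)
    dist = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    comp = np.array(
        [
            np.frombuffer(complement(s).encode(), dtype=np.uint8)
            for s in seqs
        ]
    )
    rc = np.array(
        [
            np.frombuffer(reverse_complement(s).encode(), dtype=np.uint8)
            for s in seqs
        ]
    )
    is_comp = (arr[:, None, :] == comp[None, :, :]).all(axis=2)
    is_rc = (arr[:, None, :] == rc[None, :, :]).all(axis=2)
    ok = (dist >= 2) & ~is_comp & ~is_rc
    np.fill_diagonal(ok, False)
    return ok


def _counts_objective(counts: np.ndarray, n: int) -> float:
    frac = counts / n
    channel = frac[:, :2].sum(axis=1)
    return float(np.abs(channel - 0.5).sum() + ((frac - 0.25) ** 2).sum())


def _base_count_rows(seqs: list[str]) -> np.ndarray:
    """Per-index one-hot (6,4) count contribution, stacked as (n,6,4)."""
    n = len(seqs)
    out = np.zeros((n, INDEX_LENGTH, 4), dtype=np.int64)
    for i, s in enumerate(seqs):
        for pos, base in enumerate(s):
            out[i, pos, BASES.index(base)] = 1
    return out


def select_panel(
    candidates: list[MultiplexIndex],
    panel_size: int = DEFAULT_PANEL_SIZE,
    *,
    check_balance: bool = True,
    balance_tol: float = DEFAULT_BALANCE_TOL,
    max_passes: int = 200,
) -> IndexPanel:
    """Select ``panel_size`` mutually compatible indexes minimizing the
    balance objective.

    Small instances (C(n, k) <= 5000 subsets) are solved by exact
    enumeration; larger ones by a deterministic greedy seed followed by
    best-improving swap refinement (ties broken toward the lexicographically
    smallest incoming index).
    """
    if panel_size < 1:
        raise ValueError("panel_size must be >= 1")
    seqs = [ix.sequence for ix in candidates]
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate candidate indexes")
    n = len(seqs)
    if panel_size > n:
        raise InfeasiblePanelError(panel_size, n)

    compat = _compat_matrix(seqs)
    onehot = _base_count_rows(seqs)

    # greedy feasible seed in candidate order
    seed: list[int] = []
    for i in range(n):
        if all(compat[i, j] for j in seed):
            seed.append(i)
    if len(seed) < panel_size:
        raise InfeasiblePanelError(panel_size, len(seed))

    from math import comb

    if comb(n, panel_size) <= _EXACT_ENUMERATION_LIMIT:
        best: tuple[float, tuple[int, ...]] | None = None
        for subset in itertools.combinations(range(n), panel_size):
            idx = list(subset)
            if not np.all(compat[np.ix_(idx, idx)] | np.eye(len(idx), dtype=bool)):
                continue
            obj = _counts_objective(onehot[idx].sum(axis=0), panel_size)
            key = (obj, tuple(seqs[i] for i in idx))
            if best is None or key < best:
                best = key
                chosen = idx
        if best is None:
            raise InfeasiblePanelError(panel_size, len(seed))
        panel_idx = chosen
    else:
        lex_order = np.array(sorted(range(n), key=lambda i: seqs[i]))

        def _objective_vector(base_counts: np.ndarray) -> np.ndarray:
            """Objective of base_counts + each candidate's one-hot, for all n."""
            frac = (base_counts[None, :, :] + onehot) / panel_size
            channel = frac[:, :, :2].sum(axis=2)
            return np.abs(channel - 0.5).sum(axis=1) + (
                (frac - 0.25) ** 2
            ).sum(axis=(1, 2))

        # balance-aware greedy seed: add the candidate that keeps the running
        # composition closest to uniform, subject to pairwise feasibility
        members: list[int] = []
        member_mask = np.zeros(n, dtype=bool)
        feasible = np.ones(n, dtype=bool)
        counts = np.zeros((INDEX_LENGTH, 4), dtype=np.int64)
        for _ in range(panel_size):
            objs = _objective_vector(counts)
            objs[~feasible | member_mask] = np.inf
            # tie-break toward the lexicographically smallest sequence
            pick = int(lex_order[np.argmin(objs[lex_order])])
            if not np.isfinite(objs[pick]):
                raise InfeasiblePanelError(panel_size, len(members))
            members.append(pick)
            member_mask[pick] = True
            feasible &= compat[pick]
            counts += onehot[pick]

        # first-improvement swap passes: for each member in turn, replace it
        # with the best strictly-improving compatible outsider
        for _ in range(max_passes):
            improved = False
            for slot in range(panel_size):
                out_i = members[slot]
                others = [m for m in members if m != out_i]
                base_counts = counts - onehot[out_i]
                feas = compat[:, others].all(axis=1)
                feas[np.array(others)] = False
                objs = _objective_vector(base_counts)
                cur_obj = objs[out_i]
                objs[~feas] = np.inf
                pick = int(lex_order[np.argmin(objs[lex_order])])
                if objs[pick] < cur_obj - 1e-15:
                    members[slot] = pick
                    counts = base_counts + onehot[pick]
                    improved = True
            if not improved:
                break
        panel_idx = members

    chosen_seqs = sorted(seqs[i] for i in panel_idx)
    panel = IndexPanel([MultiplexIndex(s) for s in chosen_seqs])
    panel.validate(balance_tol=balance_tol if check_balance else None)
    return panel
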