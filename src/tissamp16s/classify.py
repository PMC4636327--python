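"""Step 4 — naive-Bayes k-mer taxonomic classification with bootstrap.

The classifier follows the word-matching naive Bayes scheme standard for
16S reads: each genus is scored by the sum of log conditional probabilities
of the query's distinct 8-mers, with word priors shared across genera.
Confidence at each rank is the percentage of bootstrap replicates (resampling
one eighth of the distinct words, with replacement) whose winning genus
agrees with the full-word winner's lineage at that rank; ranks below the
cutoff are reported as "unclassified".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
DEFAULT_K = 8
DEFAULT_BOOTSTRAPS = 100
DEFAULT_CUTOFF = 80.0
UNCLASSIFIED = "unclassified"


@dataclass
class TaxonomyReference:
    """Training records: (seq_id, ungapped sequence, 6-rank lineage)."""

    records: list[tuple[str, str, tuple[str, ...]]]

    def __post_init__(self):
        for sid, seq, lineage in self.records:
            if len(lineage) != len(RANKS) or any(not r for r in lineage):
                raise ValueError(f"{sid}: lineage must have 6 non-empty ranks")
        if len({lin[-1] for _, _, lin in self.records}) < 2:
            raise ValueError("at least 2 genera are required for training")

    @classmethod
    def from_files(cls, fasta: str | Path, taxonomy: str | Path) -> "TaxonomyReference":
        from Bio import SeqIO

        lineages: dict[str, tuple[str, ...]] = {}
        for line in Path(taxonomy).read_text().splitlines():
            if not line.strip():
                continue
            sid, lin = line.split("\t")
            lineages[sid] = tuple(r for r in lin.strip().strip(";").split(";"))
        recs = [
            (r.id, str(r.seq).upper().replace("-", "").replace(".", ""), lineages[r.id])
            for r in SeqIO.parse(str(fasta), "fasta")
        ]
        return cls(recs)


@dataclass
class WordModel:
    k: int
    word_index: dict[str, int]
    log_conditional: np.ndarray  # (n_genera, n_words)
    log_unseen: np.ndarray  # (n_genera,) score of a word absent from training
    genus_list: list[str]
    genus_lineage: dict[str, tuple[str, ...]]


def _words(seq: str, k: int) -> set[str]:
    seq = seq.upper()
    return {seq[i : i + k] for i in range(len(seq) - k + 1) if "N" not in seq[i : i + k]}


def train(ref: TaxonomyReference, k: int = DEFAULT_K) -> WordModel:
    """Fit word priors and per-genus conditionals.

    prior(w) = (n_w + 0.5) / (N + 1) over all N training sequences;
    conditional(g, w) = (m_w + prior(w)) / (M_g + 1) over the M_g sequences
    of genus g. Words are taken from the given strand only (orientation is
    handled upstream by the aligner).
    """
    word_sets = [_words(seq, k) for _, seq, _ in ref.records]
    genus_of = [lin[-1] for _, _, lin in ref.records]
    genus_list = sorted(set(genus_of))
    genus_lineage: dict[str, tuple[str, ...]] = {}
    for _, _, lin in ref.records:
        g = lin[-1]
        if g in genus_lineage and genus_lineage[g] != lin:
            raise ValueError(f"genus {g} has inconsistent lineages")
        genus_lineage[g] = lin

    all_words = sorted(set().union(*word_sets))
    word_index = {w: i for i, w in enumerate(all_words)}
    N = len(ref.records)
    n_w = np.zeros(len(all_words))
    for ws in word_sets:
        for w in ws:
            n_w[word_index[w]] += 1
    prior = (n_w + 0.5) / (N + 1)

    G = len(genus_list)
    gidx = {g: i for i, g in enumerate(genus_list)}
    m = np.zeros((G, len(all_words)))
    M = np.zeros(G)
    for ws, g in zip(word_sets, genus_of):
        gi = gidx[g]
        M[gi] += 1
        for w in ws:
            m[gi, word_index[w]] += 1
    cond = (m + prior[None, :]) / (M[:, None] + 1)
    unseen = (0.5 / (N + 1)) / (M + 1)
    return WordModel(
        k, word_index, np.log(cond), np.log(unseen), genus_list, genus_lineage
    )


def word_prior(ref: TaxonomyReference, word: str, k: int = DEFAULT_K) -> float:
    """Standalone prior of one word, for inspection/diagnostics."""
    n = sum(1 for _, seq, _ in ref.records if word in _words(seq, k))
    return (n + 0.5) / (len(ref.records) + 1)


@dataclass
class TaxonomicAssignment:
    seq_id: str
    ranks: dict[str, tuple[str, float]]  # rank -> (label, confidence %)
    assigned_genus_raw: str

    def label(self, rank: str) -> str:
        return self.ranks[rank][0]

    def confidence(self, rank: str) -> float:
        return self.ranks[rank][1]

    def format_mothur(self) -> str:
        return ";".join(
            f"{lab}({conf:.0f})" for lab, conf in (self.ranks[r] for r in RANKS)
        )

    @classmethod
    def parse_mothur(cls, seq_id: str, text: str) -> "TaxonomicAssignment":
        """Parse the ``label(87);...`` six-rank notation."""
        parts = text.strip().strip(";").split(";")
        if len(parts) != len(RANKS):
            raise ValueError(f"expected {len(RANKS)} ranks, got {len(parts)}")
        ranks = {}
        for rank, token in zip(RANKS, parts):
            if "(" in token:
                lab, conf = token.rsplit("(", 1)
                ranks[rank] = (lab, float(conf.rstrip(")")))
            else:
                ranks[rank] = (token, 0.0)
        return cls(seq_id, ranks, ranks["genus"][0])


def classify_sequence(
    seq: str,
    model: WordModel,
    seq_id: str = "",
    bootstraps: int = DEFAULT_BOOTSTRAPS,
    cutoff: float = DEFAULT_CUTOFF,
    rng: np.random.Generator | int | None = 0,
) -> TaxonomicAssignment:
    """Assign a lineage with per-rank bootstrap confidences."""
    if len(seq) < model.k:
        raise ValueError(f"sequence shorter than word size {model.k}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    words = sorted(_words(seq, model.k))
    W = len(words)
    if W == 0:
        raise ValueError("no valid words in sequence")
    # per-word genus score columns, unseen words collapse to a constant column
    cols = np.empty((len(model.genus_list), W))
    for j, w in enumerate(words):
        wi = model.word_index.get(w)
        cols[:, j] = model.log_conditional[:, wi] if wi is not None else model.log_unseen
    full_scores = cols.sum(axis=1)
    best = int(full_scores.argmax())  # genus_list is sorted: ties lexicographic
    # argmax returns the first (lexicographically smallest) maximal genus
    sub = max(W // 8, 1)
    draws = rng.integers(0, W, size=(bootstraps, sub))
    winners = np.empty(bootstraps, dtype=np.int64)
    for b in range(bootstraps):
        winners[b] = cols[:, draws[b]].sum(axis=1).argmax()

    best_lineage = model.genus_lineage[model.genus_list[best]]
    winner_lineages = [model.genus_lineage[model.genus_list[w]] for w in winners]
    ranks: dict[str, tuple[str, float]] = {}
    parent_ok = True
    for ri, rank in enumerate(RANKS):
        agree = sum(1 for lin in winner_lineages if lin[ri] == best_lineage[ri])
        conf = 100.0 * agree / bootstraps
        if parent_ok and conf >= cutoff:
            ranks[rank] = (best_lineage[ri], conf)
        else:
            ranks[rank] = (UNCLASSIFIED, conf)
            parent_ok = False  # hierarchical consistency
    return TaxonomicAssignment(seq_id, ranks, model.genus_list[best])


def filter_non_bacteria(
    assignments: dict[str, TaxonomicAssignment], uniques: list
) -> tuple[list, int]:
    """Keep only items whose domain call is Bacteria at or above the cutoff.

    ``uniques`` may be UniqueSequence or AlignedSequence objects; matching is
    by seq_id.
    """
    kept, removed = [], 0
    for u in uniques:
        sid = u.seq_id if hasattr(u, "seq_id") else u.unique.seq_id
        a = assignments[sid]
        if a.label("domain") == "Bacteria":
            kept.append(u)
        else:
            removed += 1
    return kept, removed
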