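"""FASTQ ingestion, zero-mismatch demultiplexing, and read-pair joining.

Joining slides the reverse-complemented mate 2 along mate 1 over a bounded
range of overlap lengths and keeps the overlap with the lowest mismatch
density (ties go to the longer overlap). No quality-score-based pre-trimming
is ever applied; quality enters only to arbitrate disagreeing bases inside
the accepted overlap.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from ._seq import encode, reverse_complement


@dataclass
class ReadPair:
    read_id: str
    r1_seq: str
    r2_seq: str
    r1_qual: list[int] | None = None
    r2_qual: list[int] | None = None
    index_seq: str | None = None

    def __post_init__(self):
        if self.r1_qual is not None and len(self.r1_qual) != len(self.r1_seq):
            raise ValueError("r1 quality length mismatch")
        if self.r2_qual is not None and len(self.r2_qual) != len(self.r2_seq):
            raise ValueError("r2 quality length mismatch")


@dataclass
class JoinedSequence:
    seq_id: str
    sequence: str
    sample_id: str
    overlap_length: int
    overlap_mismatches: int


@dataclass(frozen=True)
class JoinConfig:
    """Overlap window and mismatch-density cap for pair joining.

    Presets follow the kit geometry for a 467 bp target region:
    v2 (2x250) -> (10, 70, 0.1); v3 (2x300) -> (110, 170, 0.1).
    """

    min_overlap: int
    max_overlap: int
    max_mismatch_density: float = 0.1

    def __post_init__(self):
        if not (0 < self.min_overlap <= self.max_overlap):
            raise ValueError("require 0 < min_overlap <= max_overlap")
        if not (0.0 <= self.max_mismatch_density <= 1.0):
            raise ValueError("mismatch density must be in [0, 1]")

    @classmethod
    def preset(cls, kit: str, max_mismatch_density: float = 0.1) -> "JoinConfig":
        kit = kit.lower()
        if kit == "v2":
            return cls(10, 70, max_mismatch_density)
        if kit == "v3":
            return cls(110, 170, max_mismatch_density)
        raise ValueError(f"unknown kit preset: {kit!r} (expected v2 or v3)")


@dataclass
class JoinRejection:
    read_id: str
    reason: str  # "no-overlap" or "density-exceeded"
    best_density: float | None = None


def expected_overlap(read_length: int, region_length: int) -> int:
    """Overlap of a perfect read pair spanning the region: 2L - region."""
    ov = 2 * read_length - region_length
    if ov <= 0:
        raise ValueError(
            f"reads of {read_length} nt cannot overlap across {region_length} nt"
        )
    return ov


def _best_overlap(
    a1: np.ndarray, a2rc: np.ndarray, cfg: JoinConfig
) -> tuple[int, int] | None:
    """Return (overlap_length, mismatches) minimizing density, ties to the
    longer overlap; None if no admissible overlap length exists."""
    n1, n2 = len(a1), len(a2rc)
    hi = min(cfg.max_overlap, n1, n2)
    lo = cfg.min_overlap
    if hi < lo:
        return None
    best: tuple[float, int, int] | None = None
    for L in range(hi, lo - 1, -1):
        mism = int(np.count_nonzero(a1[n1 - L :] != a2rc[:L]))
        dens = mism / L
        if best is None or dens < best[0]:
            best = (dens, L, mism)
            if mism == 0:
                break
    return (best[1], best[2])


def join_pair(
    pair: ReadPair, cfg: JoinConfig, sample_id: str = ""
) -> JoinedSequence | JoinRejection:
    """Join one read pair; mate 2 is reverse-complemented before the scan.

    At overlap mismatch positions the base with higher quality wins (ties go
    to mate 1); N always loses to a non-N base.
    """
    if not pair.r1_seq or not pair.r2_seq:
        raise ValueError("both mates must be nonempty")
    r2rc = reverse_complement(pair.r2_seq)
    a1 = encode(pair.r1_seq)
    a2 = encode(r2rc)
    hit = _best_overlap(a1, a2, cfg)
    if hit is None:
        return JoinRejection(pair.read_id, "no-overlap")
    L, mism = hit
    if mism / L > cfg.max_mismatch_density:
        return JoinRejection(pair.read_id, "density-exceeded", mism / L)
    n1 = len(a1)
    q1 = pair.r1_qual
    q2rc = pair.r2_qual[::-1] if pair.r2_qual is not None else None
    merged = list(pair.r1_seq.upper())
    r2rc_u = r2rc.upper()
    for k in range(L):
        i1 = n1 - L + k
        b1, b2 = merged[i1], r2rc_u[k]
        if b1 == b2:
            continue
        if b1 == "N":
            merged[i1] = b2
        elif b2 == "N":
            pass
        else:
            s1 = q1[i1] if q1 is not None else 0
            s2 = q2rc[k] if q2rc is not None else 0
            if s2 > s1:
                merged[i1] = b2
    sequence = "".join(merged) + r2rc_u[L:]
    return JoinedSequence(pair.read_id, sequence, sample_id, L, mism)


def join_pairs_batch(
    pairs: list[ReadPair], cfg: JoinConfig, sample_id: str = ""
) -> tuple[list[JoinedSequence], list[JoinRejection]]:
    """Vectorised joiner for a set of equal-length read pairs.

    Produces results identical to calling :func:`join_pair` on each pair.
    Pairs whose mate lengths differ from the batch mode fall back to the
    scalar path.
    """
    if not pairs:
        return [], []
    l1 = len(pairs[0].r1_seq)
    l2 = len(pairs[0].r2_seq)
    uniform = [p for p in pairs if len(p.r1_seq) == l1 and len(p.r2_seq) == l2]
    rest = [p for p in pairs if not (len(p.r1_seq) == l1 and len(p.r2_seq) == l2)]
    joined: list[JoinedSequence] = []
    rejected: list[JoinRejection] = []
    if uniform:
        n = len(uniform)
        A1 = np.zeros((n, l1), dtype=np.uint8)
        A2 = np.zeros((n, l2), dtype=np.uint8)
        r2rc_strs = []
        for i, p in enumerate(uniform):
            A1[i] = encode(p.r1_seq)
            rc = reverse_complement(p.r2_seq)
            r2rc_strs.append(rc.upper())
            A2[i] = encode(rc)
        hi = min(cfg.max_overlap, l1, l2)
        lo = cfg.min_overlap
        if hi < lo:
            rejected.extend(JoinRejection(p.read_id, "no-overlap") for p in uniform)
        else:
            lengths = np.arange(hi, lo - 1, -1)
            dens = np.empty((n, len(lengths)))
            mismat = np.empty((n, len(lengths)), dtype=np.int64)
            for j, L in enumerate(lengths):
                m = (A1[:, l1 - L :] != A2[:, :L]).sum(axis=1)
                mismat[:, j] = m
                dens[:, j] = m / L
            pick = dens.argmin(axis=1)  # first index = longest overlap on ties
            for i, p in enumerate(uniform):
                j = int(pick[i])
                L = int(lengths[j])
                mism = int(mismat[i, j])
                if mism / L > cfg.max_mismatch_density:
                    rejected.append(
                        JoinRejection(p.read_id, "density-exceeded", mism / L)
                    )
                    continue
                if mism == 0:
                    seq = p.r1_seq.upper() + r2rc_strs[i][L:]
                    joined.append(JoinedSequence(p.read_id, seq, sample_id, L, 0))
                else:
                    res = join_pair(p, cfg, sample_id)
                    assert isinstance(res, JoinedSequence)
                    joined.append(res)
    for p in rest:
        res = join_pair(p, cfg, sample_id)
        if isinstance(res, JoinedSequence):
            joined.append(res)
        else:
            rejected.append(res)
    return joined, rejected


def demultiplex(
    pairs: Iterable[ReadPair], panel_map: dict[str, str]
) -> tuple[dict[str, list[ReadPair]], list[ReadPair]]:
    """Assign read pairs to samples by exact (case-insensitive) index match.

    Any pair whose index is absent from the map — including indexes with N
    bases — goes to the unassigned pile. Two indexes mapping to the same
    sample are allowed; the same index mapping twice is a config error
    handled at map construction.
    """
    norm = {}
    for idx, sid in panel_map.items():
        key = idx.upper()
        if key in norm and norm[key] != sid:
            raise ValueError(f"index {key} mapped to multiple samples")
        norm[key] = sid
    by_sample: dict[str, list[ReadPair]] = {sid: [] for sid in dict.fromkeys(norm.values())}
    unassigned: list[ReadPair] = []
    for p in pairs:
        sid = norm.get((p.index_seq or "").upper())
        if sid is None:
            unassigned.append(p)
        else:
            by_sample[sid].append(p)
    return by_sample, unassigned


# ---------------------------------------------------------------------------
# FASTQ I/O (4-line records, optionally gzipped)

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _parse_fastq(handle) -> Iterator[tuple[str, str, list[int]]]:
    while True:
        header = handle.readline()
        if not header:
            return
        seq = handle.readline().strip()
        handle.readline()
        qual = handle.readline().strip()
        if not header.startswith("@"):
            raise ValueError(f"malformed FASTQ record header: {header!r}")
        yield header[1:].strip(), seq, [ord(c) - 33 for c in qual]


def _index_from_header(read_id: str) -> str | None:
    """Illumina header dialect: the index is the last ':'-separated field."""
    if ":" in read_id:
        field_ = read_id.rsplit(":", 1)[1]
        if field_ and set(field_.upper()) <= set("ACGTN"):
            return field_
    return None


def read_fastq_pairs(
    r1_path: str | Path,
    r2_path: str | Path,
    index_path: str | Path | None = None,
) -> Iterator[ReadPair]:
    """Stream read pairs from two (optionally gzipped) FASTQ files.

    The per-read index comes from a third FASTQ if given, otherwise from
    the read header's last ':'-separated field.
    """
    with _open_text(r1_path) as h1, _open_text(r2_path) as h2:
        if index_path is not None:
            with _open_text(index_path) as hi:
                for (id1, s1, q1), (_, s2, q2), (_, si, _) in zip(
                    _parse_fastq(h1), _parse_fastq(h2), _parse_fastq(hi)
                ):
                    yield ReadPair(id1.split()[0], s1, s2, q1, q2, si)
        else:
            for (id1, s1, q1), (_, s2, q2) in zip(_parse_fastq(h1), _parse_fastq(h2)):
                rid = id1.split()[0]
                yield ReadPair(rid, s1, s2, q1, q2, _index_from_header(id1))


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, list[int]]]) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{''.join(chr(q + 33) for q in qual)}\n")


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")
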