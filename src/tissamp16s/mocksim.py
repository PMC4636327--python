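"""Mock-community and MiSeq-run simulator with ground-truth ledger.

Emulates the validation designs used to qualify the pipeline: even mocks
(equal 16S copies per strain, default 10^7), staggered mocks (copies
spanning 10^3-10^6), serial dilutions against a constant reagent-contaminant
background, and template-free negative controls. Reads carry substitution
errors at the MiSeq-typical 0.1% per base, negligible indels, optional PCR
chimeras with a single uniform crossover, and constant base quality 38
(errored bases 20) — quality scores are deliberately uninformative because
the pipeline never filters on them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from . import protocol
from ._seq import reverse_complement
from .classify import TaxonomyReference
from .indexdesign import INDEX_LENGTH, BASES, is_compatible_pair
from .readprep import ReadPair
from .screenalign import ReferenceAlignment

CORE_LENGTH = protocol.REGION_LENGTH - len(protocol.FORWARD_16S_PRIMER) - len(
    protocol.REVERSE_16S_PRIMER
)

DEFAULT_EVEN_COPIES = 10_000_000
DEFAULT_STAGGERED_RANGE = (1_000, 1_000_000)

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Strain:
    name: str
    lineage: tuple[str, ...]  # domain..genus
    sequence: str  # full amplifiable region incl. primer sites
    copies: int


@dataclass
class MockSpec:
    strains: list[Strain]
    design_name: str = "custom"

    def with_copies(self, copies: int | dict[str, int]) -> "MockSpec":
        if isinstance(copies, int):
            strains = [replace(s, copies=copies) for s in self.strains]
        else:
            strains = [replace(s, copies=copies[s.name]) for s in self.strains]
        return MockSpec(strains, self.design_name)


@dataclass
class SeqRunConfig:
    kit: str = "v2"  # v2 = 2x250, v3 = 2x300
    depth: int = 10_000
    substitution_rate: float = 0.001
    indel_rate: float = 0.00001
    chimera_rate: float = 0.0
    background: list[Strain] = field(default_factory=list)
    sample_id: str = "sample1"
    index_seq: str | None = None
    seed: int = 0

    @property
    def read_length(self) -> int:
        return {"v2": 250, "v3": 300}[self.kit]


@dataclass
class GroundTruth:
    reads: list[tuple[str, str, bool]]  # (read_id, template_name, is_chimera)
    sample_id: str
    expected_abundance: dict[str, float]  # over amplifiable molecule sources


@dataclass
class SimulatedRun:
    pairs: list[ReadPair]
    truth: GroundTruth


def _mutate(seq: str, rate: float, rng: np.random.Generator, lo: int, hi: int) -> str:
    """Substitute bases at the given rate, restricted to [lo, hi)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    span = hi - lo
    n = rng.binomial(span, rate)
    if n == 0:
        return seq
    pos = lo + rng.choice(span, size=n, replace=False)
    for p in pos:
        choices = _BASE_ARR[_BASE_ARR != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


def default_index_list(n: int) -> list[str]:
    """First n hexamers of a lexicographic greedy compatible scan."""
    out: list[str] = []
    for combo in itertools.product(BASES, repeat=INDEX_LENGTH):
        cand = "".join(combo)
        if all(is_compatible_pair(prev, cand) for prev in out):
            out.append(cand)
            if len(out) == n:
                return out
    raise ValueError(f"cannot produce {n} compatible indexes")


def synth_reference_set(
    n_strains: int,
    seed: int = 0,
    primer_dropout: list[int] | None = None,
    *,
    copies: int = DEFAULT_EVEN_COPIES,
    genus_divergence: tuple[float, float] = (0.03, 0.05),
    family_divergence: tuple[float, float] = (0.08, 0.12),
    training_mutation_rate: float = 0.01,
    training_per_strain: int = 2,
) -> tuple[MockSpec, TaxonomyReference]:
    """Generate a clade-structured mock community plus classifier training
    data.

    Strains (one per genus, two genera per family) descend from a random
    core flanked by the real primer-binding sites; per-rank divergence is
    injected hierarchically. Strains listed in ``primer_dropout`` receive
    >= 3 substitutions inside their forward primer site, making them
    unamplifiable. Training sequences are disjoint mutants of each strain
    (~1% extra substitutions), so classification never sees its exact
    training data.
    """
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    primer_dropout = primer_dropout or []
    rng = np.random.default_rng(seed)
    fwd = protocol.FORWARD_16S_PRIMER
    rev_site = protocol.reverse_site_on_plus_strand()
    core = "".join(rng.choice(list("ACGT"), size=CORE_LENGTH))
    root = fwd + core + rev_site
    lo, hi = len(fwd), len(fwd) + CORE_LENGTH  # mutable span (spares primers)

    n_fam = (n_strains + 1) // 2
    strains: list[Strain] = []
    records: list[tuple[str, str, tuple[str, ...]]] = []
    si = 0
    for f in range(n_fam):
        fam_rate = rng.uniform(*family_divergence)
        fam_seq = _mutate(root, fam_rate, rng, lo, hi)
        phylum = f"Phylum{f % 3 + 1}"
        lineage_head = (
            "Bacteria",
            phylum,
            f"Class{f % 3 + 1}",
            f"Order{f + 1}",
            f"Family{f + 1}",
        )
        for g in range(2):
            if si >= n_strains:
                break
            gen_rate = rng.uniform(*genus_divergence)
            seq = _mutate(fam_seq, gen_rate, rng, lo, hi)
            name = f"Strain{si + 1:02d}"
            genus = f"Genus{si + 1:02d}"
            if si in primer_dropout:
                # kill the forward primer site with 3 substitutions
                seq = _mutate_positions(seq, [2, 8, 14], rng)
            strains.append(Strain(name, lineage_head + (genus,), seq, copies))
            for t in range(training_per_strain):
                train_seq = _mutate(seq, training_mutation_rate, rng, lo, hi)
                records.append((f"{name}_train{t+1}", train_seq, lineage_head + (genus,)))
            si += 1
    spec = MockSpec(strains, design_name="even")
    return spec, TaxonomyReference(records)


def _mutate_positions(seq: str, positions: list[int], rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for p in positions:
        choices = _BASE_ARR[_BASE_ARR != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


def synth_background(
    n_organisms: int = 5, seed: int = 12345, copies: int = 3000
) -> tuple[list[Strain], TaxonomyReference]:
    """Synthetic reagent-contaminant organisms, each its own family.

    The default load (5 organisms x 3000 copies) is comparable to a mock at
    ~10^3 copies per strain, so dilution series cross into the background
    regime between 10^2 and 10^4 copies, as low-biomass chemistry behaves.
    """
    rng = np.random.default_rng(seed)
    fwd = protocol.FORWARD_16S_PRIMER
    rev_site = protocol.reverse_site_on_plus_strand()
    core = "".join(rng.choice(list("ACGT"), size=CORE_LENGTH))
    root = fwd + core + rev_site
    lo, hi = len(fwd), len(fwd) + CORE_LENGTH
    strains = []
    records = []
    for i in range(n_organisms):
        seq = _mutate(root, rng.uniform(0.12, 0.18), rng, lo, hi)
        lineage = (
            "Bacteria",
            "PhylumR",
            "ClassR",
            f"OrderR{i+1}",
            f"ReagentFamily{i+1}",
            f"ReagentGenus{i+1}",
        )
        strains.append(Strain(f"Reagent{i+1}", lineage, seq, copies))
        for t in range(2):
            records.append(
                (f"Reagent{i+1}_train{t+1}", _mutate(seq, 0.01, rng, lo, hi), lineage)
            )
    return strains, TaxonomyReference(records)


def merge_taxonomies(*refs: TaxonomyReference) -> TaxonomyReference:
    records = [r for ref in refs for r in ref.records]
    return TaxonomyReference(records)


def reference_alignment(
    spec: MockSpec, background: list[Strain] | None = None
) -> ReferenceAlignment:
    """Ungapped reference alignment over mock + background templates."""
    templates = [(s.name, s.sequence) for s in spec.strains]
    for s in background or []:
        templates.append((s.name, s.sequence))
    return ReferenceAlignment(templates)


def in_silico_pcr(
    spec: MockSpec,
    forward: str = protocol.FORWARD_16S_PRIMER,
    reverse: str = protocol.REVERSE_16S_PRIMER,
    max_mismatches: int = 2,
) -> list[tuple[Strain, tuple[int, int]]]:
    """Strains whose both primer sites match within the mismatch budget;
    returns each with its amplicon interval (0-based half-open)."""
    if not forward or not reverse:
        raise ValueError("primers must be nonempty")
    rev_site = reverse_complement(reverse)
    out = []
    for s in spec.strains:
        fhit = _best_site(s.sequence, forward)
        rhit = _best_site(s.sequence, rev_site)
        if fhit is None or rhit is None:
            continue
        (fpos, fmm), (rpos, rmm) = fhit, rhit
        if fmm <= max_mismatches and rmm <= max_mismatches and fpos < rpos:
            out.append((s, (fpos, rpos + len(rev_site))))
    return out


def _best_site(template: str, site: str) -> tuple[int, int] | None:
    """(offset, mismatches) of the best match of site in template."""
    L, n = len(site), len(template)
    if n < L:
        return None
    tarr = np.frombuffer(template.encode(), dtype=np.uint8)
    sarr = np.frombuffer(site.encode(), dtype=np.uint8)
    best = None
    for off in range(n - L + 1):
        mm = int((tarr[off : off + L] != sarr).sum())
        if best is None or mm < best[1]:
            best = (off, mm)
            if mm == 0:
                break
    return best


def simulate_run(spec: MockSpec, cfg: SeqRunConfig) -> SimulatedRun:
    """Draw reads multinomially from the amplifiable molecule pool and apply
    the MiSeq error model; exactly cfg.depth pairs are emitted."""
    rng = np.random.default_rng(cfg.seed)
    pool: list[tuple[str, str]] = []  # (source name, amplicon)
    weights: list[float] = []
    for strain, (a, b) in in_silico_pcr(spec):
        if strain.copies > 0:
            pool.append((strain.name, strain.sequence[a:b]))
            weights.append(strain.copies)
    bg_spec = MockSpec(list(cfg.background))
    if cfg.background:
        for strain, (a, b) in in_silico_pcr(bg_spec):
            if strain.copies > 0:
                pool.append((strain.name, strain.sequence[a:b]))
                weights.append(strain.copies)
    if cfg.depth > 0 and not pool:
        raise ValueError("no amplifiable strains and no background")
    total = float(sum(weights))
    probs = np.array(weights) / total if pool else np.array([])
    expected = {name: w / total for (name, _), w in zip(pool, weights)}

    L = cfg.read_length
    const_qual = np.full(L, 38, dtype=np.int64)
    pairs: list[ReadPair] = []
    truth_rows: list[tuple[str, str, bool]] = []
    if cfg.depth > 0:
        n_chim = int(round(cfg.chimera_rate * cfg.depth))
        choices = rng.choice(len(pool), size=cfg.depth, p=probs)
        for i in range(cfg.depth):
            rid = f"{cfg.sample_id}_r{i+1}"
            is_chim = i < n_chim and len(pool) >= 2
            if is_chim:
                a, b = rng.choice(len(pool), size=2, replace=False, p=probs)
                sa, sb = pool[a][1], pool[b][1]
                cut = int(rng.integers(30, min(len(sa), len(sb)) - 30))
                amplicon = sa[:cut] + sb[cut:]
                tname = f"chimera:{pool[a][0]}+{pool[b][0]}"
            else:
                src = int(choices[i])
                amplicon = pool[src][1]
                tname = pool[src][0]
            amplicon, err_pos = _apply_errors(
                amplicon, cfg.substitution_rate, cfg.indel_rate, rng
            )
            r1 = amplicon[:L]
            r2 = reverse_complement(amplicon)[:L]
            if err_pos:
                q1 = const_qual.copy()
                q2 = const_qual.copy()
                n_amp = len(amplicon)
                for p in err_pos:
                    if p < L:
                        q1[p] = 20
                    rp = n_amp - 1 - p
                    if rp < L:
                        q2[rp] = 20
            else:
                q1 = q2 = const_qual
            pairs.append(ReadPair(rid, r1, r2, q1, q2, cfg.index_seq))
            truth_rows.append((rid, tname, is_chim))
    return SimulatedRun(
        pairs, GroundTruth(truth_rows, cfg.sample_id, expected)
    )


def _apply_errors(
    seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator
) -> tuple[str, list[int]]:
    n = len(seq)
    n_sub = rng.binomial(n, sub_rate)
    n_indel = rng.binomial(n, indel_rate)
    if n_sub == 0 and n_indel == 0:
        return seq, []
    arr = list(seq)
    err_pos: list[int] = []
    if n_sub:
        for p in rng.choice(n, size=n_sub, replace=False):
            cur = arr[p]
            alts = [b for b in "ACGT" if b != cur]
            arr[p] = alts[rng.integers(0, 3)]
            err_pos.append(int(p))
    for _ in range(n_indel):
        p = int(rng.integers(0, len(arr)))
        if rng.random() < 0.5 and len(arr) > 1:
            del arr[p]
        else:
            arr.insert(p, "ACGT"[rng.integers(0, 4)])
        err_pos.append(p)
    return "".join(arr), err_pos


def write_run_fastq(run: SimulatedRun, r1_path, r2_path) -> None:
    from .readprep import write_fastq

    def recs(mate: int):
        for p in run.pairs:
            seq = p.r1_seq if mate == 1 else p.r2_seq
            qual = p.r1_qual if mate == 1 else p.r2_qual
            rid = f"{p.read_id}:{p.index_seq or ''}"
            yield rid, seq, list(qual)

    write_fastq(r1_path, recs(1))
    write_fastq(r2_path, recs(2))


def staggered_copies(
    n_strains: int, low: int = DEFAULT_STAGGERED_RANGE[0],
    high: int = DEFAULT_STAGGERED_RANGE[1],
) -> list[int]:
    """Log-spaced copy numbers from low to high (inclusive ends)."""
    return [
        int(round(low * (high / low) ** (i / (n_strains - 1))))
        for i in range(n_strains)
    ]


def dilution_series(
    spec: MockSpec,
    cfg: SeqRunConfig,
    copies_grid: list[int] | None = None,
    *,
    n_negative_controls: int = 1,
) -> list[tuple[str, int, SimulatedRun]]:
    """One run per grid point with strain copies set to the grid value and
    the background held constant; negative controls carry zero strain
    copies (water analog). Each run gets its own sample id, index and seed.
    Returns (sample_id, copies, run) triples."""
    if copies_grid is None:
        copies_grid = [10**k for k in range(1, 8)]
    indexes = default_index_list(len(copies_grid) + n_negative_controls)
    out = []
    for i, copies in enumerate(copies_grid):
        sub = spec.with_copies(copies)
        sid = f"D{copies:.0e}".replace("+", "")
        run_cfg = replace(
            cfg, sample_id=sid, index_seq=indexes[i], seed=cfg.seed + i + 1
        )
        out.append((sid, copies, simulate_run(sub, run_cfg)))
    for j in range(n_negative_controls):
        sid = f"H2O{j+1}"
        run_cfg = replace(
            cfg,
            sample_id=sid,
            index_seq=indexes[len(copies_grid) + j],
            seed=cfg.seed + 1000 + j,
        )
        out.append((sid, 0, simulate_run(spec.with_copies(0), run_cfg)))
    return out
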