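"""End-to-end orchestration of the amplicon pipeline with attrition
accounting.

Stage order: demultiplex -> pair joining -> dereplication -> reference
alignment & culling -> blunt trimming -> pre-clustering & singleton removal
-> chimera screening -> taxonomic classification & non-Bacteria filtering ->
OTU clustering & consensus taxonomy -> OTU table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classify as _classify
from . import denoise as _denoise
from . import otucluster as _otu
from . import readprep as _readprep
from . import screenalign as _screen
from .classify import TaxonomicAssignment, TaxonomyReference
from .otucluster import OTU, OTUTable
from .readprep import JoinConfig, ReadPair
from .screenalign import AlignedSequence, ReferenceAlignment


@dataclass
class RunConfig:
    """All stage parameters with the protocol's defaults."""

    kit: str = "v2"
    max_mismatch_density: float = 0.1
    align_k: int = 8
    min_identity: float = 0.50
    min_coverage: float = 0.50
    precluster_diffs: int = 3
    chimera_chunks: int = 4
    chimera_skew: float = 2.0
    chimera_score_threshold: float = 0.28
    classifier_k: int = 8
    classifier_bootstraps: int = 100
    classifier_cutoff: float = 80.0
    otu_cutoff: float = 0.03
    consensus_cutoff: float = 51.0
    rarefaction_step: int = 100
    rarefaction_resamples: int = 1000
    seed: int = 0

    def join_config(self) -> JoinConfig:
        return JoinConfig.preset(self.kit, self.max_mismatch_density)


@dataclass
class AttritionLedger:
    """Per-stage read counts; every decrement has a reason entry."""

    raw_pairs: int = 0
    assigned: int = 0
    joined: int = 0
    aligned_kept: int = 0
    post_precluster: int = 0
    post_singleton: int = 0
    post_chimera: int = 0
    bacterial: int = 0
    clustered: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    def note(self, reason: str, n: int) -> None:
        if n:
            self.reasons[reason] = self.reasons.get(reason, 0) + n

    def stages(self) -> list[tuple[str, int]]:
        return [
            ("raw_pairs", self.raw_pairs),
            ("assigned", self.assigned),
            ("joined", self.joined),
            ("aligned_kept", self.aligned_kept),
            ("post_precluster", self.post_precluster),
            ("post_singleton", self.post_singleton),
            ("post_chimera", self.post_chimera),
            ("bacterial", self.bacterial),
            ("clustered", self.clustered),
        ]


@dataclass
class PipelineResult:
    otu_table: OTUTable
    otus: list[OTU]
    assignments: dict[str, TaxonomicAssignment]
    aligned: list[AlignedSequence]  # cleaned working set (blunt)
    ledger: AttritionLedger
    unique_counts: dict[str, dict[str, int]]  # seq_id -> per-sample counts


def run_pipeline(
    pairs: list[ReadPair],
    reference: ReferenceAlignment,
    taxonomy: TaxonomyReference,
    cfg: RunConfig,
    panel_map: dict[str, str] | None = None,
) -> PipelineResult:
    """Run all stages on in-memory read pairs.

    If ``panel_map`` is None the reads' existing sample assignment is a
    single pseudo-sample per distinct index; pass a map for real
    demultiplexing.
    """
    ledger = AttritionLedger(raw_pairs=len(pairs))

    if panel_map is not None:
        by_sample, unassigned = _readprep.demultiplex(pairs, panel_map)
        ledger.note("demux-unassigned", len(unassigned))
    else:
        by_sample = {"sample1": list(pairs)}
    ledger.assigned = sum(len(v) for v in by_sample.values())

    join_cfg = cfg.join_config()
    joined_all = []
    for sid, sample_pairs in by_sample.items():
        joined, rejected = _readprep.join_pairs_batch(sample_pairs, join_cfg, sid)
        joined_all.extend(joined)
        for r in rejected:
            ledger.note(f"join-{r.reason}", 1)
    ledger.joined = len(joined_all)

    if not joined_all:
        return PipelineResult(
            OTUTable(*_empty_table()), [], {}, [], ledger, {}
        )

    uniques = _screen.dereplicate(joined_all)

    index = _screen._TemplateIndex(reference, cfg.align_k)
    results = [
        _screen.align_to_reference(
            u,
            index,
            cfg.align_k,
            min_identity=cfg.min_identity,
            min_coverage=cfg.min_coverage,
        )
        for u in uniques
    ]
    kept, culled = _screen.cull_nonspecific(results)
    culled_reads = sum(
        r.unique.total_count for r in results if isinstance(r, _screen.NonAlignable)
    )
    ledger.note("align-culled", culled_reads)
    if not kept:
        return PipelineResult(
            OTUTable(*_empty_table()), [], {}, [], ledger, {}
        )
    blunt, trimmed_away = _screen.trim_blunt(kept)
    ledger.note("blunt-trim-removed", trimmed_away)
    ledger.aligned_kept = sum(a.unique.total_count for a in blunt)

    pre = _denoise.precluster(blunt, cfg.precluster_diffs)
    ledger.post_precluster = ledger.aligned_kept
    ledger.post_singleton = sum(a.unique.total_count for a in pre.merged)
    ledger.note("singletons-removed", pre.singletons_removed)

    verdicts = _denoise.screen_chimeras(
        pre.merged,
        cfg.chimera_chunks,
        cfg.chimera_skew,
        cfg.chimera_score_threshold,
    )
    cleaned, removed_chim = _denoise.apply_verdicts(pre.merged, verdicts)
    ledger.note("chimeras-removed", sum(a.unique.total_count for a in removed_chim))
    ledger.post_chimera = sum(a.unique.total_count for a in cleaned)

    if not cleaned:
        return PipelineResult(
            OTUTable(*_empty_table()), [], {}, [], ledger, {}
        )

    model = _classify.train(taxonomy, cfg.classifier_k)
    rng = np.random.default_rng(cfg.seed)
    assignments: dict[str, TaxonomicAssignment] = {}
    for a in cleaned:
        assignments[a.unique.seq_id] = _classify.classify_sequence(
            a.ungapped_span(),
            model,
            a.unique.seq_id,
            cfg.classifier_bootstraps,
            cfg.classifier_cutoff,
            rng,
        )
    bacterial, removed_nb = _classify.filter_non_bacteria(assignments, cleaned)
    ledger.note(
        "non-bacteria-removed",
        sum(a.unique.total_count for a in cleaned) -
        sum(a.unique.total_count for a in bacterial),
    )
    ledger.bacterial = sum(a.unique.total_count for a in bacterial)
    if not bacterial:
        return PipelineResult(
            OTUTable(*_empty_table()), [], assignments, [], ledger, {}
        )

    dm = _otu.distance_matrix(bacterial)
    counts = {a.unique.seq_id: a.unique.total_count for a in bacterial}
    partition = _otu.cluster_average_neighbor(dm, cfg.otu_cutoff, counts)
    otus = _otu.make_otus(partition, counts)
    for otu in otus:
        otu.consensus_lineage = _otu.consensus_taxonomy(
            otu, assignments, cfg.consensus_cutoff
        )
    per_sample = {a.unique.seq_id: dict(a.unique.per_sample_counts) for a in bacterial}
    table = _otu.build_otu_table(otus, per_sample)
    ledger.clustered = int(table.counts.to_numpy().sum()) if not table.is_empty else 0
    return PipelineResult(table, otus, assignments, bacterial, ledger, per_sample)


def _empty_table():
    import pandas as pd

    return (pd.DataFrame(), {}, True)


def report(ledger: AttritionLedger, table: OTUTable | None = None) -> str:
    """Human-readable per-stage attrition report with percentages relative
    to the assigned (manufacturer passing-filter) pairs."""
    lines = ["stage\tcount\tpct_of_assigned"]
    base = ledger.assigned or 0
    for name, count in ledger.stages():
        pct = (100.0 * count / base) if base else 0.0
        lines.append(f"{name}\t{count}\t{pct:.2f}%")
    for reason, n in sorted(ledger.reasons.items()):
        lines.append(f"removed:{reason}\t{n}\t")
    if table is not None and not table.is_empty:
        lines.append(f"otus\t{len(table.counts)}\t")
    return "\n".join(lines) + "\n"


def parse_report(text: str) -> dict[str, int]:
    out = {}
    for line in text.strip().splitlines()[1:]:
        name, count, *_ = line.split("\t")
        out[name] = int(count)
    return out
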