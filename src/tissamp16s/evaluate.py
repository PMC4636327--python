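"""Validation metrics: mock composition deviation, replicate variability,
and background-similarity flagging of low-biomass samples."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import CompositionProfile, generalized_unifrac

DEFAULT_BACKGROUND_THRESHOLD = 0.2


@dataclass
class DeviationReport:
    rank: str
    per_taxon: pd.DataFrame  # columns: actual, measured, deviation (all in %)
    min_deviation: float
    max_deviation: float
    median_deviation: float


@dataclass
class ReplicateReport:
    per_taxon_median_diff: pd.Series  # read %, per taxon
    median_difference: float
    sem_of_median: float


def composition_deviation(
    measured: CompositionProfile | pd.Series | dict,
    actual: pd.Series | dict,
    rank: str = "",
    sample_id: str | None = None,
) -> DeviationReport:
    """Per-taxon |measured - actual| in percentage points, with summary.

    The taxon universe is the union of both inputs; a taxon missing from one
    side contributes zero there.
    """
    if isinstance(measured, CompositionProfile):
        rank = rank or measured.rank
        col = sample_id or measured.proportions.columns[0]
        mvec = measured.proportions[col]
    else:
        mvec = pd.Series(measured, dtype=float)
    avec = pd.Series(actual, dtype=float)
    taxa = sorted(set(mvec.index) | set(avec.index))
    m = mvec.reindex(taxa).fillna(0.0) * 100.0
    a = avec.reindex(taxa).fillna(0.0) * 100.0
    dev = (m - a).abs()
    df = pd.DataFrame({"actual": a, "measured": m, "deviation": dev})
    return DeviationReport(
        rank,
        df,
        float(dev.min()),
        float(dev.max()),
        float(dev.median()),
    )


def replicate_variability(
    profiles: list[CompositionProfile | pd.Series],
    *,
    bootstrap_resamples: int = 1000,
    seed: int = 0,
) -> ReplicateReport:
    """Pool per-taxon pairwise absolute differences (in read %) across
    replicate profiles; report their median and a seeded-bootstrap SEM of
    that median."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 replicate profiles")
    vecs = []
    for p in profiles:
        if isinstance(p, CompositionProfile):
            if p.proportions.shape[1] != 1:
                raise ValueError("each replicate profile must hold one sample")
            vecs.append(p.proportions.iloc[:, 0])
        else:
            vecs.append(pd.Series(p, dtype=float))
    taxa = sorted(set().union(*[set(v.index) for v in vecs]))
    mat = np.stack([v.reindex(taxa).fillna(0.0).to_numpy() * 100 for v in vecs])
    diffs = []
    n = len(vecs)
    for i in range(n):
        for j in range(i + 1, n):
            diffs.append(np.abs(mat[i] - mat[j]))
    diffs = np.stack(diffs)  # (n_pairs, n_taxa)
    pooled = diffs.ravel()
    per_taxon = pd.Series(np.median(diffs, axis=0), index=taxa)
    med = float(np.median(pooled))
    rng = np.random.default_rng(seed)
    boots = np.median(
        rng.choice(pooled, size=(bootstrap_resamples, pooled.size), replace=True),
        axis=1,
    )
    return ReplicateReport(per_taxon, med, float(boots.std(ddof=1)))


def background_check(
    sample_profile: dict[str, float] | np.ndarray,
    negative_control_profiles: list[dict[str, float] | np.ndarray],
    tree,
    alpha: float = 0.6,
    threshold: float = DEFAULT_BACKGROUND_THRESHOLD,
    leaf_ids: list[str] | None = None,
) -> tuple[float, bool]:
    """Generalized-UniFrac distance to the nearest negative control.

    Returns (distance, flagged); flagged means the sample sits inside the
    reagent-background cloud and its profile should not be trusted.
    """
    if not negative_control_profiles:
        raise ValueError("at least one negative control profile is required")
    dists = [
        generalized_unifrac(tree, sample_profile, ctrl, alpha, leaf_ids=leaf_ids)
        for ctrl in negative_control_profiles
    ]
    nearest = min(dists)
    return nearest, nearest < threshold
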