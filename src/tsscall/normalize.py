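"""Two-stage inter-library normalization.

Stage 1 (percentile normalization): for every library pair the 90th
percentile Q_PL of the enriched track's *nonzero* values is computed; both
tracks of the pair are multiplied by Q_min / Q_PL, where Q_min is the minimal
percentile across pairs.  Afterwards every enriched library's percentile
equals Q_min, which restores the original data range while equalizing
library depths.

Stage 2 (enrichment-factor equalization): the median per-position enrichment
factor (enriched / control over positions where both are strictly positive)
is computed per pair; every control track is multiplied by
median_EF(pair) / EF_max, so that each pair's post-hoc median enrichment
factor equals the largest one observed (EF_max).

Percentiles over nonzero positions only: prokaryotic coverage is sparse and
a percentile over all positions is frequently 0, which would degenerate the
scheme.  The median enrichment factor likewise ignores positions where either
library is zero (the ratio is undefined there).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import NormalizationError
from .model import LibraryPair

PairKey = tuple[str, str, str, str]


@dataclass
class NormalizationStats:
    """Factors recorded while normalizing; q_min also rescales the
    step-height threshold into absolute coverage units."""

    percentile_rank: float = 0.9
    q_pl: dict[PairKey, float] = field(default_factory=dict)
    q_min: float = 1.0
    median_ef: dict[PairKey, float] = field(default_factory=dict)
    ef_max: float = 1.0


def percentile_normalize(pairs: Sequence[LibraryPair],
                         percentile_rank: float = 0.9,
                         ) -> tuple[list[LibraryPair], NormalizationStats]:
    """Scale each pair by Q_min / Q_PL (enriched nonzero percentile)."""
    stats = NormalizationStats(percentile_rank=percentile_rank)
    for pair in pairs:
        nonzero = pair.enriched.values[pair.enriched.values > 0]
        if nonzero.size == 0:
            raise NormalizationError(
                f"pair {pair.key}: enriched library has no nonzero positions")
        q = float(np.quantile(nonzero, percentile_rank))
        if q == 0:
            raise NormalizationError(
                f"pair {pair.key}: percentile value is 0 (degenerate library)")
        stats.q_pl[pair.key] = q
    stats.q_min = min(stats.q_pl.values())

    out = []
    for pair in pairs:
        scale = stats.q_min / stats.q_pl[pair.key]
        scaled = pair.copy()
        scaled.enriched.values *= scale
        scaled.control.values *= scale
        out.append(scaled)
    return out, stats


def enrichment_normalize(pairs: Sequence[LibraryPair],
                         stats: NormalizationStats) -> list[LibraryPair]:
    """Equalize apparent enrichment by scaling controls to EF_max."""
    for pair in pairs:
        both = (pair.enriched.values > 0) & (pair.control.values > 0)
        if not both.any():
            raise NormalizationError(
                f"pair {pair.key}: no position with both libraries > 0")
        ratio = pair.enriched.values[both] / pair.control.values[both]
        stats.median_ef[pair.key] = float(np.median(ratio))
    stats.ef_max = max(stats.median_ef.values())

    out = []
    for pair in pairs:
        scaled = pair.copy()
        scaled.control.values *= stats.median_ef[pair.key] / stats.ef_max
        out.append(scaled)
    return out


def normalize_experiment(pairs: Sequence[LibraryPair],
                         percentile: bool = True,
                         enrichment: bool = True,
                         percentile_rank: float = 0.9,
                         ) -> tuple[list[LibraryPair], NormalizationStats]:
    """Apply percentile normalization then enrichment equalization.

    Either stage can be disabled.  With the percentile stage off, q_min
    stays 1.0 and step-height thresholds are interpreted as absolute
    coverage units downstream.
    """
    stats = NormalizationStats(percentile_rank=percentile_rank)
    out = list(pairs)
    if percentile:
        out, stats = percentile_normalize(out, percentile_rank)
    if enrichment:
        out = enrichment_normalize(out, stats)
    return out, stats
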