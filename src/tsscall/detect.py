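"""Per-replicate TSS candidate detection on enriched coverage profiles.

A position i is a candidate when the rise over the previous position in the
direction of transcription passes both thresholds:

    step height  e(i) - e(prev)  >=  T_h
    step factor  e(i) / e(prev)  >=  T_f

On the forward strand ``prev = i - 1``; on the reverse strand transcription
runs toward decreasing coordinates, so ``prev = i + 1``.  A previous value
outside the replicon counts as 0.  The step factor is +infinity when
e(prev) = 0 < e(i) and 1 when both are 0; a position with zero coverage is
never a candidate.  Candidates closer than a window W are afterwards thinned
to one representative per run.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import BoundsError
from .model import FORWARD, CoverageTrack, LibraryPair, TssCandidate
from .params import ParameterSet


def step_metrics(track: CoverageTrack, position: int) -> tuple[float, float]:
    """Step height and step factor at a 1-based position (strand-aware)."""
    if not 1 <= position <= track.length:
        raise BoundsError(
            f"position {position} outside track of length {track.length}")
    prev = position - 1 if track.strand == FORWARD else position + 1
    current = track.value_at(position)
    previous = track.value_at(prev)
    height = current - previous
    if previous > 0:
        factor = current / previous
    elif current > 0:
        factor = float("inf")
    else:
        factor = 1.0
    return height, factor


def _step_arrays(track: CoverageTrack) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized heights and factors for all positions of a track."""
    e = track.values
    prev = np.empty_like(e)
    if track.strand == FORWARD:
        prev[1:] = e[:-1]
        prev[0] = 0.0
    else:
        prev[:-1] = e[1:]
        prev[-1] = 0.0
    heights = e - prev
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(prev > 0, e / np.where(prev > 0, prev, 1.0),
                           np.where(e > 0, np.inf, 1.0))
    return heights, factors


def detect_candidates(pair: LibraryPair, params: ParameterSet,
                      ) -> list[TssCandidate]:
    """Scan the enriched track of a (normalized) pair for TSS candidates.

    ``params.step_height`` is taken in absolute coverage units here: callers
    working with percentile-normalized tracks pass
    ``params.scaled_by(stats.q_min)``.  The control track plays no role at
    this stage — enrichment is tested after consolidation.
    """
    heights, factors = _step_arrays(pair.enriched)
    mask = ((heights >= params.step_height)
            & (factors >= params.step_factor)
            & (pair.enriched.values > 0))
    return [
        TssCandidate(pair.replicon_id, int(idx) + 1, pair.strand,
                     float(heights[idx]), float(factors[idx]),
                     condition=pair.condition, replicate=pair.replicate)
        for idx in np.nonzero(mask)[0]
    ]


def reduce_close_candidates(candidates: Sequence[TssCandidate], window: int,
                            mode: str = "strongest") -> list[TssCandidate]:
    """Thin runs of close candidates (one strand) to a single survivor.

    A run chains candidates whose consecutive distances are <= ``window`` bp.
    ``mode="first"`` keeps the 5'-most candidate (smallest coordinate on the
    forward strand, largest on the reverse); ``mode="strongest"`` keeps the
    largest step height, ties broken toward the 5' end.  ``window=0`` returns
    the input unchanged.  Idempotent, never increases the count.
    """
    cands = sorted(candidates, key=lambda c: c.position)
    if window == 0 or len(cands) < 2:
        return cands

    runs: list[list[TssCandidate]] = [[cands[0]]]
    for cand in cands[1:]:
        if cand.position - runs[-1][-1].position <= window:
            runs[-1].append(cand)
        else:
            runs.append([cand])

    survivors = []
    for run in runs:
        five_prime = run if run[0].strand == FORWARD else list(reversed(run))
        if mode == "first":
            survivors.append(five_prime[0])
        else:
            survivors.append(max(five_prime,
                                 key=lambda c: c.step_height))
    return sorted(survivors, key=lambda c: c.position)
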