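"""Cross-replicate reconciliation, enrichment filtering and cross-condition
clustering of TSS candidates.

Within one condition, candidates from different replicates that lie within
the cross-replicate shift of each other are treated as the same TSS
(single-linkage chaining).  Replicates missing a detection re-test the
neighborhood against subtractively reduced thresholds (T_h - rho_h, floored
at 0; T_f - rho_f, floored at 1).  A TSS survives when at least R_min
replicates detect it, and is *enriched* when the maximal per-replicate
enrichment factor e_enr / e_control at its position reaches T_EF.

Across conditions, enriched TSS within the cross-condition shift are merged
into one consolidated record whose representative position is the
contributing position with the largest step height (ties toward the smaller
coordinate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ConfigurationError
from .model import (ConditionRecord, ConsolidatedTss, LibraryPair,
                    TssCandidate)
from .detect import step_metrics
from .params import ParameterSet

logger = logging.getLogger(__name__)


@dataclass
class DetectedTss:
    """A per-condition TSS after replicate reconciliation."""

    replicon_id: str
    position: int
    strand: str
    condition: str
    step_height: float
    step_factor: float
    det_count: int
    enrichment_factor: float = 0.0
    enriched: bool = False


def _single_linkage(items: list, max_gap: int, position) -> list[list]:
    """Group sorted items into runs with consecutive gaps <= max_gap."""
    items = sorted(items, key=position)
    if not items:
        return []
    clusters = [[items[0]]]
    for item in items[1:]:
        if position(item) - position(clusters[-1][-1]) <= max_gap:
            clusters[-1].append(item)
        else:
            clusters.append([item])
    return clusters


def reconcile_replicates(candidates_by_replicate: Mapping[str, Sequence[TssCandidate]],
                         pairs_by_replicate: Mapping[str, LibraryPair],
                         params: ParameterSet) -> list[DetectedTss]:
    """Merge window-reduced candidates of one (condition, replicon, strand).

    Thresholds in ``params`` are in absolute units (already scaled by q_min).
    """
    replicates = list(pairs_by_replicate)
    if params.min_replicates > len(replicates):
        raise ConfigurationError(
            f"min_replicates={params.min_replicates} exceeds the "
            f"{len(replicates)} available replicates")

    pool = [c for reps in candidates_by_replicate.values() for c in reps]
    if not pool:
        return []
    replicon = pool[0].replicon_id
    strand = pool[0].strand
    condition = pool[0].condition

    reduced_h = max(0.0, params.step_height - params.height_reduction)
    reduced_f = max(1.0, params.step_factor - params.factor_reduction)
    shift = params.cross_replicate_shift

    detected = []
    for cluster in _single_linkage(pool, shift, lambda c: c.position):
        # one (position, height, factor) per replicate; strongest on collision
        per_rep: dict[str, tuple[int, float, float]] = {}
        for cand in cluster:
            best = per_rep.get(cand.replicate)
            if best is None or cand.step_height > best[1]:
                per_rep[cand.replicate] = (cand.position, cand.step_height,
                                           cand.step_factor)
        rep_pos, rep_h, rep_f = max(
            per_rep.values(), key=lambda v: (v[1], -v[0]))

        # re-evaluate missing replicates at reduced thresholds within +-shift
        for rep in replicates:
            if rep in per_rep:
                continue
            track = pairs_by_replicate[rep].enriched
            best = None
            for pos in range(max(1, rep_pos - shift),
                             min(track.length, rep_pos + shift) + 1):
                height, factor = step_metrics(track, pos)
                if (track.value_at(pos) > 0 and height >= reduced_h
                        and factor >= reduced_f):
                    if best is None or height > best[1]:
                        best = (pos, height, factor)
            if best is not None:
                per_rep[rep] = best

        if len(per_rep) < params.min_replicates:
            continue
        # representative metrics: the strongest step across replicates
        rep_pos, rep_h, rep_f = max(
            per_rep.values(), key=lambda v: (v[1], -v[0]))
        detected.append(DetectedTss(replicon, rep_pos, strand, condition,
                                    rep_h, rep_f, det_count=len(per_rep)))
    return detected


def enrichment_filter(detected: Sequence[DetectedTss],
                      pairs_by_replicate: Mapping[str, LibraryPair],
                      params: ParameterSet) -> list[DetectedTss]:
    """Keep TSS whose maximal per-replicate enrichment factor reaches T_EF.

    EF = e_enriched(j) / e_control(j) at the TSS position j; +infinity when
    the control is 0 but the enriched value is positive; positions where both
    libraries are 0 contribute no factor.
    """
    enriched = []
    for tss in detected:
        factors = []
        for pair in pairs_by_replicate.values():
            e = pair.enriched.value_at(tss.position)
            c = pair.control.value_at(tss.position)
            if e <= 0 and c <= 0:
                continue
            factors.append(float("inf") if c == 0 else e / c)
        if not factors:
            continue
        best = max(factors)
        if best >= params.enrichment_factor:
            tss.enrichment_factor = best
            tss.enriched = True
            enriched.append(tss)
    return enriched


def cluster_across_conditions(by_condition: Mapping[str, Sequence[DetectedTss]],
                              params: ParameterSet,
                              conditions: Sequence[str],
                              ) -> list[ConsolidatedTss]:
    """Merge per-condition enriched TSS sharing one coordinate system.

    Single-linkage clustering per (replicon, strand) with linkage distance
    <= cross_condition_shift; conditions not contributing to a cluster are
    recorded as neither detected nor enriched.
    """
    groups: dict[tuple[str, str], list[DetectedTss]] = {}
    for cond_tss in by_condition.values():
        for tss in cond_tss:
            groups.setdefault((tss.replicon_id, tss.strand), []).append(tss)

    consolidated = []
    for (replicon, strand), items in sorted(groups.items()):
        for cluster in _single_linkage(items, params.cross_condition_shift,
                                       lambda t: t.position):
            per_cond: dict[str, DetectedTss] = {}
            for tss in cluster:
                best = per_cond.get(tss.condition)
                if best is not None:
                    logger.warning(
                        "condition %s contributes two TSS (%d, %d) to one "
                        "cluster; keeping the stronger", tss.condition,
                        best.position, tss.position)
                if best is None or tss.step_height > best.step_height:
                    per_cond[tss.condition] = tss
            representative = max(per_cond.values(),
                                 key=lambda t: (t.step_height, -t.position))
            records = {}
            for cond in conditions:
                tss = per_cond.get(cond)
                if tss is None:
                    records[cond] = ConditionRecord(position=representative.position)
                else:
                    records[cond] = ConditionRecord(
                        detected=True, enriched=tss.enriched,
                        step_height=tss.step_height,
                        step_factor=tss.step_factor,
                        enrichment_factor=tss.enrichment_factor,
                        det_count=tss.det_count, position=tss.position)
            consolidated.append(ConsolidatedTss(
                replicon, representative.position, strand, records))
    consolidated.sort(key=lambda t: (t.replicon_id, t.position, t.strand))
    return consolidated
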