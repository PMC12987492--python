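"""Post-prediction statistics.

Two families:

* UpSet-style subset counts of TSS over their classes or over the conditions
  in which they are enriched, aggregated either by genomic location alone or
  by location and condition.

* Differential-TSS testing between two conditions: the enriched coverage
  window around each TSS is treated as an empirical distribution over
  offsets; all replicate pairs across the two conditions are compared with a
  two-sample Kolmogorov-Smirnov test on the weighted ECDFs, the per-TSS
  p-values are merged with the Cauchy combination test, and the combined
  p-values are Bonferroni-corrected over the number of tested TSS.

The KS test operates on coverage-mass-weighted ECDFs rather than resampled
reads: it is deterministic, and the asymptotic p-value uses an effective
sample size equal to the rounded total coverage mass of each window, capped
at 10,000 (coverage mass approximates, but does not equal, a read count —
an interpretation, documented in the methods note).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import special

from .errors import DegenerateWindowError
from .model import FORWARD, ConsolidatedTss, CoverageTrack, LibraryPair

logger = logging.getLogger(__name__)

EFFECTIVE_N_CAP = 10_000
P_CLIP = 1e-15


# ---------------------------------------------------------------------------
# subset counts


@dataclass
class SubsetCounts:
    """Counts of TSS units per non-empty label subset (UpSet plot input)."""

    mode: str  # by_class | by_condition
    aggregation: str  # position_only | position_and_condition
    counts: dict[frozenset, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, labels) -> None:
        key = frozenset(labels)
        if key:
            self.counts[key] = self.counts.get(key, 0) + 1

    def to_tsv(self, path) -> None:
        lines = ["labels\tcount"]
        for labels, count in sorted(self.counts.items(),
                                    key=lambda kv: (-kv[1], sorted(kv[0]))):
            lines.append(f"{','.join(sorted(labels))}\t{count}")
        with open(path, "w") as handle:
            handle.write("\n".join(lines) + "\n")


def subset_counts(tss: Sequence[ConsolidatedTss], mode: str = "by_class",
                  aggregation: str = "position_only") -> SubsetCounts:
    """Aggregate TSS into label subsets.

    * ``by_class`` / ``position_only``: each distinct location counted once
      under the union of its class names pooled over enriched conditions.
    * ``by_class`` / ``position_and_condition``: each (location, enriched
      condition) counted separately under that condition's class set.
    * ``by_condition``: label set = conditions in which the TSS is enriched.
    """
    if mode not in ("by_class", "by_condition"):
        raise ValueError(f"unknown mode {mode!r}")
    if aggregation not in ("position_only", "position_and_condition"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    out = SubsetCounts(mode, aggregation)
    for t in tss:
        if mode == "by_condition":
            out.add(t.enriched_conditions)
        elif aggregation == "position_only":
            pooled: set[str] = set()
            for record in t.records.values():
                if record.enriched:
                    pooled.update(record.classes)
            if not pooled:
                pooled = {c.tss_class for c in t.classifications}
            out.add(pooled)
        else:
            for record in t.records.values():
                if record.enriched:
                    out.add(record.classes)
    return out


# ---------------------------------------------------------------------------
# differential testing


def extract_profile(track: CoverageTrack, position: int, strand: str,
                    half_window: int = 50) -> tuple[np.ndarray, float]:
    """Enriched coverage around a TSS as a distribution over offsets.

    Returns (probabilities over the 2*half_window+1 offsets, total mass).
    Offsets run 5'->3' in transcript orientation (reverse-strand windows are
    flipped); positions beyond the replicon contribute zero.  An all-zero
    window defines no distribution and raises :class:`DegenerateWindowError`.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    window = np.zeros(2 * half_window + 1)
    lo = max(1, position - half_window)
    hi = min(track.length, position + half_window)
    if lo > position - half_window or hi < position + half_window:
        logger.warning("window around %d truncated at replicon boundary",
                       position)
    window[lo - (position - half_window):
           hi - (position - half_window) + 1] = \
        track.values[lo - 1:hi]
    if strand != FORWARD:
        window = window[::-1]
    mass = float(window.sum())
    if mass <= 0:
        raise DegenerateWindowError(
            f"all-zero coverage window around position {position}")
    return window / mass, mass


def _ks_pvalue(window_a: tuple[np.ndarray, float],
               window_b: tuple[np.ndarray, float]) -> float:
    probs_a, mass_a = window_a
    probs_b, mass_b = window_b
    d = float(np.max(np.abs(np.cumsum(probs_a) - np.cumsum(probs_b))))
    n_a = min(max(1, round(mass_a)), EFFECTIVE_N_CAP)
    n_b = min(max(1, round(mass_b)), EFFECTIVE_N_CAP)
    en = n_a * n_b / (n_a + n_b)
    return float(np.clip(special.kolmogorov(math.sqrt(en) * d), 0.0, 1.0))


def pairwise_ks(windows_a: Sequence[tuple[np.ndarray, float]],
                windows_b: Sequence[tuple[np.ndarray, float]]) -> list[float]:
    """KS p-values for every replicate pair across two conditions."""
    if not windows_a or not windows_b:
        raise ValueError("each condition needs at least one window")
    return [_ks_pvalue(a, b) for a in windows_a for b in windows_b]


def cauchy_combine(pvalues: Sequence[float]) -> float:
    """Cauchy combination test: T = mean(tan((0.5 - p) * pi)),
    combined p = 0.5 - arctan(T) / pi.  Identity on constant inputs."""
    if len(pvalues) == 0:
        raise ValueError("cauchy_combine needs at least one p-value")
    p = np.clip(np.asarray(pvalues, dtype=np.float64), P_CLIP, 1 - P_CLIP)
    t = float(np.mean(np.tan((0.5 - p) * np.pi)))
    return 0.5 - math.atan(t) / math.pi


def bonferroni_adjust(pvalues: Sequence[float], n: int | None = None,
                      ) -> list[float]:
    """min(1, p * n) with n defaulting to the number of tested hypotheses."""
    if n is None:
        n = len(pvalues)
    if n < 1:
        raise ValueError("n must be >= 1")
    return [min(1.0, p * n) for p in pvalues]


@dataclass
class DifferentialResult:
    replicon_id: str
    position: int
    strand: str
    condition_a: str
    condition_b: str
    ks_pvalues: list[float]
    combined_p: float
    adjusted_p: float = 1.0


def differential_test(tss: Sequence[ConsolidatedTss],
                      pairs: Sequence[LibraryPair],
                      condition_a: str, condition_b: str,
                      half_window: int = 50) -> list[DifferentialResult]:
    """Test every consolidated TSS for a coverage-profile difference between
    two conditions, on the normalized enriched tracks of all replicates."""
    tracks: dict[tuple[str, str, str], list[CoverageTrack]] = {}
    for pair in pairs:
        tracks.setdefault((pair.condition, pair.strand, pair.replicon_id),
                          []).append(pair.enriched)

    results = []
    for t in tss:
        windows = {}
        degenerate = False
        for cond in (condition_a, condition_b):
            cond_windows = []
            for track in tracks.get((cond, t.strand, t.replicon_id), []):
                try:
                    cond_windows.append(
                        extract_profile(track, t.position, t.strand,
                                        half_window))
                except DegenerateWindowError:
                    logger.warning(
                        "TSS %s:%d%s: degenerate window in %s excluded",
                        t.replicon_id, t.position, t.strand, cond)
            if not cond_windows:
                degenerate = True
            windows[cond] = cond_windows
        if degenerate:
            continue
        ks = pairwise_ks(windows[condition_a], windows[condition_b])
        results.append(DifferentialResult(
            t.replicon_id, t.position, t.strand, condition_a, condition_b,
            ks, cauchy_combine(ks)))

    adjusted = bonferroni_adjust([r.combined_p for r in results])
    for result, adj in zip(results, adjusted):
        result.adjusted_p = adj
    return results


def write_differential_tsv(results: Sequence[DifferentialResult], path) -> None:
    lines = ["Replicon\tPos\tStrand\tConditionA\tConditionB\t"
             "ksPvalues\tcombinedP\tadjustedP"]
    for r in results:
        ks = ",".join(f"{p:.6g}" for p in r.ks_pvalues)
        lines.append(f"{r.replicon_id}\t{r.position}\t{r.strand}\t"
                     f"{r.condition_a}\t{r.condition_b}\t{ks}\t"
                     f"{r.combined_p:.6g}\t{r.adjusted_p:.6g}")
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")
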