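"""Core in-memory containers shared across the pipeline.

Coordinates are 1-based inclusive everywhere (the native convention of
wiggle and GFF3); bedGraph intervals are converted on load.  Strands are
encoded as ``"+"`` / ``"-"`` and never by coordinate swaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ValidationError

FORWARD = "+"
REVERSE = "-"
STRANDS = (FORWARD, REVERSE)

ENRICHED = "enriched"
CONTROL = "control"
LIBRARIES = (ENRICHED, CONTROL)


@dataclass
class CoverageTrack:
    """Dense per-base expression values for one replicon and strand.

    ``values[i]`` holds the expression at 1-based genomic position ``i + 1``.
    Values are non-negative; exporters that encode the reverse strand with
    negative numbers are handled at load time (absolute value).
    """

    replicon_id: str
    strand: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")
        if self.values.ndim != 1:
            raise ValidationError("coverage values must be one-dimensional")
        if self.values.size and float(self.values.min()) < 0.0:
            raise ValidationError(
                f"negative coverage in track {self.replicon_id}{self.strand}"
            )

    @property
    def length(self) -> int:
        return int(self.values.size)

    def value_at(self, position: int) -> float:
        """Expression at a 1-based position; 0.0 outside the replicon."""
        if 1 <= position <= self.length:
            return float(self.values[position - 1])
        return 0.0

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(self.replicon_id, self.strand, self.values.copy())


@dataclass
class GeneRecord:
    """One annotated gene (or CDS fallback), strand encoded separately."""

    replicon_id: str
    locus_tag: str
    name: str
    product: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.locus_tag}: start {self.start} > end {self.end}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"gene {self.locus_tag}: bad strand")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def translation_start(self) -> int:
        """Position of the annotated start codon (strand-aware)."""
        return self.start if self.strand == FORWARD else self.end


@dataclass
class ExperimentLayout:
    """Which file feeds which (condition, replicate, strand, library) slot.

    Every (condition, replicate) needs exactly four files: two strands times
    enriched/control.
    """

    conditions: list[str]
    replicates: dict[str, list[str]]
    files: dict[tuple[str, str, str, str], Path] = field(default_factory=dict)

    def assign(self, condition: str, replicate: str, strand: str,
               library: str, path: Path | str) -> None:
        if strand not in STRANDS or library not in LIBRARIES:
            raise ConfigurationError(
                f"invalid slot ({condition}, {replicate}, {strand}, {library})"
            )
        self.files[(condition, replicate, strand, library)] = Path(path)

    def validate(self) -> None:
        for cond in self.conditions:
            if cond not in self.replicates or not self.replicates[cond]:
                raise ConfigurationError(f"condition {cond!r} has no replicates")
            for rep in self.replicates[cond]:
                for strand in STRANDS:
                    for lib in LIBRARIES:
                        if (cond, rep, strand, lib) not in self.files:
                            raise ConfigurationError(
                                "missing file for slot "
                                f"(condition={cond}, replicate={rep}, "
                                f"strand={strand}, library={lib})"
                            )

    def slots(self):
        for cond in self.conditions:
            for rep in self.replicates[cond]:
                for strand in STRANDS:
                    yield cond, rep, strand


@dataclass
class LibraryPair:
    """Matched enriched + control tracks for one replicate, strand, replicon."""

    condition: str
    replicate: str
    strand: str
    enriched: CoverageTrack
    control: CoverageTrack

    def __post_init__(self) -> None:
        if self.enriched.replicon_id != self.control.replicon_id:
            raise ValidationError("library pair mixes replicons")
        if self.enriched.strand != self.control.strand:
            raise ValidationError("library pair mixes strands")
        if self.enriched.length != self.control.length:
            raise ValidationError(
                f"library pair {self.key}: track lengths differ "
                f"({self.enriched.length} vs {self.control.length})"
            )

    @property
    def replicon_id(self) -> str:
        return self.enriched.replicon_id

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.condition, self.replicate, self.strand, self.replicon_id)

    def copy(self) -> "LibraryPair":
        return LibraryPair(self.condition, self.replicate, self.strand,
                           self.enriched.copy(), self.control.copy())


@dataclass
class TssCandidate:
    """A per-replicate putative TSS with its step metrics."""

    replicon_id: str
    position: int
    strand: str
    step_height: float
    step_factor: float
    condition: str = ""
    replicate: str = ""
    enrichment_factor: float | None = None
    detected: bool = True
    enriched: bool = False


@dataclass
class TssClassification:
    """Gene-relative class of a TSS (one entry per associated gene)."""

    tss_class: str  # primary | secondary | internal | antisense | orphan
    locus_tag: str = ""
    gene_name: str = ""
    product: str = ""
    utr_length: int | None = None
    offset: int = 0
    gene_length: int | None = None


@dataclass
class ConditionRecord:
    """Per-condition status of a consolidated TSS."""

    detected: bool = False
    enriched: bool = False
    step_height: float = 0.0
    step_factor: float = 0.0
    enrichment_factor: float = 0.0
    det_count: int = 0
    position: int = 0  # condition-local position within the cluster
    classes: list[str] = field(default_factory=list)


@dataclass
class ConsolidatedTss:
    """A clustered TSS with per-condition records and classifications."""

    replicon_id: str
    position: int
    strand: str
    records: dict[str, ConditionRecord] = field(default_factory=dict)
    classifications: list[TssClassification] = field(default_factory=list)

    @property
    def max_enriched_height(self) -> float:
        """Strongest step height among conditions where the TSS is enriched."""
        heights = [r.step_height for r in self.records.values() if r.enriched]
        return max(heights) if heights else 0.0

    @property
    def enriched_conditions(self) -> list[str]:
        return [c for c, r in self.records.items() if r.enriched]

    @property
    def detected_conditions(self) -> list[str]:
        return [c for c, r in self.records.items() if r.detected]
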