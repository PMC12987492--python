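"""Synthetic multi-condition 5'-enrichment experiments with known truth.

The generator emulates the structure of a Cappable-seq-style comparative
experiment: several conditions x replicates x strands, an enriched coverage
profile with a sharp 5' step at each planted TSS followed by exponentially
decaying gene-body coverage, and a control profile equal to the enriched
signal divided by the planted enrichment factor.  Uniform low-level
background noise and per-replicate library scale factors stress the
normalization and thresholding stages.  It is *not* a read simulator: there
is no fragment model, no mapping ambiguity, and processed-transcript 5' ends
are not modeled separately in the control.

Everything is reproducible from the spec's seed; two runs with the same spec
write byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .model import (CONTROL, ENRICHED, FORWARD, REVERSE, ConditionRecord,
                    ConsolidatedTss, CoverageTrack, ExperimentLayout,
                    GeneRecord, LibraryPair)
from .params import ParameterSet

SIGNAL_SPAN = 400  # bp of decaying gene-body coverage downstream of a TSS


@dataclass
class PlantedTss:
    """Ground truth for one planted TSS."""

    position: int
    strand: str
    height: float
    enrichment_factor: float = 5.0
    expected_class: str = "orphan"
    conditions: list[str] | None = None  # None = present in all conditions
    condition_heights: dict[str, float] = field(default_factory=dict)

    def height_in(self, condition: str) -> float:
        if self.conditions is not None and condition not in self.conditions:
            return 0.0
        return self.condition_heights.get(condition, self.height)


@dataclass
class SyntheticSpec:
    """Full description of a synthetic experiment."""

    replicon_id: str = "chr"
    length: int = 20_000
    genes: list[GeneRecord] = field(default_factory=list)
    tss: list[PlantedTss] = field(default_factory=list)
    conditions: list[str] = field(default_factory=lambda: ["ctrl"])
    replicates: list[str] = field(default_factory=lambda: ["r1"])
    noise: float = 0.0          # upper bound of uniform background coverage
    decay: float = 0.99         # per-base retention of gene-body coverage
    replicate_scales: dict[str, float] = field(default_factory=dict)
    poisson_jitter: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.decay <= 1:
            raise ValidationError("decay must lie in (0, 1]")
        if self.noise < 0:
            raise ValidationError("noise must be >= 0")
        for t in self.tss:
            if not 1 <= t.position <= self.length:
                raise ValidationError(
                    f"planted TSS at {t.position} outside replicon "
                    f"of length {self.length}")
            if t.enrichment_factor < 1:
                raise ValidationError("planted enrichment factor must be >= 1")
        for scale in self.replicate_scales.values():
            if scale <= 0:
                raise ValidationError("replicate scale factors must be > 0")
        _check_expected_classes(self)


def _check_expected_classes(spec: SyntheticSpec) -> None:
    """Verify planted classes against the classifier on the planted layout."""
    from .classify import classify  # deferred: classify imports nothing heavy

    fakes = []
    for t in spec.tss:
        record = ConditionRecord(detected=True, enriched=True,
                                 step_height=t.height, position=t.position)
        fakes.append(ConsolidatedTss(spec.replicon_id, t.position, t.strand,
                                     {"truth": record}))
    classify(fakes, spec.genes, ParameterSet())
    for planted, fake in zip(spec.tss, fakes):
        produced = {c.tss_class for c in fake.classifications}
        if planted.expected_class not in produced:
            raise ValidationError(
                f"planted TSS at {planted.position}{planted.strand} expects "
                f"class {planted.expected_class!r} but the gene layout "
                f"yields {sorted(produced)}")


def _signal(spec: SyntheticSpec, condition: str) -> dict[str, np.ndarray]:
    """Noise-free enriched signal per strand for one condition."""
    signal = {FORWARD: np.zeros(spec.length), REVERSE: np.zeros(spec.length)}
    for t in spec.tss:
        h = t.height_in(condition)
        if h <= 0:
            continue
        offsets = np.arange(SIGNAL_SPAN)
        values = h * spec.decay ** offsets
        if t.strand == FORWARD:
            lo = t.position - 1
            hi = min(spec.length, lo + SIGNAL_SPAN)
            signal[FORWARD][lo:hi] += values[:hi - lo]
        else:
            hi = t.position
            lo = max(0, hi - SIGNAL_SPAN)
            signal[REVERSE][lo:hi] += values[:hi - lo][::-1]
    return signal


def _control_signal(spec: SyntheticSpec, condition: str) -> dict[str, np.ndarray]:
    control = {FORWARD: np.zeros(spec.length), REVERSE: np.zeros(spec.length)}
    for t in spec.tss:
        h = t.height_in(condition)
        if h <= 0:
            continue
        offsets = np.arange(SIGNAL_SPAN)
        values = (h / t.enrichment_factor) * spec.decay ** offsets
        if t.strand == FORWARD:
            lo = t.position - 1
            hi = min(spec.length, lo + SIGNAL_SPAN)
            control[FORWARD][lo:hi] += values[:hi - lo]
        else:
            hi = t.position
            lo = max(0, hi - SIGNAL_SPAN)
            control[REVERSE][lo:hi] += values[:hi - lo][::-1]
    return control


def generate_tracks(spec: SyntheticSpec) -> list[LibraryPair]:
    """Build the in-memory library pairs of a synthetic experiment."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pairs = []
    for condition in spec.conditions:
        enriched_signal = _signal(spec, condition)
        control_signal = _control_signal(spec, condition)
        for replicate in spec.replicates:
            scale = spec.replicate_scales.get(replicate, 1.0)
            for strand in (FORWARD, REVERSE):
                enriched = enriched_signal[strand].copy()
                control = control_signal[strand].copy()
                if spec.noise > 0:
                    enriched += rng.uniform(0, spec.noise, spec.length)
                    control += rng.uniform(0, spec.noise, spec.length)
                if spec.poisson_jitter:
                    enriched = rng.poisson(enriched).astype(float)
                    control = rng.poisson(control).astype(float)
                enriched *= scale
                control *= scale
                pairs.append(LibraryPair(
                    condition, replicate, strand,
                    CoverageTrack(spec.replicon_id, strand, enriched),
                    CoverageTrack(spec.replicon_id, strand, control)))
    return pairs


def generate_experiment(spec: SyntheticSpec, directory: str | Path,
                        ) -> tuple[ExperimentLayout, Path]:
    """Write a complete experiment to disk: wiggle files for every slot, a
    GFF3 of the planted genes, a random genome FASTA and a truth TSV.

    Returns the experiment layout and the truth-table path.
    """
    from .formats import _write_wiggle  # writer shared with normalized export

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pairs = generate_tracks(spec)

    layout = ExperimentLayout(list(spec.conditions),
                              {c: list(spec.replicates)
                               for c in spec.conditions})
    slug = {FORWARD: "fwd", REVERSE: "rev"}
    for pair in pairs:
        for lib, track in ((ENRICHED, pair.enriched), (CONTROL, pair.control)):
            name = f"{pair.condition}_{pair.replicate}_{slug[pair.strand]}_{lib}"
            path = directory / f"{name}.wig"
            _write_wiggle([track], path, name)
            layout.assign(pair.condition, pair.replicate, pair.strand,
                          lib, path)

    gff = directory / "genes.gff"
    lines = ["##gff-version 3"]
    for gene in spec.genes:
        lines.append("\t".join([
            spec.replicon_id, "synthetic", "gene", str(gene.start),
            str(gene.end), ".", gene.strand, ".",
            f"ID={gene.locus_tag};locus_tag={gene.locus_tag};"
            f"gene={gene.name};product={gene.product}"]))
    gff.write_text("\n".join(lines) + "\n")

    rng = np.random.default_rng(spec.seed + 1)
    sequence = "".join(rng.choice(list("ACGT"), size=spec.length))
    fasta = directory / "genome.fa"
    fasta.write_text(f">{spec.replicon_id}\n" + "\n".join(
        sequence[i:i + 70] for i in range(0, len(sequence), 70)) + "\n")

    truth = directory / "truth.tsv"
    rows = ["position\tstrand\theight\tenrichment_factor\texpected_class\t"
            "conditions"]
    for t in spec.tss:
        conds = ",".join(t.conditions if t.conditions is not None
                         else spec.conditions)
        rows.append(f"{t.position}\t{t.strand}\t{t.height}\t"
                    f"{t.enrichment_factor}\t{t.expected_class}\t{conds}")
    truth.write_text("\n".join(rows) + "\n")
    return layout, truth


def score_recovery(truth: Sequence[PlantedTss],
                   predicted: Sequence[ConsolidatedTss],
                   tolerance: int = 0) -> tuple[float, float, float]:
    """(recall, precision, class accuracy) of a prediction against the truth.

    A planted TSS is recovered when a predicted TSS lies within ``tolerance``
    bp on the same strand; class accuracy is the fraction of recovered TSS
    whose expected class appears among the predicted classifications.
    """
    recovered = 0
    class_hits = 0
    matched_predictions: set[int] = set()
    for planted in truth:
        match = None
        for idx, pred in enumerate(predicted):
            if (pred.strand == planted.strand
                    and abs(pred.position - planted.position) <= tolerance):
                match = idx
                break
        if match is None:
            continue
        recovered += 1
        matched_predictions.add(match)
        produced = {c.tss_class for c in predicted[match].classifications}
        if planted.expected_class in produced:
            class_hits += 1
    recall = recovered / len(truth) if truth else 0.0
    precision = (len(matched_predictions) / len(predicted)
                 if predicted else 0.0)
    class_accuracy = class_hits / recovered if recovered else 0.0
    return recall, precision, class_accuracy


# ---------------------------------------------------------------------------
# canonical example experiment


def example_genes(replicon_id: str = "chr") -> list[GeneRecord]:
    spans = [
        ("g1", 1000, 1900, FORWARD), ("g2", 2500, 3400, FORWARD),
        ("g3", 5000, 5900, REVERSE), ("g4", 7000, 7900, FORWARD),
        ("g5", 9500, 10400, REVERSE), ("g6", 12000, 12900, FORWARD),
        ("g7", 14500, 15400, REVERSE), ("g8", 17000, 17900, FORWARD),
    ]
    return [GeneRecord(replicon_id, tag, tag.upper(), f"{tag} product",
                       start, end, strand)
            for tag, start, end, strand in spans]


def example_tss(conditions: Sequence[str]) -> list[PlantedTss]:
    """Twenty planted TSS spanning all five classes on both strands."""
    plan = [
        (900, FORWARD, 120, "primary"),    # 100 bp upstream of g1
        (750, FORWARD, 60, "secondary"),   # 250 bp upstream of g1, weaker
        (1400, FORWARD, 80, "internal"),   # inside g1
        (1600, REVERSE, 70, "antisense"),  # inside g1, opposite strand
        (4300, FORWARD, 150, "orphan"),
        (6000, REVERSE, 200, "primary"),   # 100 bp upstream of g3 (reverse)
        (6150, REVERSE, 90, "secondary"),
        (5500, REVERSE, 75, "internal"),
        (5300, FORWARD, 85, "antisense"),
        (6900, FORWARD, 110, "primary"),   # g4
        (6950, REVERSE, 96, "antisense"),  # 50 bp 3' of g4, opposite strand
        (10500, REVERSE, 95, "primary"),   # g5
        (10000, REVERSE, 65, "internal"),
        (11500, FORWARD, 130, "orphan"),
        (11900, FORWARD, 140, "primary"),  # g6
        (11750, FORWARD, 70, "secondary"),
        (12500, FORWARD, 55, "internal"),
        (15500, REVERSE, 105, "primary"),  # g7
        (15000, FORWARD, 88, "antisense"),
        (16900, FORWARD, 125, "primary"),  # g8
    ]
    tss = []
    for idx, (pos, strand, height, cls) in enumerate(plan):
        conds = None
        heights = {}
        if len(conditions) > 1:
            # two condition-specific TSS and mild condition-to-condition
            # height variation exercise the cross-condition machinery
            if idx == 4:
                conds = [conditions[0]]
            elif idx == 13:
                conds = list(conditions[1:])
            heights = {c: height * (1.0 + 0.05 * j)
                       for j, c in enumerate(conditions)}
        tss.append(PlantedTss(pos, strand, height, enrichment_factor=5.0,
                              expected_class=cls, conditions=conds,
                              condition_heights=heights))
    return tss


def example_spec(n_conditions: int = 4, n_replicates: int = 3,
                 noise: float = 0.0, seed: int = 0,
                 length: int = 20_000) -> SyntheticSpec:
    """The canonical fixture: 4 conditions x 3 replicates, 20 planted TSS
    spanning all five classes, enrichment factor 5, replicate library sizes
    varying 1x-1.5x."""
    conditions = [f"c{i + 1}" for i in range(n_conditions)]
    replicates = [f"r{i + 1}" for i in range(n_replicates)]
    scales = {rep: 1.0 + 0.25 * i for i, rep in enumerate(replicates)}
    return SyntheticSpec(
        replicon_id="chr", length=length, genes=example_genes("chr"),
        tss=example_tss(conditions), conditions=conditions,
        replicates=replicates, noise=noise, replicate_scales=scales,
        seed=seed)


def null_profile_windows(n_tss: int, n_replicates_a: int, n_replicates_b: int,
                         half_window: int = 50, depth: float = 30.0,
                         seed: int = 0):
    """Simulate per-replicate coverage windows for null differential testing.

    Every TSS gets one true decaying profile; each replicate of both
    conditions observes an independent Poisson draw of it.  Yields
    (windows_a, windows_b) per TSS, in the (probabilities, mass) form
    consumed by :func:`tsscall.stats.pairwise_ks`.
    """
    rng = np.random.default_rng(seed)
    offsets = np.arange(2 * half_window + 1)
    out = []
    for _ in range(n_tss):
        scale = rng.uniform(10, 40)
        profile = depth * np.exp(-(offsets - half_window).clip(0) / scale)
        profile[:half_window] = depth * 0.05  # low upstream background

        def draw(n):
            windows = []
            for _ in range(n):
                counts = rng.poisson(profile).astype(float)
                mass = counts.sum()
                if mass == 0:
                    counts[half_window] = 1.0
                    mass = 1.0
                windows.append((counts / mass, float(mass)))
            return windows

        out.append((draw(n_replicates_a), draw(n_replicates_b)))
    return out
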