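"""Reading and writing the standard file formats around the pipeline.

Supported inputs: wiggle (``variableStep`` and ``fixedStep``), 4-column
bedGraph, GFF3 gene annotations and FASTA genomes.  Outputs: the MasterTable
TSV (one row per TSS, condition and classification), per-condition GFF3 files
of predicted TSS and normalized coverage tracks in wiggle format.

Internal coordinates are 1-based inclusive; bedGraph's 0-based half-open
intervals are converted on load.  Negative coverage values (a common export
convention for the reverse strand) are replaced by their absolute value,
logged once per file.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import BoundsError, ParseError
from .model import (CONTROL, ENRICHED, FORWARD, REVERSE, ConsolidatedTss,
                    CoverageTrack, ExperimentLayout, GeneRecord, LibraryPair)

logger = logging.getLogger(__name__)

MASTER_TABLE_COLUMNS = [
    "SuperPos", "SuperStrand", "mapCount", "detCount", "Condition",
    "detected", "enriched", "stepHeight", "stepFactor", "enrichmentFactor",
    "Pos", "Strand", "Locus_tag", "GeneName", "Product", "Class",
    "UTRlength", "GeneLength", "Sequence-50nt",
]

_STRAND_SLUG = {FORWARD: "fwd", REVERSE: "rev"}


# ---------------------------------------------------------------------------
# coverage input


def _densify(sparse: dict[str, tuple[list[int], list[float]]],
             expected_length: int | None, strand: str,
             path: Path) -> list[CoverageTrack]:
    tracks = []
    for replicon, (positions, values) in sparse.items():
        if not positions:
            continue
        top = max(positions)
        if expected_length is not None:
            if top > expected_length:
                raise BoundsError(
                    f"{path}: position {top} on {replicon} exceeds "
                    f"expected length {expected_length}")
            length = expected_length
        else:
            length = top
        dense = np.zeros(length, dtype=np.float64)
        dense[np.asarray(positions) - 1] = values
        tracks.append(CoverageTrack(replicon, strand, dense))
    return tracks


def read_wiggle(path: str | Path, expected_length: int | None = None,
                strand: str = FORWARD) -> list[CoverageTrack]:
    """Parse a wiggle file into dense per-replicon coverage tracks.

    Both ``variableStep`` and ``fixedStep`` blocks are accepted, several
    blocks per file are allowed (one :class:`CoverageTrack` per replicon),
    ``track`` header lines are skipped, unlisted positions are zero and
    negative values are stored as absolute values.
    """
    path = Path(path)
    sparse: dict[str, tuple[list[int], list[float]]] = {}
    mode = None  # ("variable", chrom, span) | ("fixed", chrom, next_pos, step, span)
    saw_negative = False

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if fields[0] in ("variableStep", "fixedStep"):
                attrs = {}
                for item in fields[1:]:
                    if "=" not in item:
                        raise ParseError(
                            f"{path}:{lineno}: malformed declaration {line!r}")
                    key, _, value = item.partition("=")
                    attrs[key] = value
                if "chrom" not in attrs:
                    raise ParseError(
                        f"{path}:{lineno}: declaration missing chrom")
                chrom = attrs["chrom"]
                span = int(attrs.get("span", 1))
                sparse.setdefault(chrom, ([], []))
                if fields[0] == "variableStep":
                    mode = ("variable", chrom, span)
                else:
                    try:
                        start = int(attrs["start"])
                        step = int(attrs.get("step", 1))
                    except (KeyError, ValueError) as exc:
                        raise ParseError(
                            f"{path}:{lineno}: bad fixedStep declaration "
                            f"{line!r}") from exc
                    mode = ("fixed", chrom, start, step, span)
                continue
            if mode is None:
                raise ParseError(
                    f"{path}:{lineno}: data line before any step declaration")
            if mode[0] == "variable":
                _, chrom, span = mode
                if len(fields) != 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected 'position value'")
                try:
                    pos, value = int(fields[0]), float(fields[1])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {line!r}") from exc
            else:
                _, chrom, pos, step, span = mode
                if len(fields) != 1:
                    raise ParseError(f"{path}:{lineno}: expected single value")
                try:
                    value = float(fields[0])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {line!r}") from exc
                mode = ("fixed", chrom, pos + step, step, span)
            if pos < 1:
                raise ParseError(f"{path}:{lineno}: position {pos} < 1")
            if value < 0:
                saw_negative = True
                value = abs(value)
            positions, values = sparse[chrom]
            for offset in range(span):
                positions.append(pos + offset)
                values.append(value)

    if saw_negative:
        logger.info("%s: negative values converted to absolute values", path)
    return _densify(sparse, expected_length, strand, path)


def read_bedgraph(path: str | Path, expected_length: int | None = None,
                  strand: str = FORWARD) -> list[CoverageTrack]:
    """Parse a 4-column bedGraph (0-based half-open) into dense tracks.

    Interval ``[s, e)`` with value v fills 1-based positions ``s+1 .. e``.
    Overlapping intervals on one replicon are an error (ambiguous value).
    """
    path = Path(path)
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    saw_negative = False
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {line!r}") from exc
            if start < 0 or end <= start:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})")
            if value < 0:
                saw_negative = True
                value = abs(value)
            intervals.setdefault(chrom, []).append((start, end, value))

    if saw_negative:
        logger.info("%s: negative values converted to absolute values", path)

    tracks = []
    for replicon, ivs in intervals.items():
        ivs.sort()
        top = ivs[-1][1]
        if expected_length is not None:
            if top > expected_length:
                raise BoundsError(
                    f"{path}: interval end {top} on {replicon} exceeds "
                    f"expected length {expected_length}")
            length = expected_length
        else:
            length = top
        dense = np.zeros(length, dtype=np.float64)
        prev_end = -1
        for start, end, value in ivs:
            if start < prev_end:
                raise ParseError(
                    f"{path}: overlapping intervals on {replicon} at {start}")
            dense[start:end] = value
            prev_end = end
        tracks.append(CoverageTrack(replicon, strand, dense))
    return tracks


# ---------------------------------------------------------------------------
# annotation input


def _parse_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for item in field.strip().split(";"):
        item = item.strip()
        if not item or "=" not in item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff(path: str | Path) -> list[GeneRecord]:
    """Extract gene records from a GFF3 annotation.

    Rows of type ``gene`` are preferred; replicons without any gene rows fall
    back to their ``CDS`` rows.  The locus tag comes from the ``locus_tag``
    attribute, falling back to ``ID``; the gene name from ``gene``/``Name``;
    the product from the feature itself or a child CDS (matched by Parent).
    """
    path = Path(path)
    rows: list[tuple[str, str, int, int, str, dict[str, str]]] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns")
            replicon, _, ftype, start, end, _, strand, _ = fields[:8]
            if ftype not in ("gene", "CDS"):
                continue
            if strand not in (FORWARD, REVERSE):
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            rows.append((replicon, ftype,
                         min(start_i, end_i), max(start_i, end_i),
                         strand, _parse_attributes(fields[8])))

    # products of CDS rows, indexed by their Parent for gene-row resolution
    cds_products = {}
    for replicon, ftype, start, end, strand, attrs in rows:
        if ftype == "CDS" and "product" in attrs and "Parent" in attrs:
            cds_products.setdefault(attrs["Parent"], attrs["product"])

    replicons_with_genes = {r for r, t, *_ in rows if t == "gene"}
    genes = []
    for replicon, ftype, start, end, strand, attrs in rows:
        wanted = "gene" if replicon in replicons_with_genes else "CDS"
        if ftype != wanted:
            continue
        locus = attrs.get("locus_tag") or attrs.get("ID", "")
        name = attrs.get("gene") or attrs.get("Name", "")
        product = attrs.get("product", "")
        if not product and "ID" in attrs:
            product = cds_products.get(attrs["ID"], "")
        genes.append(GeneRecord(replicon, locus, name, product,
                                start, end, strand))
    return genes


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA as a mapping replicon id -> uppercase sequence."""
    return {record.id: str(record.seq).upper()
            for record in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# output


def _fmt(value: float | None) -> str:
    if value is None:
        return "NA"
    if math.isinf(value):
        return "inf"
    return f"{value:.2f}"


def write_master_table(tss: Sequence[ConsolidatedTss], layout: ExperimentLayout,
                       path: str | Path, genome: dict[str, str] | None = None,
                       sequence_length: int = 50) -> None:
    """Write the MasterTable TSV: one row per (TSS, condition, classification).

    Numeric fields are rendered with two decimals.  The upstream-sequence
    column is filled only when a genome is supplied.
    """
    from .classify import upstream_sequence  # local import avoids a cycle

    path = Path(path)
    lines = ["\t".join(MASTER_TABLE_COLUMNS)]
    for t in sorted(tss, key=lambda t: (t.replicon_id, t.position, t.strand)):
        map_count = len(t.detected_conditions)
        seq = ""
        if genome is not None:
            seq = upstream_sequence(t, genome, sequence_length)
        classifications = t.classifications or [None]
        for condition in layout.conditions:
            record = t.records.get(condition)
            for cls in classifications:
                row = [
                    str(t.position),
                    t.strand,
                    str(map_count),
                    str(record.det_count if record else 0),
                    condition,
                    "1" if record and record.detected else "0",
                    "1" if record and record.enriched else "0",
                    _fmt(record.step_height if record else 0.0),
                    _fmt(record.step_factor if record else 0.0),
                    _fmt(record.enrichment_factor if record else 0.0),
                    str(record.position if record and record.detected
                        else t.position),
                    t.strand,
                    cls.locus_tag if cls else "",
                    cls.gene_name if cls else "",
                    cls.product if cls else "",
                    cls.tss_class if cls else "",
                    str(cls.utr_length) if cls and cls.utr_length is not None
                    else "NA",
                    str(cls.gene_length) if cls and cls.gene_length is not None
                    else "NA",
                    seq,
                ]
                lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def write_gff_output(tss: Sequence[ConsolidatedTss], condition: str,
                     path: str | Path, source: str = "tsscall") -> None:
    """Write the TSS enriched in one condition as 1-bp GFF3 features."""
    path = Path(path)
    lines = ["##gff-version 3"]
    for t in sorted(tss, key=lambda t: (t.replicon_id, t.position)):
        record = t.records.get(condition)
        if record is None or not record.enriched:
            continue
        classes = sorted({c.tss_class for c in t.classifications})
        loci = sorted({c.locus_tag for c in t.classifications if c.locus_tag})
        attrs = [f"ID=tss_{t.replicon_id}_{t.position}"
                 f"{'f' if t.strand == FORWARD else 'r'}",
                 f"tss_class={','.join(classes)}"]
        if loci:
            attrs.append(f"locus_tag={','.join(loci)}")
        lines.append("\t".join([
            t.replicon_id, source, "TSS", str(t.position), str(t.position),
            _fmt(record.step_height), t.strand, ".", ";".join(attrs)]))
    path.write_text("\n".join(lines) + "\n")


def _write_wiggle(tracks: Iterable[CoverageTrack], path: Path,
                  name: str) -> None:
    with open(path, "w") as handle:
        handle.write(f'track type=wiggle_0 name="{name}"\n')
        for track in tracks:
            handle.write(f"variableStep chrom={track.replicon_id}\n")
            nonzero = np.nonzero(track.values)[0]
            for idx in nonzero:
                handle.write(f"{idx + 1} {track.values[idx]:.6f}\n")


def write_normalized_tracks(pairs: Sequence[LibraryPair],
                            directory: str | Path) -> list[Path]:
    """Export normalized libraries, one wiggle per (condition, replicate,
    strand, library); zero positions are omitted (sparse variableStep)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    groups: dict[tuple[str, str, str, str], list[CoverageTrack]] = {}
    for pair in pairs:
        key_e = (pair.condition, pair.replicate, pair.strand, ENRICHED)
        key_c = (pair.condition, pair.replicate, pair.strand, CONTROL)
        groups.setdefault(key_e, []).append(pair.enriched)
        groups.setdefault(key_c, []).append(pair.control)
    written = []
    for (cond, rep, strand, lib), tracks in sorted(groups.items()):
        name = f"{cond}_{rep}_{_STRAND_SLUG[strand]}_{lib}"
        path = directory / f"{name}.wig"
        _write_wiggle(tracks, path, name)
        written.append(path)
    return written


def load_layout_pairs(layout: ExperimentLayout,
                      expected_length: int | None = None) -> list[LibraryPair]:
    """Read every layout slot and assemble per-replicon library pairs.

    Tracks of one replicon are zero-padded to a common length so matched
    enriched/control tracks always align.
    """
    layout.validate()
    raw: dict[tuple[str, str, str, str], dict[str, CoverageTrack]] = {}
    lengths: dict[str, int] = {}
    for cond, rep, strand in layout.slots():
        for lib in (ENRICHED, CONTROL):
            path = layout.files[(cond, rep, strand, lib)]
            reader = read_bedgraph if path.suffix.lower() in (
                ".bedgraph", ".bg") else read_wiggle
            for track in reader(path, expected_length, strand):
                raw.setdefault((cond, rep, strand, track.replicon_id),
                               {})[lib] = track
                lengths[track.replicon_id] = max(
                    lengths.get(track.replicon_id, 0), track.length)

    pairs = []
    for (cond, rep, strand, replicon), libs in sorted(raw.items()):
        length = lengths[replicon]
        for lib in (ENRICHED, CONTROL):
            track = libs.get(lib)
            if track is None:
                libs[lib] = CoverageTrack(replicon, strand,
                                          np.zeros(length))
            elif track.length < length:
                padded = np.zeros(length)
                padded[:track.length] = track.values
                libs[lib] = CoverageTrack(replicon, strand, padded)
        pairs.append(LibraryPair(cond, rep, strand,
                                 libs[ENRICHED], libs[CONTROL]))
    return pairs
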