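"""Gene-relative classification of consolidated TSS.

Five classes, following the classical manual-annotation scheme:

* **primary** / **secondary** — same strand, within ``utr_length`` bp (default
  300) upstream of a gene's annotated translation start.  Exactly one primary
  per gene: the strongest enriched step height (configurable to the 5'-most
  signal); the remaining upstream TSS of that gene are secondary.
* **internal** — same strand, within the gene body.
* **antisense** — opposite strand, inside the gene or within
  ``antisense_distance`` bp (default 150, boundary included) of it.
* **orphan** — associated with no gene; always a TSS's sole class.

A TSS may carry several classes at once (e.g. primary for one gene and
antisense for a gene on the opposite strand).  A TSS exactly at a gene's
start is internal, not primary (upstream distance must be strictly positive).
"""

from __future__ import annotations

from typing import Mapping, Sequence

from Bio.Seq import Seq

from .model import (FORWARD, ConsolidatedTss, GeneRecord, TssClassification)
from .params import ParameterSet

CLASS_NAMES = ("primary", "secondary", "internal", "antisense", "orphan")


def _upstream_distance(position: int, strand: str, gene: GeneRecord) -> int | None:
    """Distance (bp) from a same-strand TSS to the gene's translation start;
    None when the TSS is not strictly upstream."""
    if strand != gene.strand:
        return None
    if gene.strand == FORWARD:
        d = gene.start - position
    else:
        d = position - gene.end
    return d if d > 0 else None


def _is_internal(position: int, strand: str, gene: GeneRecord) -> bool:
    return strand == gene.strand and gene.start <= position <= gene.end


def _is_antisense(position: int, strand: str, gene: GeneRecord,
                  distance: int) -> bool:
    if strand == gene.strand:
        return False
    if gene.start <= position <= gene.end:
        return True
    gap = gene.start - position if position < gene.start else position - gene.end
    return gap <= distance


def _classification(tss_class: str, gene: GeneRecord, position: int,
                    utr: int | None = None) -> TssClassification:
    offset = (position - gene.start if gene.strand == FORWARD
              else gene.end - position)
    return TssClassification(tss_class, gene.locus_tag, gene.name,
                             gene.product, utr, offset, gene.length)


def assign_primary_secondary(candidates: Sequence[tuple[ConsolidatedTss, int]],
                             mode: str = "strongest",
                             ) -> tuple[ConsolidatedTss, list[ConsolidatedTss]]:
    """Pick the primary TSS among a gene's upstream candidates.

    ``candidates`` holds (TSS, utr_length) pairs.  ``mode="strongest"`` takes
    the largest enriched step height (ties toward the smaller UTR);
    ``mode="first"`` takes the 5'-most signal, i.e. the largest UTR.
    """
    if mode == "first":
        primary, _ = max(candidates, key=lambda cu: cu[1])
    else:
        primary, _ = max(candidates,
                         key=lambda cu: (cu[0].max_enriched_height, -cu[1]))
    secondaries = [t for t, _ in candidates if t is not primary]
    return primary, secondaries


def classify(tss: Sequence[ConsolidatedTss], genes: Sequence[GeneRecord],
             params: ParameterSet) -> list[ConsolidatedTss]:
    """Fill ``classifications`` on every TSS (and per-condition class lists).

    Every (TSS, gene) association within range yields one classification;
    TSS with no association get exactly one orphan entry.  Per-condition
    class lists are computed at the condition-local position, so conditions
    whose local position falls outside a window may class differently.
    """
    genes_by_replicon: dict[str, list[GeneRecord]] = {}
    for gene in genes:
        genes_by_replicon.setdefault(gene.replicon_id, []).append(gene)

    # gene -> upstream candidate TSS, competed for the primary slot globally
    upstream: dict[int, list[tuple[ConsolidatedTss, int]]] = {}
    gene_index: dict[int, GeneRecord] = {}
    for t in tss:
        t.classifications = []
        for gene in genes_by_replicon.get(t.replicon_id, []):
            utr = _upstream_distance(t.position, t.strand, gene)
            if utr is not None and utr <= params.utr_length:
                upstream.setdefault(id(gene), []).append((t, utr))
                gene_index[id(gene)] = gene
            if _is_internal(t.position, t.strand, gene):
                t.classifications.append(
                    _classification("internal", gene, t.position))
            if _is_antisense(t.position, t.strand, gene,
                             params.antisense_distance):
                t.classifications.append(
                    _classification("antisense", gene, t.position))

    primary_of: dict[int, ConsolidatedTss] = {}
    for gid, candidates in upstream.items():
        gene = gene_index[gid]
        primary, secondaries = assign_primary_secondary(
            candidates, params.primary_mode)
        primary_of[gid] = primary
        for t, utr in candidates:
            cls = "primary" if t is primary else "secondary"
            t.classifications.append(_classification(cls, gene, t.position, utr))

    for t in tss:
        if not t.classifications:
            t.classifications.append(TssClassification("orphan"))
        _fill_condition_classes(t, genes_by_replicon.get(t.replicon_id, []),
                                params, primary_of)
    return list(tss)


def _fill_condition_classes(t: ConsolidatedTss, genes: Sequence[GeneRecord],
                            params: ParameterSet,
                            primary_of: Mapping[int, ConsolidatedTss]) -> None:
    """Class names per condition, evaluated at the condition-local position.

    The primary/secondary competition is resolved once, at the representative
    positions; a condition-local position merely re-checks the geometry.
    """
    for record in t.records.values():
        record.classes = []
        if not record.enriched:
            continue
        pos = record.position
        names = []
        for gene in genes:
            utr = _upstream_distance(pos, t.strand, gene)
            if utr is not None and utr <= params.utr_length:
                names.append("primary" if primary_of.get(id(gene)) is t
                             else "secondary")
            if _is_internal(pos, t.strand, gene):
                names.append("internal")
            if _is_antisense(pos, t.strand, gene, params.antisense_distance):
                names.append("antisense")
        record.classes = sorted(set(names)) if names else ["orphan"]


def upstream_sequence(tss, genome: Mapping[str, str], n: int = 50) -> str:
    """The n bases 5' of a TSS in transcript orientation.

    Reverse-strand sequences are reverse-complemented; the TSS base itself is
    excluded; the window is truncated at replicon boundaries.
    """
    if tss.replicon_id not in genome:
        raise LookupError(f"replicon {tss.replicon_id!r} not in genome")
    seq = genome[tss.replicon_id]
    if tss.strand == FORWARD:
        start = max(0, tss.position - 1 - n)
        return seq[start:tss.position - 1]
    segment = seq[tss.position:tss.position + n]
    return str(Seq(segment).reverse_complement())
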