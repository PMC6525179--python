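"""Exon-retention quantification from junction-spanning RNA-seq reads.

For an internal exon of interest (Eoi), three junction categories are
counted from spliced (N-gapped) alignments:

* reads splicing from the adjacent upstream exon into the Eoi,
* reads splicing from the Eoi into the adjacent downstream exon,
* reads splicing directly between the two flanking exons (skipping the Eoi).

Percentage exon retention is then

    PIR = 100 * inclusion / (inclusion + exclusion)

with ``inclusion = (upstream-junction reads + downstream-junction reads)/2``
and ``exclusion`` the skip-junction count.  A read supports a junction only
if its splice gap exactly matches the annotated intron and it carries at
least ``min_anchor`` aligned bases on each side of the junction.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Mapping

from .gene_model import Transcript
from .indel_caller import AlignedRead, parse_cigar, _REF_OPS

__all__ = [
    "JunctionCounts",
    "PIRRecord",
    "UnsupportedExonError",
    "aligned_blocks",
    "classify_junction_read",
    "count_junctions",
    "compute_pir",
    "pir_table",
    "write_pir_table",
]

UP_EOI = "up_eoi"
EOI_DOWN = "eoi_down"
SKIP = "skip"


class UnsupportedExonError(ValueError):
    """The exon of interest must be internal (a skip junction needs both
    flanking exons)."""


@dataclass
class JunctionCounts:
    individual_id: str
    transcript_id: str
    eoi_index: int  # 1-based ordinal in transcript orientation
    n_up_eoi: int = 0
    n_eoi_down: int = 0
    n_skip: int = 0

    @property
    def inclusion(self) -> float:
        return (self.n_up_eoi + self.n_eoi_down) / 2

    @property
    def exclusion(self) -> int:
        return self.n_skip


@dataclass
class PIRRecord:
    individual_id: str
    eoi_index: int
    inclusion: float
    exclusion: int
    pir: float | None  # percentage in [0, 100], None when undefined

    @property
    def is_defined(self) -> bool:
        return self.pir is not None


def aligned_blocks(read: AlignedRead) -> list[tuple[int, int]]:
    """Maximal reference-aligned segments (0-based half-open), split at N.

    M/=/X extend the current block; D extends it too (a small deletion does
    not interrupt exonic coverage); N closes a block and opens the next after
    the gap; I/S/H/P do not consume reference.
    """
    blocks: list[tuple[int, int]] = []
    ref = read.pos - 1
    block_start = ref
    for n, op in parse_cigar(read.cigar):
        if op == "N":
            if ref > block_start:
                blocks.append((block_start, ref))
            ref += n
            block_start = ref
        elif op in _REF_OPS:
            ref += n
    if ref > block_start:
        blocks.append((block_start, ref))
    return blocks


def _splice_gaps(read: AlignedRead) -> list[tuple[int, int, int, int]]:
    """(gap_start, gap_end, left_anchor, right_anchor) per N gap."""
    blocks = aligned_blocks(read)
    gaps = []
    for (ls, le), (rs, re) in zip(blocks, blocks[1:]):
        gaps.append((le, rs, le - ls, re - rs))
    return gaps


def _target_junctions(
    t: Transcript, eoi_index: int
) -> dict[tuple[int, int], str]:
    """Map genomic (gap_start, gap_end) -> junction category for the Eoi.

    Categories are labelled in transcript orientation: ``up_eoi`` is the
    junction between the exon upstream of the Eoi (in the direction of
    transcription) and the Eoi itself.
    """
    if not (2 <= eoi_index <= t.n_exons - 1):
        raise UnsupportedExonError(
            f"exon {eoi_index} of {t.transcript_id} is not internal "
            f"(transcript has {t.n_exons} exons)"
        )
    g = t.genomic_index(eoi_index)
    left_exon, eoi, right_exon = t.exons[g - 1], t.exons[g], t.exons[g + 1]
    left_gap = (left_exon.end, eoi.start)
    right_gap = (eoi.end, right_exon.start)
    skip_gap = (left_exon.end, right_exon.start)
    if t.strand == "+":
        return {left_gap: UP_EOI, right_gap: EOI_DOWN, skip_gap: SKIP}
    return {right_gap: UP_EOI, left_gap: EOI_DOWN, skip_gap: SKIP}


def classify_junction_read(
    read: AlignedRead,
    t: Transcript,
    eoi_index: int,
    min_anchor: int = 8,
) -> set[str]:
    """Junction categories a read supports for the exon of interest.

    Returns a subset of ``{"up_eoi", "eoi_down", "skip"}``; the empty set
    means the read is uninformative.  Each splice gap is compared exactly
    (0 bp tolerance) against the Eoi-flanking introns and their fused
    skip gap, and must be anchored by at least *min_anchor* aligned bases
    on both sides.  A read spanning both Eoi junctions supports both
    inclusion categories.
    """
    if read.reference_name != t.chrom:
        return set()
    if not read.is_usable or read.flag & 0x400:  # duplicate-marked
        return set()
    targets = _target_junctions(t, eoi_index)
    supported: set[str] = set()
    for gap_start, gap_end, left_anchor, right_anchor in _splice_gaps(read):
        cat = targets.get((gap_start, gap_end))
        if cat is None:
            continue
        if left_anchor >= min_anchor and right_anchor >= min_anchor:
            supported.add(cat)
    return supported


def count_junctions(
    reads: Iterable[AlignedRead],
    t: Transcript,
    eoi_index: int,
    min_anchor: int = 8,
    individual_id: str = "NA",
) -> JunctionCounts:
    """Tally junction support over a read set (one vote per category per
    alignment record)."""
    jc = JunctionCounts(individual_id, t.transcript_id, eoi_index)
    for read in reads:
        cats = classify_junction_read(read, t, eoi_index, min_anchor)
        if UP_EOI in cats:
            jc.n_up_eoi += 1
        if EOI_DOWN in cats:
            jc.n_eoi_down += 1
        if SKIP in cats:
            jc.n_skip += 1
    return jc


def compute_pir(jc: JunctionCounts) -> PIRRecord:
    """Percentage exon retention from junction tallies.

    PIR = 100 * inclusion / (inclusion + exclusion); undefined (None) when
    no informative read was seen.
    """
    inclusion = jc.inclusion
    exclusion = jc.exclusion
    denom = inclusion + exclusion
    pir = None if denom == 0 else 100.0 * inclusion / denom
    return PIRRecord(jc.individual_id, jc.eoi_index, inclusion, exclusion, pir)


def pir_table(
    reads_per_individual: Mapping[str, Iterable[AlignedRead]],
    t: Transcript,
    eoi_indices: Iterable[int],
    min_anchor: int = 8,
) -> list[PIRRecord]:
    """One PIR record per (individual, exon of interest)."""
    records: list[PIRRecord] = []
    eois = list(eoi_indices)
    for individual, reads in reads_per_individual.items():
        reads = list(reads)
        for eoi in eois:
            jc = count_junctions(reads, t, eoi, min_anchor, individual)
            records.append(compute_pir(jc))
    return records


def write_pir_table(
    records: Iterable[PIRRecord],
    path: str | os.PathLike,
    groups: Mapping[str, str] | None = None,
) -> None:
    """TSV output; *groups* optionally maps individual -> group label."""
    with open(path, "w") as fh:
        fh.write("individual_id\tgroup\teoi_index\tinclusion\texclusion\tpir\n")
        for r in records:
            grp = (groups or {}).get(r.individual_id, ".")
            pir = "NA" if r.pir is None else f"{r.pir:.4f}"
            fh.write(
                f"{r.individual_id}\t{grp}\t{r.eoi_index}\t"
                f"{r.inclusion:g}\t{r.exclusion}\t{pir}\n"
            )
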