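"""Gene models and coordinate arithmetic.

This module reads transcript annotations (GFF3/GTF) into a small
:class:`Transcript` container and exposes the coordinate arithmetic the rest
of the pipeline relies on: exon/intron structure, splice boundaries, and
CDS frame bookkeeping.

All internal coordinates are 0-based, half-open ``[start, end)``.  GFF3 and
GTF files use 1-based inclusive coordinates; conversion happens exactly once,
at I/O time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Literal

import gffutils

__all__ = [
    "GenomicInterval",
    "Transcript",
    "SpliceBoundary",
    "GeneModelError",
    "TranscriptNotFoundError",
    "load_gene_model",
    "splice_boundaries",
    "cds_fraction_removed",
    "write_gff3",
]


class GeneModelError(ValueError):
    """Invalid gene-model structure (overlapping exons, missing CDS, ...)."""


class TranscriptNotFoundError(KeyError):
    """The requested transcript id is absent from the annotation file."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: Literal["+", "-"] = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise GeneModelError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise GeneModelError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of bases shared with *other* (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class Transcript:
    """A single transcript model: exons, CDS and derived introns.

    ``exons`` and ``cds`` are stored in genomic order regardless of strand;
    transcript-orientation ordinals (exon 1 = 5' most exon) are computed on
    demand, so minus-strand transcripts index their exons from the genomic
    right.
    """

    transcript_id: str
    gene_id: str
    strand: Literal["+", "-"]
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise GeneModelError(
                    f"overlapping exons in {self.transcript_id}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        for c in self.cds:
            if not any(e.contains(c) for e in self.exons):
                raise GeneModelError(
                    f"CDS interval [{c.start},{c.end}) not contained in any exon "
                    f"of {self.transcript_id}"
                )

    # -- derived structure -------------------------------------------------

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in genomic order."""
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)

    def exon_by_ordinal(self, ordinal: int) -> GenomicInterval:
        """Exon by 1-based ordinal in transcript orientation."""
        if not (1 <= ordinal <= self.n_exons):
            raise IndexError(
                f"exon ordinal {ordinal} out of range 1..{self.n_exons}"
            )
        idx = ordinal - 1 if self.strand == "+" else self.n_exons - ordinal
        return self.exons[idx]

    def genomic_index(self, ordinal: int) -> int:
        """0-based genomic-order index of the exon with the given ordinal."""
        self.exon_by_ordinal(ordinal)  # range check
        return ordinal - 1 if self.strand == "+" else self.n_exons - ordinal

    def cds_overlap(self, interval: GenomicInterval) -> int:
        """Coding bases covered by *interval*."""
        return sum(c.overlap(interval) for c in self.cds)


@dataclass(frozen=True)
class SpliceBoundary:
    """One exon/intron junction.

    ``position`` is the 0-based genomic coordinate of the junction itself:
    for a boundary at the genomic end of an exon it equals ``exon.end`` (the
    first intronic base); at the genomic start of an exon it equals
    ``exon.start``.  ``side`` is orientation-aware: a donor is the junction
    transcription runs *out of* an exon through, an acceptor the junction it
    runs *into* the next exon through.
    """

    transcript_id: str
    exon_ordinal: int
    side: Literal["donor", "acceptor"]
    position: int


def splice_boundaries(t: Transcript) -> list[SpliceBoundary]:
    """All donor/acceptor junctions of *t*, 2 per intron.

    A single-exon transcript has none.  The first exon (transcript
    orientation) carries only a donor, the last only an acceptor.
    """
    out: list[SpliceBoundary] = []
    n = t.n_exons
    for gi in range(n - 1):
        left, right = t.exons[gi], t.exons[gi + 1]
        if t.strand == "+":
            # transcription left -> right
            out.append(SpliceBoundary(t.transcript_id, gi + 1, "donor", left.end))
            out.append(
                SpliceBoundary(t.transcript_id, gi + 2, "acceptor", right.start)
            )
        else:
            # transcription right -> left; ordinal of genomic exon gi is n - gi
            out.append(
                SpliceBoundary(t.transcript_id, n - gi - 1, "donor", right.start)
            )
            out.append(SpliceBoundary(t.transcript_id, n - gi, "acceptor", left.end))
    return out


def cds_fraction_removed(t: Transcript, deletion: GenomicInterval) -> float:
    """Fraction of the transcript's coding sequence removed by a deletion.

    Raises :class:`GeneModelError` if the transcript has no CDS.
    """
    if t.cds_length == 0:
        raise GeneModelError(f"{t.transcript_id} has no CDS; fraction undefined")
    return t.cds_overlap(deletion) / t.cds_length


# ---------------------------------------------------------------------------
# I/O


def _first_attr(feature, *names: str) -> str | None:
    for name in names:
        vals = feature.attributes.get(name)
        if vals:
            return vals[0]
    return None


def load_gene_model(path: str | os.PathLike, transcript_id: str) -> Transcript:
    """Load one transcript from a GFF3 or GTF file.

    Exon features are required; CDS features are used when present.  GFF3
    parent/ID links and GTF ``transcript_id`` attributes are both understood
    (gffutils handles dialect detection).  Coordinates are converted from
    the file's 1-based inclusive convention to internal 0-based half-open.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    exons: list[GenomicInterval] = []
    cds: list[GenomicInterval] = []
    gene_id = ""
    strand = "+"
    for feat in db.all_features():
        parent = _first_attr(feat, "Parent", "transcript_id")
        if parent != transcript_id:
            continue
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if feat.featuretype.lower() == "exon":
            exons.append(iv)
            strand = feat.strand
            gene_id = _first_attr(feat, "gene_id") or gene_id
        elif feat.featuretype.upper() == "CDS":
            cds.append(iv)
    if not exons:
        raise TranscriptNotFoundError(
            f"no exon features for transcript {transcript_id!r} in {path}"
        )
    if not gene_id:
        try:
            parent_feat = db[transcript_id]
            gene_id = _first_attr(parent_feat, "Parent", "gene_id") or transcript_id
        except gffutils.FeatureNotFoundError:
            gene_id = transcript_id
    return Transcript(transcript_id, gene_id, strand, exons, cds)


def write_gff3(t: Transcript, path: str | os.PathLike) -> None:
    """Write a transcript (mRNA + exon + CDS features) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        span = t.span
        fh.write(
            f"{t.chrom}\tkovalid\tgene\t{span.start + 1}\t{span.end}\t.\t"
            f"{t.strand}\t.\tID={t.gene_id}\n"
        )
        fh.write(
            f"{t.chrom}\tkovalid\tmRNA\t{span.start + 1}\t{span.end}\t.\t"
            f"{t.strand}\t.\tID={t.transcript_id};Parent={t.gene_id}\n"
        )
        for i, e in enumerate(t.exons, 1):
            fh.write(
                f"{t.chrom}\tkovalid\texon\t{e.start + 1}\t{e.end}\t.\t"
                f"{t.strand}\t.\tID={t.transcript_id}.exon{i};"
                f"Parent={t.transcript_id};gene_id={t.gene_id}\n"
            )
        for i, c in enumerate(t.cds, 1):
            fh.write(
                f"{t.chrom}\tkovalid\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                f"{t.strand}\t.\tID={t.transcript_id}.cds{i};"
                f"Parent={t.transcript_id};gene_id={t.gene_id}\n"
            )
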