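"""Indel extraction from aligned amplicon reads and mosaicism tallies.

CRISPR editing of an F0-injected animal leaves a mixture of alleles; Sanger
clones (or amplicon reads) sampled from one individual are genotyped here by
walking each alignment's CIGAR string, collecting insertion/deletion
operations that overlap a defined target window, and summarising the allele
composition as a mutant-read fraction.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pysam

from .gene_model import GenomicInterval

__all__ = [
    "TargetSite",
    "AlignedRead",
    "IndelCall",
    "AlleleTally",
    "CigarError",
    "parse_cigar",
    "parse_cigar_indels",
    "reference_span",
    "spans_window",
    "call_indels_at_site",
    "genotypable_reads",
    "tally_alleles",
    "left_normalize",
    "read_sam",
    "write_indel_table",
    "write_tally_table",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")


class CigarError(ValueError):
    """Malformed CIGAR string."""


@dataclass(frozen=True)
class TargetSite:
    """A CRISPR target window on the reference."""

    site_id: str
    window: GenomicInterval
    guide_sequence: str | None = None


@dataclass
class AlignedRead:
    """A minimal alignment record (SAM conventions: ``pos`` is 1-based)."""

    read_id: str
    individual_id: str
    reference_name: str
    pos: int
    cigar: str
    sequence: str | None = None
    flag: int = 0

    @property
    def is_usable(self) -> bool:
        """False for unmapped, secondary, or supplementary alignments."""
        return not (self.flag & (0x4 | 0x100 | 0x800))


@dataclass(frozen=True)
class IndelCall:
    """A normalised indel, VCF-style anchored at the base before the event.

    For a deletion of length L anchored at 1-based ``pos``, the deleted
    reference bases are ``pos+1 .. pos+L`` (1-based).  For an insertion the
    inserted sequence sits between ``pos`` and ``pos+1``.
    """

    chrom: str
    pos: int
    kind: str  # "ins" | "del"
    length: int
    inserted_seq: str | None = None
    read_id: str = ""
    individual_id: str = ""
    site_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("ins", "del"):
            raise ValueError(f"kind must be ins/del, got {self.kind!r}")
        if self.length < 1:
            raise ValueError("indel length must be >= 1")

    @property
    def net_cds_change(self) -> int:
        return self.length if self.kind == "ins" else -self.length

    @property
    def footprint(self) -> GenomicInterval:
        """0-based half-open reference footprint.

        Deletions cover the deleted bases; insertions are represented by the
        single anchor base (the base immediately left of the insertion point).
        """
        if self.kind == "del":
            return GenomicInterval(self.chrom, self.pos, self.pos + self.length)
        return GenomicInterval(self.chrom, self.pos - 1, self.pos)

    @property
    def allele_token(self) -> str:
        seq = f":{self.inserted_seq}" if self.inserted_seq else ""
        return f"{self.kind}{self.length}@{self.pos}{seq}"


@dataclass
class AlleleTally:
    """Per-individual, per-site allele composition from genotyped reads."""

    individual_id: str
    site_id: str
    n_reads_total: int
    n_reads_wt: int
    allele_table: dict[str, int] = field(default_factory=dict)

    @property
    def mutant_fraction(self) -> float | None:
        """1 - WT fraction; None when no read could be genotyped."""
        if self.n_reads_total == 0:
            return None
        return 1.0 - self.n_reads_wt / self.n_reads_total


# ---------------------------------------------------------------------------
# CIGAR arithmetic


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) tuples, validating tokens."""
    if not cigar or cigar == "*":
        raise CigarError(f"empty or absent CIGAR: {cigar!r}")
    out: list[tuple[int, str]] = []
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise CigarError(f"malformed CIGAR token at {cigar[pos:]!r}")
        out.append((int(m.group(1)), m.group(2)))
        pos = m.end()
    if pos != len(cigar):
        raise CigarError(f"malformed CIGAR token at {cigar[pos:]!r}")
    return out


def reference_span(read: AlignedRead) -> GenomicInterval:
    """0-based half-open reference interval consumed by the alignment."""
    ref_len = sum(n for n, op in parse_cigar(read.cigar) if op in _REF_OPS)
    start = read.pos - 1
    return GenomicInterval(read.reference_name, start, start + ref_len)


def parse_cigar_indels(read: AlignedRead) -> list[IndelCall]:
    """One IndelCall per I/D CIGAR operation, positioned on the reference.

    The reference cursor starts at the read's leftmost aligned base; M/=/X
    consume reference and query, D/N reference only, I/S query only, H and P
    neither.  Each call is anchored at the reference base immediately before
    the event (VCF convention), with the inserted sequence captured from the
    read when available.
    """
    calls: list[IndelCall] = []
    ref = read.pos  # 1-based coordinate of next unconsumed reference base
    qry = 0
    for n, op in parse_cigar(read.cigar):
        if op == "D":
            calls.append(
                IndelCall(
                    read.reference_name,
                    ref - 1,
                    "del",
                    n,
                    read_id=read.read_id,
                    individual_id=read.individual_id,
                )
            )
        elif op == "I":
            seq = None
            if read.sequence is not None:
                seq = read.sequence[qry : qry + n]
            calls.append(
                IndelCall(
                    read.reference_name,
                    ref - 1,
                    "ins",
                    n,
                    inserted_seq=seq,
                    read_id=read.read_id,
                    individual_id=read.individual_id,
                )
            )
        if op in _REF_OPS:
            ref += n
        if op in _QUERY_OPS:
            qry += n
    if read.sequence is not None and qry != len(read.sequence):
        raise CigarError(
            f"CIGAR query length {qry} != sequence length {len(read.sequence)} "
            f"for read {read.read_id}"
        )
    return calls


def left_normalize(call: IndelCall, reference: str) -> IndelCall:
    """Shift an indel left while the flanking reference base matches.

    *reference* is the full 0-based sequence of the call's chromosome.  The
    standard VCF left-alignment: a deletion can move one base left when the
    base before the anchor equals the last deleted base; an insertion when it
    equals the last inserted base (rotating the inserted sequence).
    Normalisation makes allele keys deterministic across reads that place
    the same physical indel differently.
    """
    pos = call.pos  # 1-based anchor
    if call.kind == "del":
        while pos > 1 and reference[pos - 1] == reference[pos - 1 + call.length]:
            pos -= 1
        return IndelCall(
            call.chrom, pos, "del", call.length,
            read_id=call.read_id, individual_id=call.individual_id,
            site_id=call.site_id,
        )
    seq = call.inserted_seq
    if not seq:
        return call
    while pos > 1 and reference[pos - 1] == seq[-1]:
        seq = seq[-1] + seq[:-1]
        pos -= 1
    return IndelCall(
        call.chrom, pos, "ins", call.length, inserted_seq=seq,
        read_id=call.read_id, individual_id=call.individual_id,
        site_id=call.site_id,
    )


# ---------------------------------------------------------------------------
# Site-level calling


def spans_window(read: AlignedRead, site: TargetSite, min_flank: int) -> bool:
    """True if the aligned span covers the target window plus flanks.

    Reads that end (or are clipped) inside the extended window cannot be
    genotyped: a clipped-off indel would silently count as wild type.
    """
    span = reference_span(read)
    w = site.window
    return (
        span.chrom == w.chrom
        and span.start <= w.start - min_flank
        and span.end >= w.end + min_flank
    )


def genotypable_reads(
    reads: Iterable[AlignedRead], site: TargetSite, min_flank: int = 5
) -> list[AlignedRead]:
    """Usable reads whose alignment spans the target window + flanks."""
    return [
        r
        for r in reads
        if r.is_usable and spans_window(r, site, min_flank)
    ]


def _overlaps_window(call: IndelCall, window: GenomicInterval) -> bool:
    if call.kind == "del":
        return call.footprint.overlap(window) > 0
    # insertion: anchored between pos and pos+1 (1-based); 0-based junction
    # coordinate call.pos lies inside the window (boundaries inclusive).
    return window.start <= call.pos <= window.end


def call_indels_at_site(
    reads: Iterable[AlignedRead],
    site: TargetSite,
    min_flank: int = 5,
    reference: str | None = None,
) -> list[IndelCall]:
    """Indels overlapping the target window, from genotypable reads only.

    Reads not spanning ``site.window`` extended by *min_flank* on each side
    are discarded.  When *reference* (the chromosome sequence) is given,
    calls are left-normalised before being reported.
    """
    out: list[IndelCall] = []
    for read in genotypable_reads(reads, site, min_flank):
        for call in parse_cigar_indels(read):
            # window membership is judged on the as-aligned placement;
            # normalisation may legitimately shift the anchor outside it
            hit = _overlaps_window(call, site.window)
            if reference is not None:
                call = left_normalize(call, reference)
            if hit or _overlaps_window(call, site.window):
                out.append(
                    IndelCall(
                        call.chrom, call.pos, call.kind, call.length,
                        inserted_seq=call.inserted_seq,
                        read_id=call.read_id,
                        individual_id=call.individual_id,
                        site_id=site.site_id,
                    )
                )
    return out


WT_KEY = "WT"


def allele_key(calls: Iterable[IndelCall]) -> str:
    """Deterministic key for a (possibly composite) allele."""
    toks = [c.allele_token for c in sorted(calls, key=lambda c: (c.pos, c.kind))]
    return "+".join(toks) if toks else WT_KEY


def tally_alleles(
    calls: Iterable[IndelCall],
    genotyped_reads: Iterable[AlignedRead],
    individual_id: str,
    site: TargetSite,
) -> AlleleTally:
    """Collapse per-read indel calls into an allele table and mutant fraction.

    *genotyped_reads* must be exactly the reads that passed the spanning
    criterion; each contributes one vote.  Reads with no overlapping indel
    vote wild type; identical ordered indel sets collapse to one allele key.
    """
    by_read: dict[str, list[IndelCall]] = {}
    for c in calls:
        by_read.setdefault(c.read_id, []).append(c)
    table: dict[str, int] = {}
    n_total = 0
    n_wt = 0
    for read in genotyped_reads:
        n_total += 1
        key = allele_key(by_read.get(read.read_id, []))
        if key == WT_KEY:
            n_wt += 1
        table[key] = table.get(key, 0) + 1
    return AlleleTally(individual_id, site.site_id, n_total, n_wt, table)


# ---------------------------------------------------------------------------
# I/O


def read_sam(
    path: str | os.PathLike, default_individual: str = "NA"
) -> list[AlignedRead]:
    """Read alignments from SAM/BAM into AlignedRead records.

    The individual id is taken from the read-group (RG) tag when present,
    falling back to *default_individual*.
    """
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.cigarstring is None:
                continue
            indiv = default_individual
            if rec.has_tag("RG"):
                indiv = str(rec.get_tag("RG"))
            out.append(
                AlignedRead(
                    read_id=rec.query_name,
                    individual_id=indiv,
                    reference_name=rec.reference_name,
                    pos=rec.reference_start + 1,
                    cigar=rec.cigarstring,
                    sequence=rec.query_sequence,
                    flag=rec.flag,
                )
            )
    return out


def write_indel_table(calls: Iterable[IndelCall], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tkind\tlength\tinserted_seq\tread_id\tindividual_id\tsite_id\n"
        )
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.kind}\t{c.length}\t"
                f"{c.inserted_seq or '.'}\t{c.read_id}\t{c.individual_id}\t"
                f"{c.site_id}\n"
            )


def read_indel_table(path: str | os.PathLike) -> list[IndelCall]:
    """Read back a TSV written by :func:`write_indel_table`."""
    out: list[IndelCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(
                IndelCall(
                    row["chrom"],
                    int(row["pos"]),
                    row["kind"],
                    int(row["length"]),
                    inserted_seq=None
                    if row["inserted_seq"] == "."
                    else row["inserted_seq"],
                    read_id=row["read_id"],
                    individual_id=row["individual_id"],
                    site_id=row["site_id"],
                )
            )
    return out


def write_tally_table(
    tallies: Iterable[AlleleTally], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "individual_id\tsite_id\tn_reads_total\tn_reads_wt\t"
            "mutant_fraction\talleles\n"
        )
        for t in tallies:
            mf = "NA" if t.mutant_fraction is None else f"{t.mutant_fraction:.6g}"
            alleles = ";".join(
                f"{k}={v}" for k, v in sorted(t.allele_table.items())
            )
            fh.write(
                f"{t.individual_id}\t{t.site_id}\t{t.n_reads_total}\t"
                f"{t.n_reads_wt}\t{mf}\t{alleles}\n"
            )
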