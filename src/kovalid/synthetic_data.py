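"""Seeded generators for toy loci, mosaic amplicon reads, and spliced reads.

Everything the pipeline consumes can be fabricated here in the same standard
formats real data arrive in (FASTA reference, GFF3 gene model, SAM
alignments, TSV truth tables), with a fixed seed giving byte-identical
output.  The amplicon generator emulates Sanger-clone genotyping of a mosaic
F0 animal: each clone read is wild type with probability ``1 - mutant_fraction``
and otherwise carries one indel drawn from a configurable spectrum at the
target site.  The spliced-read generator emulates an RNA-seq experiment over
a multi-exon gene in which a chosen internal exon is skipped in a
configurable fraction of transcripts.

Reads are emitted pre-aligned (correct POS/CIGAR); the mapping stage is
upstream of this toolkit.  Splice-site GT/AG dinucleotides are written at
intron ends so the toy gene models are biologically sane.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pysam

from .gene_model import GenomicInterval, Transcript, write_gff3
from .indel_caller import AlignedRead, TargetSite

__all__ = [
    "IndelSpec",
    "AmpliconConfig",
    "SplicingConfig",
    "SimConfig",
    "ToyLocus",
    "SimConfigError",
    "make_toy_locus",
    "simulate_amplicon_reads",
    "simulate_spliced_reads",
    "write_sam",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))


class SimConfigError(ValueError):
    """Infeasible simulation geometry or parameters."""


@dataclass(frozen=True)
class IndelSpec:
    """One entry of the amplicon indel spectrum.

    ``offset`` is the 0-based position of the event relative to the target
    window start: a deletion removes ``length`` reference bases starting
    there; an insertion inserts ``length`` bases immediately before it.
    ``probability`` is the chance of this allele *given* the read is mutant.
    """

    kind: str  # "ins" | "del"
    length: int
    offset: int
    probability: float

    def __post_init__(self) -> None:
        if self.kind not in ("ins", "del"):
            raise SimConfigError(f"indel kind must be ins/del, got {self.kind!r}")
        if self.length < 1 or self.probability < 0:
            raise SimConfigError("indel length >= 1 and probability >= 0 required")


@dataclass(frozen=True)
class AmpliconConfig:
    indel_spectrum: tuple[IndelSpec, ...] = (IndelSpec("del", 2, 0, 1.0),)
    mutant_fraction: float = 0.625
    n_reads: int = 8
    pad: int = 50  # aligned bases kept on each side of the target window

    def __post_init__(self) -> None:
        if not (0 <= self.mutant_fraction <= 1):
            raise SimConfigError("mutant_fraction must be in [0, 1]")
        total = sum(s.probability for s in self.indel_spectrum)
        if total > 1 + 1e-9:
            raise SimConfigError(
                f"indel spectrum probabilities sum to {total} > 1"
            )


@dataclass(frozen=True)
class SplicingConfig:
    skip_fraction: float = 0.5
    n_fragments: int = 4000
    min_anchor: int = 8  # anchor requirement downstream analyses will apply

    def __post_init__(self) -> None:
        if not (0 <= self.skip_fraction <= 1):
            raise SimConfigError("skip_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_exons: int = 8
    exon_length: int = 120
    intron_length: int = 300
    read_length: int = 100
    flank: int = 100  # sequence padding before the first / after the last exon
    chrom: str = "toy1"
    transcript_id: str = "toyT1"
    gene_id: str = "toyG1"
    strand: str = "+"
    amplicon: AmpliconConfig = field(default_factory=AmpliconConfig)
    splicing: SplicingConfig = field(default_factory=SplicingConfig)

    def __post_init__(self) -> None:
        if self.n_exons < 3:
            raise SimConfigError("need n_exons >= 3 (an internal exon)")
        if self.exon_length < 2 * self.splicing.min_anchor:
            raise SimConfigError(
                f"exon_length {self.exon_length} too short for junction reads "
                f"anchored by {self.splicing.min_anchor} bp on either side"
            )
        if self.read_length > self.exon_length + self.exon_length:
            raise SimConfigError(
                "read_length must not exceed two exon lengths (reads may span "
                "at most two junctions in this simulator)"
            )


@dataclass
class ToyLocus:
    reference: str  # full chromosome sequence
    fasta_path: Path
    gff3_path: Path
    transcript: Transcript


def _random_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def make_toy_locus(cfg: SimConfig, outdir: str | os.PathLike) -> ToyLocus:
    """Deterministic toy reference + multi-exon gene model.

    The CDS spans all exons; its total length is trimmed at the 3' end to a
    multiple of 3 so the reading frame closes.  Intron ends carry canonical
    GT/AG dinucleotides.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    step = cfg.exon_length + cfg.intron_length
    exons = [
        GenomicInterval(
            cfg.chrom,
            cfg.flank + i * step,
            cfg.flank + i * step + cfg.exon_length,
            cfg.strand,
        )
        for i in range(cfg.n_exons)
    ]
    total_len = exons[-1].end + cfg.flank
    seq = _random_sequence(rng, total_len)
    for a, b in zip(exons, exons[1:]):
        seq[a.end], seq[a.end + 1] = "G", "T"
        seq[b.start - 2], seq[b.start - 1] = "A", "G"

    total_exonic = cfg.n_exons * cfg.exon_length
    trim = total_exonic % 3
    cds = [GenomicInterval(e.chrom, e.start, e.end, e.strand) for e in exons]
    if trim:
        last = cds[-1]
        cds[-1] = GenomicInterval(last.chrom, last.start, last.end - trim, last.strand)

    t = Transcript(cfg.transcript_id, cfg.gene_id, cfg.strand, exons, cds)
    reference = "".join(seq)

    fasta_path = outdir / "reference.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{cfg.chrom}\n")
        for i in range(0, len(reference), 70):
            fh.write(reference[i : i + 70] + "\n")
    gff3_path = outdir / "gene_model.gff3"
    write_gff3(t, gff3_path)
    return ToyLocus(reference, fasta_path, gff3_path, t)


# ---------------------------------------------------------------------------
# Amplicon (mosaic clone) reads


def _amplicon_read(
    cfg: SimConfig,
    reference: str,
    site: TargetSite,
    allele: IndelSpec | None,
    read_id: str,
    individual_id: str,
) -> AlignedRead:
    pad = cfg.amplicon.pad
    p0 = max(0, site.window.start - pad)
    p1 = min(len(reference), site.window.end + pad)
    if allele is None:
        return AlignedRead(
            read_id, individual_id, cfg.chrom, p0 + 1, f"{p1 - p0}M",
            sequence=reference[p0:p1],
        )
    cut = site.window.start + allele.offset
    if allele.kind == "del":
        if not (p0 < cut and cut + allele.length < p1):
            raise SimConfigError(
                f"deletion at offset {allele.offset} leaves no aligned flank"
            )
        cigar = f"{cut - p0}M{allele.length}D{p1 - cut - allele.length}M"
        seq = reference[p0:cut] + reference[cut + allele.length : p1]
    else:
        if not (p0 < cut < p1):
            raise SimConfigError(
                f"insertion at offset {allele.offset} leaves no aligned flank"
            )
        # deterministic inserted sequence derived from position and length
        ins = "".join(
            _BASES[(cut + i) % 4] for i in range(allele.length)
        )
        cigar = f"{cut - p0}M{allele.length}I{p1 - cut}M"
        seq = reference[p0:cut] + ins + reference[cut:p1]
    return AlignedRead(read_id, individual_id, cfg.chrom, p0 + 1, cigar, sequence=seq)


def simulate_amplicon_reads(
    cfg: SimConfig,
    locus: ToyLocus,
    site: TargetSite,
    individual_id: str = "fish1",
    outdir: str | os.PathLike | None = None,
) -> tuple[list[AlignedRead], list[dict]]:
    """Mosaic clone reads at a target site, plus a per-read truth table.

    Each read is wild type with probability ``1 - mutant_fraction``;
    otherwise an allele is drawn from the indel spectrum by its conditional
    probability (any residual spectrum mass falls back to wild type).
    When *outdir* is given, a SAM file and a truth TSV are written there.
    """
    a = cfg.amplicon
    if not locus.transcript.span.contains(site.window):
        raise SimConfigError("target window outside the transcript span")
    rng = np.random.default_rng(cfg.seed)
    reads: list[AlignedRead] = []
    truth: list[dict] = []
    cum = np.cumsum([s.probability for s in a.indel_spectrum])
    for i in range(a.n_reads):
        read_id = f"{individual_id}_clone{i + 1}"
        allele: IndelSpec | None = None
        if rng.random() < a.mutant_fraction:
            u = rng.random()
            j = int(np.searchsorted(cum, u, side="right"))
            if j < len(a.indel_spectrum):
                allele = a.indel_spectrum[j]
        reads.append(
            _amplicon_read(cfg, locus.reference, site, allele, read_id, individual_id)
        )
        truth.append(
            {
                "read_id": read_id,
                "individual_id": individual_id,
                "site_id": site.site_id,
                "allele": "WT"
                if allele is None
                else f"{allele.kind}{allele.length}@offset{allele.offset}",
            }
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sam(reads, locus, outdir / f"{individual_id}_amplicon.sam")
        _write_truth(truth, outdir / f"{individual_id}_amplicon_truth.tsv")
    return reads, truth


# ---------------------------------------------------------------------------
# Spliced (junction) reads


def _isoform_exons(t: Transcript, eoi_index: int, skip: bool) -> list[GenomicInterval]:
    if not skip:
        return t.exons
    g = t.genomic_index(eoi_index)
    return t.exons[:g] + t.exons[g + 1 :]


def _place_read(
    exons: list[GenomicInterval],
    start_t: int,
    read_length: int,
    reference: str,
) -> tuple[int, str, str]:
    """Map a transcript-coordinate placement to (1-based pos, CIGAR, seq)."""
    blocks: list[tuple[int, int]] = []
    remaining = read_length
    offset = start_t
    for e in exons:
        elen = len(e)
        if offset >= elen:
            offset -= elen
            continue
        take = min(elen - offset, remaining)
        blocks.append((e.start + offset, e.start + offset + take))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    if remaining:
        raise SimConfigError("read runs off the transcript end")
    cigar_parts = []
    seq_parts = []
    for k, (bs, be) in enumerate(blocks):
        if k:
            gap = bs - blocks[k - 1][1]
            cigar_parts.append(f"{gap}N")
        cigar_parts.append(f"{be - bs}M")
        seq_parts.append(reference[bs:be])
    return blocks[0][0] + 1, "".join(cigar_parts), "".join(seq_parts)


def simulate_spliced_reads(
    cfg: SimConfig,
    locus: ToyLocus,
    eoi_index: int,
    individual_id: str = "fish1",
    outdir: str | os.PathLike | None = None,
) -> tuple[list[AlignedRead], list[dict]]:
    """N-gapped reads over the toy gene with a known exon-skip fraction.

    ``skip_fraction`` is the fraction of transcript *molecules* lacking the
    exon of interest.  As in real RNA-seq, the number of fragments an
    isoform yields is proportional to its molar amount times its (effective)
    length, so the per-fragment isoform probability is weighted by the
    number of valid read start positions; this is what makes the junction
    read counts, and hence PIR, converge to the molecular retention
    ``100 * (1 - s)``.  Read starts are uniform over the chosen isoform, so
    junction anchors span the whole 1..read_length-1 range and the
    downstream anchor filter is genuinely exercised.  Truth rows record
    each read's isoform of origin.
    """
    t = locus.transcript
    s = cfg.splicing.skip_fraction
    rng = np.random.default_rng(cfg.seed)
    reads: list[AlignedRead] = []
    truth: list[dict] = []
    iso_cache = {
        False: _isoform_exons(t, eoi_index, False),
        True: _isoform_exons(t, eoi_index, True),
    }
    # fragments per isoform ~ molar fraction x effective length
    w = {
        skip: sum(len(e) for e in exons) - cfg.read_length + 1
        for skip, exons in iso_cache.items()
    }
    if min(w.values()) < 1:
        raise SimConfigError("read_length exceeds an isoform's length")
    p_skip_fragment = s * w[True] / (s * w[True] + (1 - s) * w[False])
    for i in range(cfg.splicing.n_fragments):
        skip = bool(rng.random() < p_skip_fragment)
        exons = iso_cache[skip]
        tlen = sum(len(e) for e in exons)
        start_t = int(rng.integers(0, tlen - cfg.read_length + 1))
        pos, cigar, seq = _place_read(exons, start_t, cfg.read_length, locus.reference)
        read_id = f"{individual_id}_frag{i + 1}"
        reads.append(
            AlignedRead(read_id, individual_id, cfg.chrom, pos, cigar, sequence=seq)
        )
        truth.append(
            {
                "read_id": read_id,
                "individual_id": individual_id,
                "eoi_index": eoi_index,
                "isoform": "skip" if skip else "inclusion",
            }
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sam(reads, locus, outdir / f"{individual_id}_spliced.sam")
        _write_truth(truth, outdir / f"{individual_id}_spliced_truth.tsv")
    return reads, truth


# ---------------------------------------------------------------------------
# Writers


def write_sam(
    reads: list[AlignedRead], locus: ToyLocus, path: str | os.PathLike
) -> None:
    """Write reads as a (text) SAM file with RG tags carrying individual ids."""
    rgs = sorted({r.individual_id for r in reads})
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": locus.transcript.chrom, "LN": len(locus.reference)}],
        "RG": [{"ID": rg, "SM": rg} for rg in rgs],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in reads:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = r.read_id
            rec.reference_id = 0
            rec.reference_start = r.pos - 1
            rec.cigarstring = r.cigar
            rec.flag = r.flag
            rec.mapping_quality = 60
            if r.sequence is not None:
                rec.query_sequence = r.sequence
                rec.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(r.sequence)
                )
            rec.set_tag("RG", r.individual_id)
            fh.write(rec)


def write_fastq(reads: list[AlignedRead], path: str | os.PathLike) -> None:
    """Optional FASTQ emitter for end-to-end runs with an external aligner."""
    with open(path, "w") as fh:
        for r in reads:
            if r.sequence is None:
                continue
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def _write_truth(rows: list[dict], path: Path) -> None:
    if not rows:
        path.write_text("")
        return
    cols = list(rows[0])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
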