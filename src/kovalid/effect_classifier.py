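"""Consequence classification of CRISPR indels.

Each indel is placed into one of three mutually exclusive categories against
a transcript model, with the precedence splice-site > loss-of-function >
in-frame:

* **SS** — the indel touches a splice-boundary window (a configurable number
  of intronic and exonic bases around each donor/acceptor; the canonical
  GT/AG dinucleotides are always covered);
* **LOF** — the net coding-length change is not a multiple of 3 (frameshift),
  or the deletion removes more than half of the protein-coding sequence;
* **IF** — everything else (in-frame, small).

The three-way scheme condenses a full variant annotator's vocabulary into
the categories used when reporting CRISPR founder alleles.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

from .gene_model import GenomicInterval, Transcript
from .indel_caller import IndelCall

__all__ = [
    "SpliceWindow",
    "EffectAnnotation",
    "EffectSummary",
    "classify_indel",
    "classify_allele",
    "summarize_effects",
    "write_annotation_table",
    "format_summary_report",
]

CATEGORIES = ("LOF", "SS", "IF")


@dataclass(frozen=True)
class SpliceWindow:
    """Extent of the splice-site window around each exon/intron junction.

    ``intronic_bp`` bases into the intron and ``exonic_bp`` bases into the
    exon count as splice-site territory.  The canonical 2-bp donor/acceptor
    dinucleotides are always included even if ``intronic_bp < 2``.
    """

    intronic_bp: int = 8
    exonic_bp: int = 3

    @property
    def effective_intronic(self) -> int:
        return max(self.intronic_bp, 2)


@dataclass(frozen=True)
class EffectAnnotation:
    indel: IndelCall
    category: str  # LOF | SS | IF
    reason: str  # frameshift | cds_majority_removed | splice_donor |
    #              splice_acceptor | splice_region | inframe
    fraction_cds_removed: float
    net_frame_shift: int  # in {0, 1, 2}
    noncoding: bool = False


@dataclass
class EffectSummary:
    site_id: str
    counts: dict[str, int] = field(default_factory=lambda: dict.fromkeys(CATEGORIES, 0))
    annotations: list[EffectAnnotation] = field(default_factory=list)


def _boundary_windows(
    t: Transcript, w: SpliceWindow
) -> list[tuple[str, GenomicInterval, GenomicInterval | None]]:
    """(side, intronic window, exonic window) per junction, genomic coords.

    ``side`` is donor/acceptor in transcript orientation.  Intronic windows
    are clipped to the intron; exonic windows to the flanking exon.
    """
    out = []
    chrom = t.chrom
    ib = w.effective_intronic
    eb = w.exonic_bp
    for gi, intron in enumerate(t.introns):
        left_exon, right_exon = t.exons[gi], t.exons[gi + 1]
        left_side = "donor" if t.strand == "+" else "acceptor"
        right_side = "acceptor" if t.strand == "+" else "donor"
        # junction at intron.start (genomic-left exon end)
        intr = GenomicInterval(
            chrom, intron.start, min(intron.start + ib, intron.end)
        )
        exn = None
        if eb > 0:
            exn = GenomicInterval(
                chrom, max(intron.start - eb, left_exon.start), intron.start
            )
        out.append((left_side, intr, exn))
        # junction at intron.end (genomic-right exon start)
        intr = GenomicInterval(
            chrom, max(intron.end - ib, intron.start), intron.end
        )
        exn = None
        if eb > 0:
            exn = GenomicInterval(
                chrom, intron.end, min(intron.end + eb, right_exon.end)
            )
        out.append((right_side, intr, exn))
    return out


def _splice_hit(
    footprint: GenomicInterval, t: Transcript, w: SpliceWindow
) -> str | None:
    """Reason string if the footprint touches a splice window, else None.

    Intronic overlap wins over exonic-only overlap (splice_region).
    """
    region_hit = False
    for side, intr, exn in _boundary_windows(t, w):
        if footprint.overlap(intr) > 0:
            return f"splice_{side}"
        if exn is not None and footprint.overlap(exn) > 0:
            region_hit = True
    return "splice_region" if region_hit else None


def _frame_and_fraction(indel: IndelCall, t: Transcript) -> tuple[int, float]:
    """Net frame shift (|delta| mod 3 in {0,1,2}) and fraction of CDS removed."""
    if indel.kind == "del":
        removed = t.cds_overlap(indel.footprint)
        frac = removed / t.cds_length if t.cds_length else 0.0
        return removed % 3, frac
    # insertion: shifts frame only when its anchor base is coding
    anchored_in_cds = t.cds_overlap(indel.footprint) > 0
    return (indel.length % 3 if anchored_in_cds else 0), 0.0


def classify_indel(
    indel: IndelCall,
    t: Transcript,
    splice_window: SpliceWindow = SpliceWindow(),
) -> EffectAnnotation:
    """Deterministic three-category classification of a single indel.

    Precedence: splice-site, then loss-of-function, then in-frame.  An indel
    whose footprint lies entirely outside the transcript's exons and all
    splice windows is reported in-frame with a ``noncoding`` flag rather
    than guessed at.
    """
    fp = indel.footprint
    frame, frac = _frame_and_fraction(indel, t)

    splice_reason = _splice_hit(fp, t, splice_window)
    if splice_reason is not None:
        return EffectAnnotation(indel, "SS", splice_reason, frac, frame)

    if frame != 0:
        return EffectAnnotation(indel, "LOF", "frameshift", frac, frame)
    if frac > 0.5:
        return EffectAnnotation(indel, "LOF", "cds_majority_removed", frac, frame)

    noncoding = all(fp.overlap(e) == 0 for e in t.exons)
    return EffectAnnotation(indel, "IF", "inframe", frac, frame, noncoding=noncoding)


def classify_allele(
    calls: list[IndelCall],
    t: Transcript,
    splice_window: SpliceWindow = SpliceWindow(),
) -> EffectAnnotation:
    """Classify a composite allele (all indels carried by one read).

    The frame shift is computed from the *net* coding-length change across
    the whole allele, so e.g. a +1 insertion plus a -1 deletion is in-frame.
    Splice-site overlap by any member indel dominates.
    """
    if not calls:
        raise ValueError("empty allele")
    if len(calls) == 1:
        return classify_indel(calls[0], t, splice_window)
    net = 0
    frac = 0.0
    splice_reason = None
    for c in calls:
        _, fr = _frame_and_fraction(c, t)
        coding = t.cds_overlap(c.footprint) > 0
        if c.kind == "ins":
            net += c.length if coding else 0
        else:
            net -= t.cds_overlap(c.footprint)
        frac += fr
        if splice_reason is None:
            splice_reason = _splice_hit(c.footprint, t, splice_window)
    frame = abs(net) % 3
    frac = min(frac, 1.0)
    rep = calls[0]
    if splice_reason is not None:
        return EffectAnnotation(rep, "SS", splice_reason, frac, frame)
    if frame != 0:
        return EffectAnnotation(rep, "LOF", "frameshift", frac, frame)
    if frac > 0.5:
        return EffectAnnotation(rep, "LOF", "cds_majority_removed", frac, frame)
    return EffectAnnotation(rep, "IF", "inframe", frac, frame)


def _indel_identity(c: IndelCall) -> tuple:
    return (c.chrom, c.pos, c.kind, c.length, c.inserted_seq)


def summarize_effects(
    annotations: Iterable[EffectAnnotation], site_id: str
) -> EffectSummary:
    """Category counts over *unique* indels at one target site.

    The same physical indel observed on several clone reads is counted
    once; identity is (chrom, pos, kind, length, inserted sequence) after
    normalisation.
    """
    summary = EffectSummary(site_id)
    seen: set[tuple] = set()
    for ann in annotations:
        key = _indel_identity(ann.indel)
        if key in seen:
            continue
        seen.add(key)
        summary.counts[ann.category] += 1
        summary.annotations.append(ann)
    return summary


def write_annotation_table(
    annotations: Iterable[EffectAnnotation], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tkind\tlength\tinserted_seq\tsite_id\tcategory\t"
            "reason\tfraction_cds_removed\tnet_frame_shift\tnoncoding\n"
        )
        for a in annotations:
            c = a.indel
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.kind}\t{c.length}\t"
                f"{c.inserted_seq or '.'}\t{c.site_id}\t{a.category}\t"
                f"{a.reason}\t{a.fraction_cds_removed:.6g}\t"
                f"{a.net_frame_shift}\t{int(a.noncoding)}\n"
            )


def format_summary_report(summaries: Iterable[EffectSummary]) -> str:
    """Plain-text per-site category histogram."""
    lines = ["site_id\tLOF\tSS\tIF\tn_unique_indels"]
    for s in summaries:
        n = sum(s.counts.values())
        lines.append(
            f"{s.site_id}\t{s.counts['LOF']}\t{s.counts['SS']}\t"
            f"{s.counts['IF']}\t{n}"
        )
    return "\n".join(lines) + "\n"
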