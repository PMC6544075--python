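"""Categorize RNA-seq reads around a flagged variant into abnormal-splicing
evidence categories and count them for the index case and each control.

Four categories are counted:

* ``junction_spanning_cryptic_use`` — a split read whose splice-junction
  edge coincides base-precisely with the candidate cryptic site;
* ``exon_skipping`` — a single skip joining the flanking exons of the
  affected exon, omitting it entirely;
* ``intron_inclusion_total`` — a contiguous (unspliced) alignment crossing
  the natural exon/intron boundary with at least ``min_overhang`` aligned
  bases on both sides;
* ``intron_inclusion_with_variant`` — intron inclusion where the read
  demonstrably carries the alternate allele.

Categorization is partition-like: a read lands in at most one category,
except that with-variant inclusion is a subset of total inclusion.  Reads
whose skips match annotated introns are normally spliced; reads with skips
matching no annotated or candidate junction are ignored.  Control samples
do not carry the variant, so their with-variant count is defined as the
number of boundary-crossing reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .splice_info import ACCEPTOR, DONOR, SiteImpact, Transcript, VariantRecord

CRYPTIC_USE = "junction_spanning_cryptic_use"
EXON_SKIPPING = "exon_skipping"
INTRON_INCLUSION = "intron_inclusion_total"
INTRON_INCLUSION_VARIANT = "intron_inclusion_with_variant"
CATEGORIES = (CRYPTIC_USE, EXON_SKIPPING, INTRON_INCLUSION, INTRON_INCLUSION_VARIANT)

#: CIGAR operations that consume the reference / the query
_REF_OPS = set("MDN=X")
_QUERY_OPS = set("MIS=X")


@dataclass(frozen=True)
class AlignedRead:
    """Minimal aligned-read record (single-end, already aligned)."""

    name: str
    contig: str
    start: int  # 1-based leftmost reference position
    cigar: tuple[tuple[str, int], ...]  # e.g. (("M", 50), ("N", 200), ("M", 50))
    seq: str
    carries_alt: bool | None = None  # tri-state; None = unknown

    def __post_init__(self) -> None:
        for op, length in self.cigar:
            if length < 1:
                raise ValueError("CIGAR operation lengths must be >= 1")
            if op not in "MIDNS=X":
                raise ValueError(f"unsupported CIGAR operation {op!r}")

    @classmethod
    def from_pysam(cls, aln) -> "AlignedRead":
        cigar = tuple((op, length) for op, length in _cigar_ops(aln.cigarstring))
        return cls(
            name=aln.query_name,
            contig=aln.reference_name,
            start=aln.reference_start + 1,
            cigar=cigar,
            seq=aln.query_sequence or "",
        )

    def reference_blocks(self) -> list[tuple[int, int]]:
        """Contiguous aligned reference intervals (1-based incl.), split at skips."""
        blocks: list[tuple[int, int]] = []
        ref = self.start
        block_start: int | None = None
        for op, length in self.cigar:
            if op in "M=XD":
                if block_start is None:
                    block_start = ref
                ref += length
            elif op == "N":
                if block_start is not None:
                    blocks.append((block_start, ref - 1))
                    block_start = None
                ref += length
            # I and S consume no reference
        if block_start is not None:
            blocks.append((block_start, ref - 1))
        return blocks

    def skips(self) -> list[tuple[int, int]]:
        """Skipped (intronic) reference intervals, 1-based inclusive."""
        out: list[tuple[int, int]] = []
        ref = self.start
        for op, length in self.cigar:
            if op == "N":
                out.append((ref, ref + length - 1))
            if op in _REF_OPS:
                ref += length
        return out

    def base_at(self, pos: int) -> str | None:
        """Read base aligned to reference position ``pos``; None if deleted/uncovered."""
        ref, query = self.start, 0
        for op, length in self.cigar:
            if op in "M=X":
                if ref <= pos < ref + length:
                    return self.seq[query + (pos - ref)]
                ref += length
                query += length
            elif op == "D":
                if ref <= pos < ref + length:
                    return None
                ref += length
            elif op == "N":
                if ref <= pos < ref + length:
                    return None
                ref += length
            elif op in "IS":
                query += length
        return None


def _cigar_ops(cigarstring: str) -> Iterable[tuple[str, int]]:
    num = ""
    for ch in cigarstring:
        if ch.isdigit():
            num += ch
        else:
            yield ch, int(num)
            num = ""


def read_carries_alt(read: AlignedRead, variant: VariantRecord) -> bool | None:
    """Tri-state: does the read demonstrate the alternate allele?

    Substitutions compare the aligned base at the variant position; a
    deletion or skip over the position, a read not covering it, or an indel
    variant yield ``None`` (unknown).
    """
    if read.carries_alt is not None:
        return read.carries_alt
    if not variant.is_snv:
        return None
    base = read.base_at(variant.pos)
    if base is None:
        return None
    return base.upper() == variant.alt.upper()


# -- junction geometry helpers --------------------------------------------------


def intron_edge(polarity: str, strand: str, junction_coord: int) -> tuple[str, int]:
    """Which intron edge a site of given polarity defines, in genomic coordinates.

    Returns ("start"|"end", coordinate) for the intron interval the site
    would delimit.  junction_coord follows the +1-base convention of
    :class:`~splicevet.splice_info.SpliceSite`.
    """
    if polarity == DONOR:
        return ("start", junction_coord) if strand == "+" else ("end", junction_coord)
    # acceptor: junction_coord is the first exonic base
    return ("end", junction_coord - 1) if strand == "+" else ("start", junction_coord + 1)


def natural_boundary(polarity: str, strand: str, junction_coord: int) -> tuple[int, int]:
    """(lo, hi) adjacent genomic coordinates straddling the exon/intron boundary."""
    if strand == "+":
        return junction_coord - 1, junction_coord
    return junction_coord, junction_coord + 1


def _affected_exon_context(transcript: Transcript, impact: SiteImpact):
    """Locate the natural junction and affected exon for an impact.

    For a natural-site impact the junction is the impacted boundary itself;
    for a cryptic impact it is the nearest annotated junction of the same
    polarity.  Returns (natural_site, exon_index, introns) where introns is
    the list of annotated intron intervals.
    """
    strand = transcript.strand
    naturals = [s for s in transcript.natural_sites() if s.polarity == impact.site.polarity]
    if impact.site.kind == "natural":
        natural = next(
            s for s in naturals if s.junction_coord == impact.site.junction_coord
        )
    else:
        tiebreak = 1 if strand == "+" else -1
        natural = min(
            naturals,
            key=lambda s: (
                abs(s.junction_coord - impact.site.junction_coord),
                tiebreak * s.junction_coord,
            ),
        )
    # exon adjacent to the natural junction, on the exon side
    if impact.site.polarity == DONOR:
        exon_boundary = natural.junction_coord - 1 if strand == "+" else natural.junction_coord + 1
    else:
        exon_boundary = natural.junction_coord
    exon_index = next(
        i for i, (s, e) in enumerate(transcript.exons) if s <= exon_boundary <= e
    )
    introns = [
        (e + 1, s2 - 1) for (_, e), (s2, _) in zip(transcript.exons, transcript.exons[1:])
    ]
    return natural, exon_index, introns


def categorize_read(
    read: AlignedRead,
    transcript: Transcript,
    impact: SiteImpact,
    variant: VariantRecord | None,
    min_overhang: int = 6,
) -> str | None:
    """Assign a read to one abnormal-splicing category, or None.

    ``variant=None`` (control samples) disables the with-variant refinement:
    boundary-crossing reads are reported as total intron inclusion.
    """
    if read.contig != transcript.contig:
        return None
    natural, exon_index, introns = _affected_exon_context(transcript, impact)
    strand = transcript.strand
    skips = read.skips()

    if impact.site.kind == "cryptic" and skips:
        side, coord = intron_edge(impact.site.polarity, strand, impact.site.junction_coord)
        for i_s, i_e in skips:
            if (side == "start" and i_s == coord) or (side == "end" and i_e == coord):
                return CRYPTIC_USE

    if 0 < exon_index < len(transcript.exons) - 1:
        prev_e = transcript.exons[exon_index - 1][1]
        next_s = transcript.exons[exon_index + 1][0]
        for i_s, i_e in skips:
            if (i_s, i_e) == (prev_e + 1, next_s - 1):
                return EXON_SKIPPING

    # reads with skips matching no annotated or candidate junction are ignored;
    # a contiguous or normally-spliced read may still show intron inclusion
    if all(sk in introns for sk in skips):
        lo, hi = natural_boundary(impact.site.polarity, strand, natural.junction_coord)
        for b_s, b_e in read.reference_blocks():
            if b_s <= lo - (min_overhang - 1) and b_e >= hi + (min_overhang - 1):
                if variant is not None and read_carries_alt(read, variant):
                    return INTRON_INCLUSION_VARIANT
                return INTRON_INCLUSION
    return None


@dataclass
class EvidenceCounts:
    """Per-category counts for the index case and each control sample."""

    index_counts: dict[str, int] = field(default_factory=dict)
    control_counts: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat in CATEGORIES:
            self.index_counts.setdefault(cat, 0)
            self.control_counts.setdefault(cat, [])

    def validate(self) -> None:
        assert all(v >= 0 for v in self.index_counts.values())
        assert (
            self.index_counts[INTRON_INCLUSION_VARIANT]
            <= self.index_counts[INTRON_INCLUSION]
        )


def count_evidence(
    index_reads: Iterable[AlignedRead],
    control_read_sets: Sequence[Iterable[AlignedRead]],
    transcript: Transcript,
    impact: SiteImpact,
    variant: VariantRecord,
    min_overhang: int = 6,
) -> EvidenceCounts:
    """Count evidence categories for the index case against every control.

    With-variant inclusion is a subset of total inclusion for the index; in
    controls (which lack the variant) the with-variant count equals the
    number of boundary-crossing reads.
    """
    if not control_read_sets:
        raise ValueError("at least one control read set is required")
    counts = EvidenceCounts()
    for read in index_reads:
        cat = categorize_read(read, transcript, impact, variant, min_overhang)
        if cat is None:
            continue
        counts.index_counts[cat] += 1
        if cat == INTRON_INCLUSION_VARIANT:
            counts.index_counts[INTRON_INCLUSION] += 1
    for reads in control_read_sets:
        per = {cat: 0 for cat in CATEGORIES}
        for read in reads:
            cat = categorize_read(read, transcript, impact, None, min_overhang)
            if cat is None:
                continue
            per[cat] += 1
            if cat == INTRON_INCLUSION:
                per[INTRON_INCLUSION_VARIANT] += 1
        for cat in CATEGORIES:
            counts.control_counts[cat].append(per[cat])
    counts.validate()
    return counts
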