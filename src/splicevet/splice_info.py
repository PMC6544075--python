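"""Individual-information models of splice sites and per-variant impact scoring.

A splice site is modelled with a positional bit-weight matrix built from a
training alignment of donor or acceptor sites.  The weight of base ``b`` at
position ``l`` is ``2 + log2 f(b, l)`` where ``f`` is the (pseudocounted)
observed base frequency, so a uniformly random position contributes exactly
0 bits.  The individual information ``Ri`` of a candidate window is the sum
of its per-position weights; only windows with ``Ri > 0`` are considered
bindable.  The mean ``Ri`` of the training set is ``Rsequence``, the
model-level information content.

A variant's impact on a site is summarised by ``delta_r_i = Ri,final −
Ri,initial``; ``|delta_r_i|`` bits imply a minimum ``2**|delta_r_i|``-fold
change in binding affinity.  Candidate filtering retains natural-site
weakenings and cryptic-site strengthenings of at least ``min_cryptic_gain``
bits whose final strength exceeds the nearest cognate natural site.

Coordinates in domain records are 1-based inclusive (VCF/GTF convention);
conversion to 0-based happens only where sequences are sliced.  Model
geometry is expressed relative to the exon/intron junction with no position
0: for donors, negative positions are exonic and positive intronic
(default −3..+6, GT at +1/+2); for acceptors, negative positions are
intronic and positive exonic (default −25..+2, AG at −2/−1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DONOR = "donor"
ACCEPTOR = "acceptor"

#: default geometries (inclusive, no position 0) relative to the junction
DEFAULT_GEOMETRY = {DONOR: (-3, 6), ACCEPTOR: (-25, 2)}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SiteGeometry:
    """Inclusive position range around the junction; position 0 does not exist."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= 0 or self.end <= 0:
            raise ValueError("geometry must straddle the junction (start < 0 < end)")

    @property
    def span(self) -> int:
        return self.end - self.start  # position 0 is skipped

    @property
    def positions(self) -> list[int]:
        return [p for p in range(self.start, self.end + 1) if p != 0]


@dataclass
class SpliceModel:
    """Positional bit-weight model for donor or acceptor sites."""

    polarity: str
    geometry: SiteGeometry
    weights: np.ndarray  # (span, 4) bits, columns A C G T
    r_sequence: float
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.polarity not in (DONOR, ACCEPTOR):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.geometry.span, 4):
            raise ValueError("weight matrix shape does not match geometry span")

    @property
    def span(self) -> int:
        return self.geometry.span

    def score(self, window: str) -> float:
        """Individual information Ri (bits) of one window.

        Ambiguous bases contribute the position's minimum weight (the most
        conservative assumption for bindability).
        """
        return score_site(self, window)

    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=1))

    def frequencies(self) -> np.ndarray:
        """Back out the positional base frequencies from the weights."""
        return np.exp2(self.weights - 2.0)

    # -- serialization: TSV with a 3-line header ------------------------------

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            f"# polarity\t{self.polarity}",
            f"# geometry\t{self.geometry.start}\t{self.geometry.end}",
            f"# r_sequence\t{self.r_sequence:.10g}",
            "position\tA\tC\tG\tT",
        ]
        for pos, row in zip(self.geometry.positions, self.weights):
            lines.append(str(pos) + "\t" + "\t".join(f"{w:.10g}" for w in row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpliceModel":
        lines = Path(path).read_text().splitlines()
        polarity = lines[0].split("\t")[1]
        _, gstart, gend = lines[1].split("\t")
        r_sequence = float(lines[2].split("\t")[1])
        geometry = SiteGeometry(int(gstart), int(gend))
        rows = [list(map(float, ln.split("\t")[1:5])) for ln in lines[4:] if ln]
        return cls(polarity, geometry, np.array(rows), r_sequence)


@dataclass(frozen=True)
class SpliceSite:
    """A donor or acceptor junction, natural (annotated) or cryptic.

    ``junction_coord`` is the 1-based genomic coordinate of the base at
    relative position +1, i.e. the first base downstream of the junction in
    transcript orientation (first intronic base for donors, first exonic
    base for acceptors).
    """

    contig: str
    junction_coord: int
    strand: str
    polarity: str
    kind: str  # natural | cryptic
    r_i: float = float("nan")


@dataclass(frozen=True)
class VariantRecord:
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    rsid: str | None = None
    heterozygosity: float | None = None

    def __post_init__(self) -> None:
        if self.heterozygosity is not None and not 0.0 <= self.heterozygosity <= 0.5:
            raise ValueError("heterozygosity must lie in [0, 0.5]")

    @property
    def ref_end(self) -> int:
        """Last 1-based reference coordinate covered by the ref allele."""
        return self.pos + len(self.ref) - 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class SiteImpact:
    """One (variant, splice site) assessment."""

    variant: VariantRecord
    site: SpliceSite
    r_i_initial: float
    r_i_final: float
    nearest_cognate_natural_r_i: float
    distance_to_natural: int
    location_class: str  # exonic | intronic

    @property
    def delta_r_i(self) -> float:
        return self.r_i_final - self.r_i_initial


# -- gene model ---------------------------------------------------------------


@dataclass(frozen=True)
class Transcript:
    name: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive, ascending

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        for (s, e), (s2, _) in zip(self.exons, self.exons[1:]):
            if not (s <= e < s2):
                raise ValueError("exons must be non-overlapping and ascending")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def natural_sites(self) -> list[SpliceSite]:
        """Annotated donors/acceptors at the internal exon boundaries."""
        sites: list[SpliceSite] = []
        n = len(self.exons)
        for i, (s, e) in enumerate(self.exons):
            if self.strand == "+":
                if i < n - 1:
                    sites.append(SpliceSite(self.contig, e + 1, "+", DONOR, "natural"))
                if i > 0:
                    sites.append(SpliceSite(self.contig, s, "+", ACCEPTOR, "natural"))
            else:
                if i > 0:  # genomically-first exon is the transcript's last
                    sites.append(SpliceSite(self.contig, s - 1, "-", DONOR, "natural"))
                if i < n - 1:
                    sites.append(SpliceSite(self.contig, e, "-", ACCEPTOR, "natural"))
        return sites


@dataclass
class GeneModel:
    transcripts: list[Transcript]

    def overlapping(self, contig: str, pos: int, margin: int = 0) -> list[Transcript]:
        return [
            t
            for t in self.transcripts
            if t.contig == contig and t.start - margin <= pos <= t.end + margin
        ]


# -- window geometry ----------------------------------------------------------


def window_span(junction_coord: int, geometry: SiteGeometry, strand: str) -> tuple[int, int]:
    """Genomic 1-based inclusive interval covered by a site's model window."""
    if strand == "+":
        return junction_coord + geometry.start, junction_coord + geometry.end - 1
    return junction_coord - geometry.end + 1, junction_coord - geometry.start


def extract_window(seq: str, junction_coord: int, geometry: SiteGeometry, strand: str) -> str:
    """Window sequence in model orientation (reverse-complemented on −)."""
    lo, hi = window_span(junction_coord, geometry, strand)
    if lo < 1 or hi > len(seq):
        raise ValueError("window extends beyond the reference contig")
    window = seq[lo - 1 : hi]
    return reverse_complement(window) if strand == "-" else window


# -- model construction and scoring -------------------------------------------


def build_model(
    training_sequences: Sequence[str],
    polarity: str,
    geometry: SiteGeometry | tuple[int, int] | None = None,
    pseudocount: float = 0.25,
) -> SpliceModel:
    """Build a positional bit-weight model from aligned site sequences.

    weight(b, l) = 2 + log2 f(b, l) with f the pseudocounted base frequency;
    r_sequence is the mean model score of the training sequences.
    """
    if geometry is None:
        geometry = SiteGeometry(*DEFAULT_GEOMETRY[polarity])
    elif not isinstance(geometry, SiteGeometry):
        geometry = SiteGeometry(*geometry)
    if not training_sequences:
        raise ValueError("empty training set")
    span = geometry.span
    counts = np.zeros((span, 4), dtype=float)
    for seq in training_sequences:
        seq = seq.upper()
        if len(seq) != span:
            raise ValueError(
                f"training sequence length {len(seq)} does not match geometry span {span}"
            )
        for l, b in enumerate(seq):
            try:
                counts[l, _BASE_INDEX[b]] += 1.0
            except KeyError:
                raise ValueError(f"non-ACGT base {b!r} in training sequence") from None
    n = len(training_sequences)
    freqs = (counts + pseudocount) / (n + 4.0 * pseudocount)
    weights = 2.0 + np.log2(freqs)
    model = SpliceModel(polarity, geometry, weights, r_sequence=0.0, pseudocount=pseudocount)
    model.r_sequence = float(np.mean([score_site(model, s) for s in training_sequences]))
    return model


def score_site(model: SpliceModel, window_sequence: str) -> float:
    """Ri (bits) of one window: the sum of per-position base weights.

    The caller supplies minus-strand windows already reverse-complemented.
    Ambiguous bases contribute the position's minimum weight.
    """
    window_sequence = window_sequence.upper()
    if len(window_sequence) != model.span:
        raise ValueError(
            f"window length {len(window_sequence)} does not match model span {model.span}"
        )
    total = 0.0
    for l, b in enumerate(window_sequence):
        idx = _BASE_INDEX.get(b)
        if idx is None:
            total += float(model.weights[l].min())
        else:
            total += float(model.weights[l, idx])
    return total


def fold_change(delta_r_i: float) -> float:
    """Minimum fold change in binding affinity implied by a ΔRi of |x| bits.

    The affinity ratio of two sites is bounded below by 2**|ΔRi|; the
    direction (strengthening vs weakening) is carried by the sign of ΔRi
    and reported separately by the caller.
    """
    return 2.0 ** abs(delta_r_i)


# -- variant assessment -------------------------------------------------------


def _contig_sequence(reference, contig: str) -> str:
    """Materialize one contig from a dict of strings or a pyfaidx.Fasta."""
    seq = reference[contig]
    if not isinstance(seq, str):
        seq = str(seq[:])
    return seq.upper()


def apply_variant(seq: str, variant: VariantRecord) -> tuple[str, "CoordMap"]:
    """Mutated contig sequence plus a reference→mutated coordinate map."""
    i = variant.pos - 1
    observed = seq[i : i + len(variant.ref)]
    if observed != variant.ref.upper():
        raise ValueError(
            f"ref allele mismatch at {variant.contig}:{variant.pos}: "
            f"expected {variant.ref!r}, reference has {observed!r}"
        )
    mutated = seq[:i] + variant.alt.upper() + seq[i + len(variant.ref) :]
    return mutated, CoordMap(variant.pos, len(variant.ref), len(variant.alt))


@dataclass(frozen=True)
class CoordMap:
    """Maps 1-based reference coordinates onto the mutated sequence.

    Coordinates inside the replaced ref allele are anchored to the variant
    position; downstream coordinates shift by the allele length difference.
    """

    pos: int
    ref_len: int
    alt_len: int

    def __call__(self, coord: int) -> int:
        if coord < self.pos:
            return coord
        if coord >= self.pos + self.ref_len:
            return coord + self.alt_len - self.ref_len
        return min(coord, self.pos + self.alt_len - 1)


def _nearest_cognate(
    site_jc: int,
    polarity: str,
    strand: str,
    naturals: Sequence[tuple[SpliceSite, float]],
) -> tuple[float, int]:
    """(Ri, distance) of the nearest annotated site of the same polarity.

    Ties in genomic distance resolve toward the site 5' on the transcript
    strand (smaller coordinate on +, larger on −).
    """
    candidates = [(s, r) for s, r in naturals if s.polarity == polarity]
    if not candidates:
        return float("nan"), -1

    def key(item: tuple[SpliceSite, float]):
        s, _ = item
        tiebreak = s.junction_coord if strand == "+" else -s.junction_coord
        return (abs(s.junction_coord - site_jc), tiebreak)

    best, r_i = min(candidates, key=key)
    return r_i, abs(best.junction_coord - site_jc)


def assess_variant(
    variant: VariantRecord,
    reference,
    gene_model: GeneModel,
    donor_model: SpliceModel,
    acceptor_model: SpliceModel,
    scan_radius_nt: int = 300,
) -> list[SiteImpact]:
    """Score every splice-site window a variant can touch.

    Emits one :class:`SiteImpact` per natural site whose model window
    overlaps the variant and one per candidate cryptic junction (every
    position within ``scan_radius_nt`` of the variant at which the variant
    lies inside the model window), for both polarities.  Indels rescore the
    window re-extracted from the mutated sequence anchored at the junction
    coordinate.
    """
    seq = _contig_sequence(reference, variant.contig)
    if not 1 <= variant.pos <= len(seq) or variant.ref_end > len(seq):
        raise ValueError(f"variant at {variant.contig}:{variant.pos} outside reference bounds")
    mutated, coord_map = apply_variant(seq, variant)
    models = {DONOR: donor_model, ACCEPTOR: acceptor_model}

    impacts: list[SiteImpact] = []
    seen: set[tuple[str, str, int]] = set()
    p1, p2 = variant.pos, variant.ref_end

    for transcript in gene_model.overlapping(variant.contig, variant.pos, margin=scan_radius_nt):
        strand = transcript.strand
        naturals = transcript.natural_sites()
        scored_naturals = []
        for s in naturals:
            model = models[s.polarity]
            r = score_site(model, extract_window(seq, s.junction_coord, model.geometry, strand))
            scored_naturals.append((replace(s, r_i=r), r))
        natural_jcs = {(s.polarity, s.junction_coord) for s, _ in scored_naturals}

        variant_exonic = transcript.contains(variant.pos)

        for site, r_i in scored_naturals:
            model = models[site.polarity]
            lo, hi = window_span(site.junction_coord, model.geometry, strand)
            if hi < p1 or lo > p2:
                continue
            key = ("natural", site.polarity, site.junction_coord)
            if key in seen:
                continue
            seen.add(key)
            final = score_site(
                model,
                extract_window(mutated, coord_map(site.junction_coord), model.geometry, strand),
            )
            impacts.append(
                SiteImpact(
                    variant=variant,
                    site=site,
                    r_i_initial=r_i,
                    r_i_final=final,
                    nearest_cognate_natural_r_i=r_i,
                    distance_to_natural=0,
                    location_class="exonic" if variant_exonic else "intronic",
                )
            )

        for polarity, model in models.items():
            g = model.geometry
            if strand == "+":
                jc_range = range(p1 - g.end + 1, p2 - g.start + 1)
            else:
                jc_range = range(p1 + g.start, p2 + g.end)
            for jc in jc_range:
                if (polarity, jc) in natural_jcs:
                    continue
                if abs(jc - variant.pos) > scan_radius_nt:
                    continue
                lo, hi = window_span(jc, g, strand)
                if lo < 1 or hi > len(seq):
                    continue
                key = ("cryptic", polarity, jc)
                if key in seen:
                    continue
                seen.add(key)
                initial = score_site(model, extract_window(seq, jc, g, strand))
                final = score_site(model, extract_window(mutated, coord_map(jc), g, strand))
                near_r, near_d = _nearest_cognate(jc, polarity, strand, scored_naturals)
                impacts.append(
                    SiteImpact(
                        variant=variant,
                        site=SpliceSite(variant.contig, jc, strand, polarity, "cryptic", initial),
                        r_i_initial=initial,
                        r_i_final=final,
                        nearest_cognate_natural_r_i=near_r,
                        distance_to_natural=near_d,
                        location_class="exonic" if transcript.contains(jc) else "intronic",
                    )
                )

    impacts.sort(key=lambda im: (im.site.kind != "natural", im.site.polarity, im.site.junction_coord))
    return impacts


def filter_candidates(
    impacts: Iterable[SiteImpact], min_cryptic_gain: float = 2.0
) -> list[SiteImpact]:
    """Apply the candidate filters.

    Natural sites are retained only when weakened (ΔRi < 0): variants
    predicted to strengthen natural sites are excluded.  Cryptic sites are
    retained only when strengthened by at least ``min_cryptic_gain`` bits,
    bindable (Ri,final > 0) and with final strength exceeding the nearest
    natural site of the same polarity.
    """
    kept: list[SiteImpact] = []
    for im in impacts:
        if im.site.kind == "natural":
            if im.delta_r_i < 0:
                kept.append(im)
        else:
            if (
                im.delta_r_i >= min_cryptic_gain
                and im.r_i_final > 0.0
                and not math.isnan(im.nearest_cognate_natural_r_i)
                and im.r_i_final > im.nearest_cognate_natural_r_i
            ):
                kept.append(im)
    return kept
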