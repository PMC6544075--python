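"""Seeded generator of desk-scale inputs: splice-site training sets, a toy
multi-exon gene on a synthetic contig, variants of each mechanistic class,
and index/control read sets with planted evidence fractions, plus a
ground-truth manifest for every planted read.

Five scenarios are emulated:

* ``natural_loss_exon_skip`` — the exon-2 donor is abolished (GT -> AT);
  a planted fraction of index reads skip exon 2 entirely.
* ``natural_loss_intron_inclusion`` — same donor loss; a planted fraction
  of index reads run contiguously across the donor boundary and carry the
  alternate allele.
* ``cryptic_activation`` — an exonic cryptic donor 31 nt inside exon 2 is
  strengthened to above the natural donor; planted index reads splice at
  the cryptic junction.
* ``common_snp_benign`` — a common polymorphism (heterozygosity 0.2)
  modestly weakens the donor; no abnormal reads are planted.
* ``alt_spliced_control_masquerade`` — the cryptic junction is used at the
  same rate in index and controls: naturally occurring alternative splicing
  masquerading as a splicing mutation.

Index abnormal-read counts are planted deterministically at
``round(fraction * depth)``; control counts are Binomial(depth, fraction)
per control sample.  A small intron-inclusion background (fraction 0.02)
runs through every sample, emulating baseline pre-mRNA signal.  Reads are
single-end, error-free, 100 nt.  All randomness flows from a single
``numpy.random.default_rng(seed)``, so a seed fully determines every output
byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import splice_info as si
from . import read_evidence as re_
from .splice_info import (
    ACCEPTOR,
    BASES,
    DONOR,
    GeneModel,
    SiteGeometry,
    SpliceModel,
    Transcript,
    VariantRecord,
    build_model,
)
from .read_evidence import (
    CRYPTIC_USE,
    EXON_SKIPPING,
    INTRON_INCLUSION,
    INTRON_INCLUSION_VARIANT,
    AlignedRead,
)

READ_LENGTH = 100
BASELINE_INCLUSION = 0.02

NATURAL_LOSS_EXON_SKIP = "natural_loss_exon_skip"
NATURAL_LOSS_INTRON_INCLUSION = "natural_loss_intron_inclusion"
CRYPTIC_ACTIVATION = "cryptic_activation"
COMMON_SNP_BENIGN = "common_snp_benign"
ALT_SPLICED_CONTROL_MASQUERADE = "alt_spliced_control_masquerade"
SCENARIOS = (
    NATURAL_LOSS_EXON_SKIP,
    NATURAL_LOSS_INTRON_INCLUSION,
    CRYPTIC_ACTIVATION,
    COMMON_SNP_BENIGN,
    ALT_SPLICED_CONTROL_MASQUERADE,
)

INTENDED_PHENOTYPE = {
    NATURAL_LOSS_EXON_SKIP: "aberrant",
    NATURAL_LOSS_INTRON_INCLUSION: "aberrant",
    CRYPTIC_ACTIVATION: "aberrant",
    COMMON_SNP_BENIGN: "allele_specific",
    ALT_SPLICED_CONTROL_MASQUERADE: "allele_specific",
}

#: planted abnormal-read fractions (index, control) per scenario
SCENARIO_FRACTIONS = {
    NATURAL_LOSS_EXON_SKIP: {EXON_SKIPPING: (0.30, 0.0)},
    NATURAL_LOSS_INTRON_INCLUSION: {INTRON_INCLUSION_VARIANT: (0.30, 0.0)},
    CRYPTIC_ACTIVATION: {CRYPTIC_USE: (0.25, 0.0)},
    COMMON_SNP_BENIGN: {},
    ALT_SPLICED_CONTROL_MASQUERADE: {CRYPTIC_USE: (0.10, 0.10)},
}


@dataclass(frozen=True)
class SyntheticScenario:
    """Seeded recipe for one complete case/control bundle."""

    name: str
    seed: int
    depth: int = 200
    control_n: int = 20
    fractions: dict = field(default_factory=dict)  # category -> (index_f, control_f)

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}")
        for idx_f, ctl_f in self.fractions.values():
            if not (0.0 <= idx_f <= 1.0 and 0.0 <= ctl_f <= 1.0):
                raise ValueError("planted fractions must lie in [0, 1]")
        if sum(f[0] for f in self.fractions.values()) + BASELINE_INCLUSION > 1.0:
            raise ValueError("planted index fractions exceed available depth")


def scenario(name: str, seed: int, depth: int = 200, control_n: int = 20) -> SyntheticScenario:
    """A scenario with its default planted fractions."""
    return SyntheticScenario(
        name=name,
        seed=seed,
        depth=depth,
        control_n=control_n,
        fractions=dict(SCENARIO_FRACTIONS[name]),
    )


# -- splice-model training-set generation ---------------------------------------

_DONOR_CONSENSUS = "CAGGTAAGT"  # positions -3..-1, +1..+6
_DONOR_PROBS = (0.45, 0.65, 0.80, 0.99, 0.99, 0.60, 0.70, 0.80, 0.50)

# acceptor positions -25..+2: 20-nt pyrimidine tract, then branch-distal
# positions, the invariant AG, and the first two exonic bases
_ACCEPTOR_TRACT = {"T": 0.40, "C": 0.35, "A": 0.15, "G": 0.10}
_ACCEPTOR_TAIL = (
    {"C": 0.45, "T": 0.30, "A": 0.15, "G": 0.10},  # -5
    {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},  # -4
    {"C": 0.65, "A": 0.1167, "G": 0.1167, "T": 0.1166},  # -3
    {"A": 0.99, "C": 0.00333, "G": 0.00333, "T": 0.00334},  # -2
    {"G": 0.99, "A": 0.00333, "C": 0.00333, "T": 0.00334},  # -1
    {"G": 0.55, "A": 0.15, "C": 0.15, "T": 0.15},  # +1
    {"T": 0.50, "A": 0.1667, "C": 0.1667, "G": 0.1666},  # +2
)


def _profile_matrix(polarity: str, strength_profile: str) -> np.ndarray:
    """Positional base-frequency matrix (span x 4, columns ACGT)."""
    if polarity == DONOR:
        rows = []
        for base, p in zip(_DONOR_CONSENSUS, _DONOR_PROBS):
            row = {b: (1.0 - p) / 3.0 for b in BASES}
            row[base] = p
            rows.append(row)
    else:
        rows = [dict(_ACCEPTOR_TRACT) for _ in range(20)] + [dict(d) for d in _ACCEPTOR_TAIL]
    mat = np.array([[row[b] for b in BASES] for row in rows])
    if strength_profile == "uniform":
        mat = np.full_like(mat, 0.25)
    elif strength_profile == "moderate":
        mat = 0.25 + 0.5 * (mat - 0.25)
    elif strength_profile != "strong":
        raise ValueError(f"unknown strength profile {strength_profile!r}")
    return mat / mat.sum(axis=1, keepdims=True)


@dataclass
class ModelSet:
    donor: SpliceModel
    acceptor: SpliceModel
    donor_training: list[str]
    acceptor_training: list[str]

    def write_fasta(self, out_dir: str | Path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for polarity, seqs in (
            (DONOR, self.donor_training),
            (ACCEPTOR, self.acceptor_training),
        ):
            records = [
                SeqRecord(Seq(s), id=f"{polarity}_{i:05d}", description="")
                for i, s in enumerate(seqs)
            ]
            SeqIO.write(records, out_dir / f"{polarity}_training.fa", "fasta")


def _sample_sequences(matrix: np.ndarray, n: int, rng: np.random.Generator) -> list[str]:
    base_array = np.array(list(BASES))
    draws = np.stack(
        [rng.choice(4, size=n, p=matrix[l]) for l in range(matrix.shape[0])], axis=1
    )
    return ["".join(base_array[row]) for row in draws]


def generate_models(
    strength_profile: str = "strong",
    n_training: int = 1000,
    seed: int = 0,
    pseudocount: float = 0.25,
) -> ModelSet:
    """Donor and acceptor training sets sampled from consensus-biased
    positional frequencies, plus the models built from them."""
    if n_training < 4:
        raise ValueError("n_training must be at least 4")
    rng = np.random.default_rng(seed)
    donor_seqs = _sample_sequences(_profile_matrix(DONOR, strength_profile), n_training, rng)
    acceptor_seqs = _sample_sequences(
        _profile_matrix(ACCEPTOR, strength_profile), n_training, rng
    )
    donor = build_model(donor_seqs, DONOR, pseudocount=pseudocount)
    acceptor = build_model(acceptor_seqs, ACCEPTOR, pseudocount=pseudocount)
    return ModelSet(donor, acceptor, donor_seqs, acceptor_seqs)


# -- toy gene and genome --------------------------------------------------------


@dataclass(frozen=True)
class GeneParams:
    contig: str = "chrT"
    length: int = 6000
    exons: tuple[tuple[int, int], ...] = ((1001, 1200), (1801, 2100), (2701, 3000))
    strand: str = "+"
    gene_id: str = "TOY1"
    transcript_id: str = "TOY1-201"

    def transcript(self) -> Transcript:
        return Transcript(self.transcript_id, self.contig, self.strand, self.exons)


def _weakest_base(model: SpliceModel, rel_pos: int) -> str:
    i = model.geometry.positions.index(rel_pos)
    return BASES[int(model.weights[i].argmin())]


def _plant(seq: list[str], start: int, fragment: str) -> None:
    seq[start - 1 : start - 1 + len(fragment)] = list(fragment)


def _plant_window(
    seq: list[str], model: SpliceModel, junction_coord: int, window: str
) -> None:
    lo, _ = si.window_span(junction_coord, model.geometry, "+")
    _plant(seq, lo, window)


def _window_with(model: SpliceModel, substitutions: dict[int, str]) -> str:
    chars = list(model.consensus())
    for rel, base in substitutions.items():
        chars[model.geometry.positions.index(rel)] = base
    return "".join(chars)


# -- read synthesis -------------------------------------------------------------


def _read_from_blocks(
    name: str, contig: str, blocks: list[tuple[int, int]], genome: str
) -> AlignedRead:
    cigar: list[tuple[str, int]] = []
    seq_parts: list[str] = []
    prev_end: int | None = None
    for s, e in blocks:
        if prev_end is not None:
            cigar.append(("N", s - prev_end - 1))
        cigar.append(("M", e - s + 1))
        seq_parts.append(genome[s - 1 : e])
        prev_end = e
    return AlignedRead(name, contig, blocks[0][0], tuple(cigar), "".join(seq_parts))


class _ReadFactory:
    """Builds the read repertoire of one synthetic gene."""

    def __init__(
        self,
        params: GeneParams,
        reference: str,
        mutated: str,
        cryptic_jc: int | None,
        rng: np.random.Generator,
    ):
        self.params = params
        self.ref = reference
        self.mut = mutated
        self.cryptic_jc = cryptic_jc
        self.rng = rng
        self.counter = 0

    def _name(self) -> str:
        self.counter += 1
        return f"r{self.counter:06d}"

    def _split(self) -> int:
        return int(self.rng.integers(10, READ_LENGTH - 10 + 1))

    def normal(self) -> AlignedRead:
        """Normally spliced read: exonic contiguous or annotated junction."""
        exons = self.params.exons
        if self.rng.random() < 0.4:
            s, e = exons[int(self.rng.integers(0, len(exons)))]
            start = int(self.rng.integers(s, e - READ_LENGTH + 2))
            blocks = [(start, start + READ_LENGTH - 1)]
        else:
            k = int(self.rng.integers(0, len(exons) - 1))
            a = self._split()
            left_end = exons[k][1]
            right_start = exons[k + 1][0]
            blocks = [
                (left_end - a + 1, left_end),
                (right_start, right_start + (READ_LENGTH - a) - 1),
            ]
        return _read_from_blocks(self._name(), self.params.contig, blocks, self.ref)

    def exon_skip(self) -> AlignedRead:
        (_, e1), _, (s3, _) = self.params.exons
        a = self._split()
        blocks = [(e1 - a + 1, e1), (s3, s3 + (READ_LENGTH - a) - 1)]
        return _read_from_blocks(self._name(), self.params.contig, blocks, self.ref)

    def intron_inclusion(self, with_variant: bool) -> AlignedRead:
        donor_boundary = self.params.exons[1][1]  # last base of exon 2
        a = self._split()
        start = donor_boundary - a + 1
        blocks = [(start, start + READ_LENGTH - 1)]
        genome = self.mut if with_variant else self.ref
        return _read_from_blocks(self._name(), self.params.contig, blocks, genome)

    def cryptic_use(self, from_mutated: bool) -> AlignedRead:
        assert self.cryptic_jc is not None
        a = self._split()
        exon_end = self.cryptic_jc - 1
        s3 = self.params.exons[2][0]
        blocks = [(exon_end - a + 1, exon_end), (s3, s3 + (READ_LENGTH - a) - 1)]
        genome = self.mut if from_mutated else self.ref
        return _read_from_blocks(self._name(), self.params.contig, blocks, genome)


# -- case bundles ---------------------------------------------------------------


@dataclass
class CaseBundle:
    """Complete in-memory inputs for one case, plus the ground-truth manifest."""

    scenario: SyntheticScenario
    params: GeneParams
    reference: dict[str, str]
    gene_model: GeneModel
    variant: VariantRecord
    models: ModelSet
    index_reads: list[AlignedRead]
    control_read_sets: list[list[AlignedRead]]
    manifest: dict

    @property
    def transcript(self) -> Transcript:
        return self.gene_model.transcripts[0]

    def write(self, out_dir: str | Path) -> Path:
        """Write the bundle as standard files (FASTA/GTF/BED12/VCF/SAM/JSON/TSV)."""
        from . import cli_io

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cli_io.write_fasta(self.reference, out_dir / "reference.fa")
        cli_io.write_gtf(self.params, out_dir / "gene.gtf")
        cli_io.write_bed12(self.params, out_dir / "gene.bed")
        cli_io.write_vcf(
            [self.variant], {self.params.contig: len(self.reference[self.params.contig])},
            out_dir / "variants.vcf",
        )
        cli_io.write_heterozygosity_table([self.variant], out_dir / "heterozygosity.tsv")
        cli_io.write_sam(
            self.index_reads,
            {self.params.contig: len(self.reference[self.params.contig])},
            out_dir / "index.sam",
        )
        control_dir = out_dir / "controls"
        control_dir.mkdir(exist_ok=True)
        for i, reads in enumerate(self.control_read_sets):
            cli_io.write_sam(
                reads,
                {self.params.contig: len(self.reference[self.params.contig])},
                control_dir / f"control_{i:02d}.sam",
            )
        self.models.donor.to_tsv(out_dir / "donor_model.tsv")
        self.models.acceptor.to_tsv(out_dir / "acceptor_model.tsv")
        (out_dir / "manifest.json").write_text(json.dumps(self.manifest, indent=2) + "\n")
        return out_dir


def _build_genome(
    params: GeneParams,
    models: ModelSet,
    scenario_name: str,
    rng: np.random.Generator,
) -> tuple[str, VariantRecord, int | None]:
    """Background sequence with planted splice sites plus the scenario variant.

    Natural sites are planted as model consensus with one sub-optimal base,
    leaving headroom so an activated cryptic site (full consensus) can
    exceed them.  Returns (reference, variant, cryptic_junction_coord).
    """
    seq = list("".join(rng.choice(list(BASES), size=params.length)))
    donor, acceptor = models.donor, models.acceptor

    natural_donor_window = _window_with(donor, {-3: _weakest_base(donor, -3)})
    natural_acceptor_window = _window_with(acceptor, {-25: _weakest_base(acceptor, -25)})
    t = params.transcript()
    for site in t.natural_sites():
        if site.polarity == DONOR:
            _plant_window(seq, donor, site.junction_coord, natural_donor_window)
        else:
            _plant_window(seq, acceptor, site.junction_coord, natural_acceptor_window)

    exon2_end = params.exons[1][1]
    donor_jc = exon2_end + 1
    cryptic_jc: int | None = None

    if scenario_name in (NATURAL_LOSS_EXON_SKIP, NATURAL_LOSS_INTRON_INCLUSION):
        pos = donor_jc  # relative position +1: the G of the GT dinucleotide
        ref = seq[pos - 1]
        alt = _weakest_base(donor, 1)
        variant = VariantRecord(params.contig, pos, ref, alt)
    elif scenario_name == COMMON_SNP_BENIGN:
        pos = donor_jc + 4  # relative position +5: a modest weakening
        ref = seq[pos - 1]
        alt = _weakest_base(donor, 5)
        variant = VariantRecord(
            params.contig, pos, ref, alt, rsid="rs1000001", heterozygosity=0.2
        )
    else:  # cryptic scenarios: a donor 31 nt inside exon 2
        cryptic_jc = exon2_end - 30
        weak = _weakest_base(donor, -1)
        _plant_window(seq, donor, cryptic_jc, _window_with(donor, {-1: weak}))
        pos = cryptic_jc - 1  # relative position -1 of the cryptic donor
        variant = VariantRecord(params.contig, pos, weak, donor.consensus()[2])
    return "".join(seq), variant, cryptic_jc


def _planted_counts(depth: int, fractions: dict, which: int) -> dict[str, int]:
    return {cat: round(f[which] * depth) for cat, f in fractions.items()}


def _sample_reads(
    factory: _ReadFactory,
    depth: int,
    planted: dict[str, int],
    baseline_inclusion: int,
    index: bool,
) -> tuple[list[AlignedRead], dict[str, int]]:
    reads: list[AlignedRead] = []
    counts = {cat: 0 for cat in re_.CATEGORIES}
    for cat, n in planted.items():
        for _ in range(n):
            if cat == EXON_SKIPPING:
                reads.append(factory.exon_skip())
            elif cat == CRYPTIC_USE:
                reads.append(factory.cryptic_use(from_mutated=index))
            elif cat in (INTRON_INCLUSION, INTRON_INCLUSION_VARIANT):
                with_var = index and cat == INTRON_INCLUSION_VARIANT
                reads.append(factory.intron_inclusion(with_variant=with_var))
            else:
                raise ValueError(f"cannot plant category {cat!r}")
            counts[cat] += 1
    for _ in range(baseline_inclusion):
        reads.append(factory.intron_inclusion(with_variant=False))
        counts[INTRON_INCLUSION] += 1
    n_planted = len(reads)
    for _ in range(max(0, depth - n_planted)):
        reads.append(factory.normal())
    # inclusion-with-variant implies inclusion-total
    counts[INTRON_INCLUSION] += counts[INTRON_INCLUSION_VARIANT]
    return reads, counts


def generate_case(
    scn: SyntheticScenario | str,
    gene_model_params: GeneParams | None = None,
    strength_profile: str = "strong",
    n_training: int = 1000,
) -> CaseBundle:
    """Generate the complete input bundle for one scenario.

    The variant is engineered so the information analysis reproduces the
    scenario's intended sign of dRi (natural losses abolish the GT donor;
    cryptic scenarios plant a >=2-bit gain that overtakes the cognate
    natural donor); reads are planted per the scenario fractions and every
    planted read's category is recorded in the manifest.
    """
    if isinstance(scn, str):
        raise TypeError("pass a SyntheticScenario (see scenario()); got a bare name")
    params = gene_model_params or GeneParams()
    rng = np.random.default_rng(scn.seed)
    models = generate_models(strength_profile, n_training, seed=int(rng.integers(2**31)))
    reference, variant, cryptic_jc = _build_genome(params, models, scn.name, rng)
    mutated, _ = si.apply_variant(reference, variant)
    factory = _ReadFactory(params, reference, mutated, cryptic_jc, rng)

    baseline = round(BASELINE_INCLUSION * scn.depth)
    index_planted = _planted_counts(scn.depth, scn.fractions, which=0)
    index_reads, index_counts = _sample_reads(
        factory, scn.depth, index_planted, baseline, index=True
    )

    control_sets: list[list[AlignedRead]] = []
    control_counts: list[dict[str, int]] = []
    for _ in range(scn.control_n):
        planted = {
            cat: int(rng.binomial(scn.depth, f[1]))
            for cat, f in scn.fractions.items()
            if f[1] > 0
        }
        ctl_baseline = int(rng.binomial(scn.depth, BASELINE_INCLUSION))
        reads, counts = _sample_reads(factory, scn.depth, planted, ctl_baseline, index=False)
        # controls lack the variant: their with-variant category is defined as
        # the number of boundary-crossing reads
        counts[INTRON_INCLUSION_VARIANT] = counts[INTRON_INCLUSION]
        control_sets.append(reads)
        control_counts.append(counts)

    manifest = {
        "scenario": scn.name,
        "seed": scn.seed,
        "depth": scn.depth,
        "control_n": scn.control_n,
        "intended_phenotype": INTENDED_PHENOTYPE[scn.name],
        "variant": {
            "contig": variant.contig,
            "pos": variant.pos,
            "ref": variant.ref,
            "alt": variant.alt,
            "rsid": variant.rsid,
            "heterozygosity": variant.heterozygosity,
        },
        "cryptic_junction_coord": cryptic_jc,
        "planted_index_counts": index_counts,
        "planted_control_counts": control_counts,
    }
    return CaseBundle(
        scenario=scn,
        params=params,
        reference={params.contig: reference},
        gene_model=GeneModel([params.transcript()]),
        variant=variant,
        models=models,
        index_reads=index_reads,
        control_read_sets=control_sets,
        manifest=manifest,
    )
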