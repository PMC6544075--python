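"""Molecular-phenotype assignment for variant-bearing cases.

Each case (one tumour carrying one variant affecting one splice site) is
assigned exactly one of three molecular phenotypes:

* ``aberrant`` — the variant demonstrably disrupts splicing;
* ``likely_aberrant`` — information and/or expression evidence point the
  same way but fall short of the strongest combination;
* ``allele_specific`` — allele-specific alternative splicing, the
  benign-leaning phenotype.

The decision sequence encodes the published rule set:

1. Common polymorphisms (average heterozygosity > 0.01) are immediately
   allele-specific, since they are indistinguishable from germline
   polymorphisms.
2. Evidence conditions over the per-category tests: the *strong* condition
   S holds when a strongly-corroborating category reaches p <= 0.005, or
   when at least two categories reach p <= 0.05 with at least one of them
   strongly corroborating; the *weak* condition W holds when any strongly
   corroborating category reaches p <= 0.05.  Strongly-corroborating
   categories are the junction-level / variant-bearing ones
   (cryptic-junction use, exon skipping, intron inclusion with variant).
3. Natural sites combine S/W with information conditions: I_ab (dRi <= -4
   bits, the threshold that nearly completely excludes benign variants),
   I_char (dRi <= -2.7 bits with heterozygosity <= 0.002 or unknown, the
   calibrated aberrant characteristic) and I_benign (dRi > -2 bits; such
   losses do not detectably alter splicing).
4. Cryptic sites rest on the evidence conditions alone: aberrant iff S,
   likely aberrant iff W, else allele-specific.

Cases classified per site are then harmonised across all sites affected by
the same variant in the same tumour type (any aberrant site promotes the
rest), and summarised across tumours as the consensus molecular phenotype.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .read_evidence import (
    CRYPTIC_USE,
    EXON_SKIPPING,
    INTRON_INCLUSION,
    INTRON_INCLUSION_VARIANT,
)
from .splice_info import SiteImpact
from .veridical_stats import DEFAULT_ALPHA, EvidenceTest, REPORT_ALPHA, STRONG_ALPHA

ABERRANT = "aberrant"
LIKELY_ABERRANT = "likely_aberrant"
ALLELE_SPECIFIC = "allele_specific"
PHENOTYPES = (ABERRANT, LIKELY_ABERRANT, ALLELE_SPECIFIC)

#: junction-level / variant-bearing categories weigh more than bulk counts
STRONGLY_CORROBORATING = frozenset(
    {CRYPTIC_USE, EXON_SKIPPING, INTRON_INCLUSION_VARIANT}
)

COMMON_SNP_HETEROZYGOSITY = 0.01
RARE_HETEROZYGOSITY = 0.002
NATURAL_ABOLITION_DRI = -4.0
NATURAL_CHARACTERISTIC_DRI = -2.7
NATURAL_BENIGN_DRI = -2.0
CRYPTIC_STRONG_GAIN = 4.0
CRYPTIC_WEAK_GAIN = 3.0
R_I_MIN = 1.6  # minimum Ri of a functional (bindable in practice) cryptic site


@dataclass
class CaseClassification:
    case_id: str
    variant: object
    site_impact: SiteImpact
    phenotype: str
    bar_position: float
    reclassified: bool = False
    evidence_tests: tuple[EvidenceTest, ...] = ()
    tumor_type: str | None = None

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if not 0.0 <= self.bar_position <= 1.0:
            raise ValueError("bar_position must lie in [0, 1]")


@dataclass(frozen=True)
class ConsensusPhenotype:
    counts: Mapping[str, int]
    consensus: tuple[str, ...]
    total: int


def _evidence_conditions(
    tests: Sequence[EvidenceTest],
    alpha: float = DEFAULT_ALPHA,
    strong_alpha: float = STRONG_ALPHA,
) -> tuple[bool, bool, bool]:
    """(S, W, any_significant) evidence conditions from the category tests."""
    strong = [t for t in tests if t.category in STRONGLY_CORROBORATING]
    sig = [t for t in tests if t.p_value <= alpha]
    strong_sig = [t for t in strong if t.p_value <= alpha]
    s_cond = any(t.p_value <= strong_alpha for t in strong) or (
        len(sig) >= 2 and bool(strong_sig)
    )
    w_cond = bool(strong_sig)
    return s_cond, w_cond, bool(sig)


def classify_case(
    impact: SiteImpact,
    tests: Sequence[EvidenceTest],
    heterozygosity: float | None = None,
    case_id: str = "case",
    tumor_type: str | None = None,
    alpha: float = DEFAULT_ALPHA,
    strong_alpha: float = STRONG_ALPHA,
) -> CaseClassification:
    """Assign the molecular phenotype of one case (see module docstring).

    ``heterozygosity`` overrides the value carried on the variant record;
    missing heterozygosity is treated as a novel variant (<= 0.002).  With
    no evidence tests the classification rests on the information
    conditions alone, capped at likely_aberrant.
    """
    if heterozygosity is None:
        heterozygosity = impact.variant.heterozygosity
    het_known = heterozygosity is not None
    dri = impact.delta_r_i
    natural = impact.site.kind == "natural"

    if het_known and heterozygosity > COMMON_SNP_HETEROZYGOSITY:
        phenotype = ALLELE_SPECIFIC
    else:
        s_cond, w_cond, any_sig = _evidence_conditions(tests, alpha, strong_alpha)
        rare = (not het_known) or heterozygosity <= RARE_HETEROZYGOSITY
        if natural:
            i_ab = dri <= NATURAL_ABOLITION_DRI
            i_char = dri <= NATURAL_CHARACTERISTIC_DRI and rare
            if not tests:
                phenotype = LIKELY_ABERRANT if (i_ab or i_char) else ALLELE_SPECIFIC
            elif (i_ab and w_cond) or (i_char and s_cond):
                phenotype = ABERRANT
            elif (i_char and w_cond) or (i_ab and any_sig):
                phenotype = LIKELY_ABERRANT
            else:
                phenotype = ALLELE_SPECIFIC
        else:
            if not tests:
                phenotype = (
                    LIKELY_ABERRANT if dri >= CRYPTIC_STRONG_GAIN else ALLELE_SPECIFIC
                )
            elif s_cond:
                phenotype = ABERRANT
            elif w_cond:
                phenotype = LIKELY_ABERRANT
            else:
                phenotype = ALLELE_SPECIFIC

    bar = evidence_bar_position(
        impact, tests, heterozygosity, alpha=alpha, strong_alpha=strong_alpha
    )
    return CaseClassification(
        case_id=case_id,
        variant=impact.variant,
        site_impact=impact,
        phenotype=phenotype,
        bar_position=bar,
        evidence_tests=tuple(tests),
        tumor_type=tumor_type,
    )


def evidence_bar_position(
    impact: SiteImpact,
    tests: Sequence[EvidenceTest],
    heterozygosity: float | None = None,
    alpha: float = DEFAULT_ALPHA,
    strong_alpha: float = STRONG_ALPHA,
) -> float:
    """Position of the evidence bar within the assigned category, in [0, 1].

    Each supporting item scores +1, each contrasting item -1; the net score
    is mapped affinely so that a balanced case sits at 0.5, an
    all-supporting case at 1.0 and an all-contrasting case at 0.0.
    Supporting items: strong information change (dRi <= -2.7 for natural,
    gain >= 4 bits for cryptic), S, W, exonic cryptic location, rarity
    (heterozygosity <= 0.002 or unknown).  Contrasting items: weak
    information change (dRi > -2 natural / gain < 3 cryptic), no
    significant test, intermediate heterozygosity in (0.002, 0.01].
    """
    s_cond, w_cond, any_sig = _evidence_conditions(tests, alpha, strong_alpha)
    dri = impact.delta_r_i
    natural = impact.site.kind == "natural"
    rare = heterozygosity is None or heterozygosity <= RARE_HETEROZYGOSITY

    if natural:
        info_support = dri <= NATURAL_CHARACTERISTIC_DRI
        info_contrast = dri > NATURAL_BENIGN_DRI
    else:
        info_support = dri >= CRYPTIC_STRONG_GAIN
        info_contrast = dri < CRYPTIC_WEAK_GAIN

    supporting = [info_support, s_cond, w_cond, rare]
    if not natural:
        supporting.append(impact.location_class == "exonic")
    contrasting = [
        info_contrast,
        not any_sig,
        heterozygosity is not None
        and RARE_HETEROZYGOSITY < heterozygosity <= COMMON_SNP_HETEROZYGOSITY,
    ]

    score = sum(supporting) - sum(contrasting)
    if score >= 0:
        pos = 0.5 + 0.5 * score / len(supporting)
    else:
        pos = 0.5 + 0.5 * score / len(contrasting)
    return min(1.0, max(0.0, pos))


def reclassify_across_sites(cases: Sequence[CaseClassification]) -> list[CaseClassification]:
    """Harmonise the classifications of all sites affected by one variant in
    one tumour type: if any site is aberrant, every site becomes aberrant
    (flagged as reclassified when changed).  Idempotent."""
    if any(c.phenotype == ABERRANT for c in cases):
        return [
            c
            if c.phenotype == ABERRANT
            else replace(c, phenotype=ABERRANT, reclassified=True)
            for c in cases
        ]
    return list(cases)


def consensus_phenotype(cases: Sequence[CaseClassification | str]) -> ConsensusPhenotype:
    """Most frequent classification among all cases of one variant.

    All phenotypes sharing the maximal count are reported (ties yield
    multiple consensus phenotypes).
    """
    if not cases:
        raise ValueError("consensus requires at least one case")
    labels = [c if isinstance(c, str) else c.phenotype for c in cases]
    counts = Counter(labels)
    top = max(counts.values())
    consensus = tuple(p for p in PHENOTYPES if counts.get(p, 0) == top)
    return ConsensusPhenotype(
        counts={p: counts.get(p, 0) for p in PHENOTYPES},
        consensus=consensus,
        total=len(labels),
    )


def igv_eligibility(
    case: CaseClassification,
    population_frequency: float | None = None,
    min_reads: int = 5,
    max_frequency: float = 0.01,
    report_alpha: float = REPORT_ALPHA,
) -> bool:
    """Screenshot-grade evidence gate.

    True iff a strongly-corroborating category holds at least ``min_reads``
    index reads, the variant's population frequency is below
    ``max_frequency`` (or unknown), and some test reaches p <= 0.01.
    """
    if population_frequency is not None and population_frequency >= max_frequency:
        return False
    counted = any(
        t.index_count >= min_reads
        for t in case.evidence_tests
        if t.category in STRONGLY_CORROBORATING
    )
    significant = any(t.p_value <= report_alpha for t in case.evidence_tests)
    return counted and significant


MASQUERADE_TIERS = ((5.0, ">=5"), (3.0, ">=3"), (1.0, ">=1"), (0.0, ">0"))


@dataclass(frozen=True)
class MasqueradeResult:
    """Control-activity tiers for evidence categories insignificant in the index.

    A non-``none`` tier flags naturally occurring alternative splicing that
    masquerades as a splicing mutation.  A cryptic-use tier is only
    meaningful when the cryptic site was already functional in the wildtype
    sequence (Ri,initial > Ri,min = 1.6 bits); violations are reported as
    inconsistencies rather than tiers.
    """

    tiers: Mapping[str, str]
    inconsistencies: tuple[str, ...] = ()


def masquerade_screen(
    tests: Sequence[EvidenceTest],
    cryptic_r_i_initial: float | None = None,
    alpha: float = DEFAULT_ALPHA,
    r_i_min: float = R_I_MIN,
) -> MasqueradeResult:
    """Tier the mean control activity of categories not significant in the index."""
    tiers: dict[str, str] = {}
    inconsistencies: list[str] = []
    for t in tests:
        if t.p_value <= alpha:
            continue
        mean_control = sum(t.control_counts) / len(t.control_counts)
        tier = "none"
        for threshold, label in MASQUERADE_TIERS:
            if mean_control >= threshold and mean_control > 0.0:
                tier = label
                break
        if (
            t.category == CRYPTIC_USE
            and tier != "none"
            and (cryptic_r_i_initial is None or cryptic_r_i_initial <= r_i_min)
        ):
            inconsistencies.append(CRYPTIC_USE)
            tier = "none"
        tiers[t.category] = tier
    return MasqueradeResult(tiers=tiers, inconsistencies=tuple(inconsistencies))
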