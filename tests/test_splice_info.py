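"""Splice-site information models: weight construction, window scoring,
the affinity fold-change relation, variant assessment and candidate filters."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicevet.splice_info import (
    DONOR,
    GeneModel,
    SiteGeometry,
    SpliceModel,
    Transcript,
    VariantRecord,
    assess_variant,
    build_model,
    extract_window,
    filter_candidates,
    fold_change,
    reverse_complement,
    score_site,
    window_span,
)


# -- model construction ---------------------------------------------------------


def test_uniform_training_set_gives_zero_weights_and_zero_rsequence():
    # each base once per position -> f = 0.25 -> weight = 2 + log2(0.25) = 0
    seqs = ["AAA", "CCC", "GGG", "TTT"]
    model = build_model(seqs, DONOR, geometry=SiteGeometry(-1, 2), pseudocount=0.0)
    assert np.allclose(model.weights, 0.0)
    assert model.r_sequence == pytest.approx(0.0, abs=1e-12)


def test_single_sequence_pseudocounted_weights_match_hand_evaluation():
    # one "GT" with pseudocount 0.25: matched f = 1.25/2, weight = 2 + log2(0.625)
    model = build_model(["GT"], DONOR, geometry=SiteGeometry(-1, 1), pseudocount=0.25)
    expected = 2.0 + math.log2(1.25 / 2.0)
    assert model.weights[0, 2] == pytest.approx(expected, abs=1e-9)  # G at -1
    assert model.weights[1, 3] == pytest.approx(expected, abs=1e-9)  # T at +1
    assert expected == pytest.approx(1.3219, abs=1e-4)


def test_rsequence_is_mean_training_score(toy_model):
    model, seqs = toy_model
    mean_score = np.mean([score_site(model, s) for s in seqs])
    assert model.r_sequence == pytest.approx(mean_score, abs=1e-9)
    assert model.r_sequence >= 0.0


@pytest.mark.parametrize(
    "seqs,err",
    [
        ([], "empty"),
        (["GTA", "GT"], "length"),
        (["GNT"], "non-ACGT"),
    ],
)
def test_build_model_input_validation(seqs, err):
    with pytest.raises(ValueError, match=err):
        build_model(seqs, DONOR, geometry=SiteGeometry(-1, 2), pseudocount=0.25)


# -- scoring --------------------------------------------------------------------


def test_all_windows_match_brute_force_summation(toy_model):
    """Exhaustive oracle: every 3-mer scores the sum of its per-position weights
    recomputed from raw counts by the 2 + log2(f) formula."""
    model, seqs = toy_model
    n, pc = len(seqs), model.pseudocount
    counts = np.zeros((3, 4))
    for s in seqs:
        for l, b in enumerate(s):
            counts[l, "ACGT".index(b)] += 1
    expected_weights = 2.0 + np.log2((counts + pc) / (n + 4 * pc))
    for window in itertools.product("ACGT", repeat=3):
        window = "".join(window)
        oracle = sum(expected_weights[l, "ACGT".index(b)] for l, b in enumerate(window))
        assert score_site(model, window) == pytest.approx(oracle, abs=1e-9)


def test_consensus_scores_sum_of_position_maxima(toy_model):
    model, _ = toy_model
    assert score_site(model, model.consensus()) == pytest.approx(
        model.max_score(), abs=1e-9
    )


def test_uniform_model_scores_every_window_zero():
    model = build_model(["AAA", "CCC", "GGG", "TTT"], DONOR, SiteGeometry(-1, 2), 0.0)
    for window in itertools.product("ACGT", repeat=3):
        assert score_site(model, "".join(window)) == pytest.approx(0.0, abs=1e-12)


def test_ambiguous_base_contributes_position_minimum(toy_model):
    model, _ = toy_model
    with_n = score_site(model, "ANT")
    worst = min(score_site(model, f"A{b}T") for b in "ACGT")
    assert with_n == pytest.approx(worst, abs=1e-9)


def test_wrong_window_length_rejected(toy_model):
    model, _ = toy_model
    with pytest.raises(ValueError, match="length"):
        score_site(model, "ACGT")


def test_sampled_window_mean_matches_rsequence(model_set):
    """Mean score of windows sampled from the model's own positional
    frequencies estimates Rsequence (within 3 standard errors)."""
    rng = np.random.default_rng(123)
    model = model_set.donor
    freqs = model.frequencies()
    freqs = freqs / freqs.sum(axis=1, keepdims=True)
    n = 10_000
    bases = np.array(list("ACGT"))
    scores = np.zeros(n)
    for l in range(model.span):
        draws = rng.choice(4, size=n, p=freqs[l])
        scores += model.weights[l, draws]
    se = scores.std(ddof=1) / math.sqrt(n)
    assert abs(scores.mean() - model.r_sequence) < 3 * se


# -- affinity relation ----------------------------------------------------------


@pytest.mark.parametrize("bits,fold", [(3.0, 8.0), (2.0, 4.0), (0.0, 1.0), (-3.0, 8.0)])
def test_fold_change_examples(bits, fold):
    assert fold_change(bits) == pytest.approx(fold, abs=1e-12)


@given(
    a=st.floats(min_value=-8, max_value=8),
    b=st.floats(min_value=0, max_value=8),
)
@settings(max_examples=50, derandomize=True)
def test_fold_change_is_multiplicative_for_same_sign_changes(a, b):
    # adding bits multiplies the minimum affinity change
    assert fold_change(abs(a) + b) == pytest.approx(
        fold_change(abs(a)) * fold_change(b), rel=1e-9
    )


# -- strand geometry ------------------------------------------------------------


def test_minus_strand_window_is_reverse_complement_of_mirror():
    geometry = SiteGeometry(-2, 3)
    seq = "ACGTACGTACGTACGT"
    jc = 8
    plus = extract_window(seq, jc, geometry, "+")
    minus = extract_window(seq, jc, geometry, "-")
    lo, hi = window_span(jc, geometry, "-")
    assert minus == reverse_complement(seq[lo - 1 : hi])
    assert len(plus) == len(minus) == geometry.span


def test_minus_strand_natural_sites_mirror_plus_strand():
    plus = Transcript("p", "c", "+", ((11, 20), (31, 40)))
    minus = Transcript("m", "c", "-", ((11, 20), (31, 40)))
    plus_sites = {(s.polarity, s.junction_coord) for s in plus.natural_sites()}
    minus_sites = {(s.polarity, s.junction_coord) for s in minus.natural_sites()}
    assert plus_sites == {("donor", 21), ("acceptor", 31)}
    assert minus_sites == {("donor", 30), ("acceptor", 20)}


# -- variant assessment ---------------------------------------------------------


def test_donor_gt_disruption_weakens_the_natural_site(skip_bundle):
    b = skip_bundle
    impacts = assess_variant(
        b.variant, b.reference, b.gene_model, b.models.donor, b.models.acceptor
    )
    naturals = [i for i in impacts if i.site.kind == "natural"]
    assert len(naturals) == 1
    impact = naturals[0]
    assert impact.site.polarity == "donor"
    assert impact.r_i_final < impact.r_i_initial
    assert impact.delta_r_i == pytest.approx(
        impact.r_i_final - impact.r_i_initial, abs=1e-12
    )
    assert impact.distance_to_natural == 0


def test_cryptic_gain_is_exonic_and_beats_the_natural_site(cryptic_bundle):
    b = cryptic_bundle
    impacts = assess_variant(
        b.variant, b.reference, b.gene_model, b.models.donor, b.models.acceptor
    )
    jc = b.manifest["cryptic_junction_coord"]
    planted = [
        i
        for i in impacts
        if i.site.kind == "cryptic"
        and i.site.polarity == "donor"
        and i.site.junction_coord == jc
    ]
    assert len(planted) == 1
    impact = planted[0]
    assert impact.delta_r_i >= 2.0
    assert impact.location_class == "exonic"
    assert impact.r_i_final > impact.nearest_cognate_natural_r_i
    assert impact.distance_to_natural == abs(jc - 2101)


def test_reference_allele_yields_zero_delta_everywhere(skip_bundle):
    b = skip_bundle
    v = b.variant
    null = VariantRecord(v.contig, v.pos, v.ref, v.ref)
    for impact in assess_variant(
        null, b.reference, b.gene_model, b.models.donor, b.models.acceptor
    ):
        assert impact.delta_r_i == pytest.approx(0.0, abs=1e-12)


def test_variant_outside_all_windows_yields_empty_list(skip_bundle):
    b = skip_bundle
    pos = 5500  # far 3' of the gene, beyond the scan radius of any window
    v = VariantRecord("chrT", pos, b.reference["chrT"][pos - 1], "A" if b.reference["chrT"][pos - 1] != "A" else "C")
    assert (
        assess_variant(v, b.reference, b.gene_model, b.models.donor, b.models.acceptor)
        == []
    )


def test_ref_mismatch_and_out_of_bounds_are_errors(skip_bundle):
    b = skip_bundle
    bad_base = "A" if b.variant.ref != "A" else "C"
    with pytest.raises(ValueError, match="ref allele mismatch"):
        assess_variant(
            VariantRecord("chrT", b.variant.pos, bad_base, "G"),
            b.reference, b.gene_model, b.models.donor, b.models.acceptor,
        )
    with pytest.raises(ValueError, match="outside reference bounds"):
        assess_variant(
            VariantRecord("chrT", 10**7, "A", "C"),
            b.reference, b.gene_model, b.models.donor, b.models.acceptor,
        )


def test_deletion_rescoring_shifts_the_window(skip_bundle):
    """A deletion inside the donor window pulls downstream sequence into it;
    the rescored window must come from the mutated sequence."""
    b = skip_bundle
    seq = b.reference["chrT"]
    pos = 2098  # donor window position -3; deletes through the GT dinucleotide
    deletion = VariantRecord("chrT", pos, seq[pos - 1 : pos + 4], seq[pos - 1])
    impacts = assess_variant(
        deletion, b.reference, b.gene_model, b.models.donor, b.models.acceptor
    )
    naturals = [i for i in impacts if i.site.kind == "natural"]
    assert naturals, "deletion reaching into the donor window must be assessed"
    assert naturals[0].r_i_final != pytest.approx(naturals[0].r_i_initial)


# -- candidate filters ----------------------------------------------------------


def _impact(kind, delta, r_final, nearest=5.0, variant=None):
    from splicevet.splice_info import SiteImpact, SpliceSite

    v = variant or VariantRecord("chrT", 100, "A", "C")
    site = SpliceSite("chrT", 50, "+", "donor", kind)
    return SiteImpact(
        variant=v,
        site=site,
        r_i_initial=r_final - delta,
        r_i_final=r_final,
        nearest_cognate_natural_r_i=nearest,
        distance_to_natural=10,
        location_class="exonic",
    )


@pytest.mark.parametrize(
    "impact,kept",
    [
        (_impact("natural", -3.0, 2.0), True),
        (_impact("natural", +1.2, 9.0), False),  # strengthened natural excluded
        (_impact("cryptic", 2.5, 8.0, nearest=7.0), True),
        (_impact("cryptic", 2.5, 6.0, nearest=7.0), False),  # below natural
        (_impact("cryptic", 1.9, 8.0, nearest=7.0), False),  # gain below 2 bits
        (_impact("cryptic", 2.5, -0.4, nearest=-1.0), False),  # not bindable
        (_impact("cryptic", -1.0, 8.0, nearest=7.0), False),  # weakened cryptic
    ],
)
def test_filter_candidate_rules(impact, kept):
    assert (filter_candidates([impact]) == [impact]) is kept


def test_filter_is_idempotent_and_order_preserving():
    impacts = [
        _impact("natural", -3.0, 2.0),
        _impact("cryptic", 2.5, 8.0, nearest=7.0),
        _impact("natural", -0.5, 9.0),
        _impact("cryptic", 4.0, 9.5, nearest=7.0),
    ]
    once = filter_candidates(impacts)
    assert filter_candidates(once) == once
    positions = [impacts.index(i) for i in once]
    assert positions == sorted(positions)
    assert filter_candidates([]) == []


# -- serialization --------------------------------------------------------------


def test_model_tsv_round_trip(tmp_path, model_set):
    path = tmp_path / "donor.tsv"
    model_set.donor.to_tsv(path)
    loaded = SpliceModel.from_tsv(path)
    assert loaded.polarity == model_set.donor.polarity
    assert loaded.geometry == model_set.donor.geometry
    assert loaded.r_sequence == pytest.approx(model_set.donor.r_sequence, abs=1e-9)
    assert np.allclose(loaded.weights, model_set.donor.weights, atol=1e-9)
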