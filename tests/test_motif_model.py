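"""Anchoring, consensus calling, PWM construction and information content."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigiscan.motif_model import (
    DEFAULT_SPEC,
    MotifSpec,
    align_as_printed,
    anchor_align,
    build_model,
    column_frequencies,
    consensus_column_frequency,
    consensus_from_pwm,
    derive_consensus,
    information_content,
    logo_matrix,
    matches_iupac,
    read_logo,
    write_logo,
)
from sigiscan.seed_corpus import PromoterSeed, PromoterSeedSet


def make_set(*sequences):
    seeds = tuple(PromoterSeed(gene_name=f"s{i}", locus_tags=(f"L{i}",),
                               organism="Ct", aligned_sequence=seq)
                  for i, seq in enumerate(sequences))
    return PromoterSeedSet(name="test", seeds=seeds)


# --- anchoring --------------------------------------------------------------

@pytest.mark.parametrize("gene, set_name, m35, spacer, m10, tetrad", [
    ("xyn10Z", "ct_candidates_table2", 9, 14, 26, "CGAA"),
    ("sigI3", "ct_sigI_table1", 13, 14, 30, "CGTA"),
    ("sigI1", "ct_sigI_table1", 13, 13, 29, "CGAA"),  # printed gap shortens spacer
    ("cipA", "ct_candidates_table2", 9, 14, 26, "CGAA"),
])
def test_anchor_matches_published_placement(gene, set_name, m35, spacer, m10, tetrad):
    from sigiscan.seed_corpus import load_seed_set

    seed = load_seed_set(set_name).get(gene)
    a = anchor_align([seed], name="one").anchored[0]
    assert (a.minus35_start, a.spacer_len, a.minus10_start) == (m35, spacer, m10)
    assert a.region_sequence("minus10", DEFAULT_SPEC) == tetrad


def test_constructed_exact_match_anchors_uniquely():
    a = anchor_align(make_set("AAA" + "T" * 13 + "CGAA"), name="x").anchored[0]
    assert (a.minus35_start, a.spacer_len, a.minus10_start) == (1, 13, 17)


def test_rejected_rows_are_exactly_the_degenerate_core_rows(table1, table2):
    """Only rows whose printed -35 triad is incomplete fail re-anchoring."""
    assert set(anchor_align(table1).rejected_names) == {"Ct:sigI7", "Cs:sigI7"}
    assert set(anchor_align(table2).rejected_names) == {
        "Ct:cel9P", "Ct:rsgI9", "Ct:sdbA", "Ct:Clo1313_1436"}


def test_rejections_carry_reasons(table1):
    aligned = anchor_align(table1)
    for _seed, reason in aligned.rejected:
        assert "placement" in reason


def test_empty_seed_set_errors():
    with pytest.raises(ValueError, match="empty"):
        anchor_align([])


def test_invalid_spacer_range_errors():
    with pytest.raises(ValueError, match="spacer_min"):
        MotifSpec(spacer_min=15, spacer_max=13)


# --- column frequencies and consensus ---------------------------------------

def test_column_frequencies_identical_seeds():
    aligned = anchor_align(make_set("AAA" + "T" * 13 + "CGAA",
                                    "AAA" + "G" * 13 + "CGAA"), name="x")
    freqs = column_frequencies(aligned, "minus10")
    assert [max(f, key=f.get) for f in freqs] == ["C", "G", "A", "A"]
    assert all(max(f.values()) == 1.0 for f in freqs)


def test_single_seed_frequencies_are_unit():
    aligned = anchor_align(make_set("AAA" + "T" * 13 + "CGAA"), name="x")
    for f in column_frequencies(aligned, "minus35_core"):
        assert max(f.values()) == 1.0


def test_table1_minus10_third_column_fraction(table1):
    """Two of the 14 operon promoters carry C in the -10 tetrad's third
    position; the A fraction is 12/14."""
    freqs = column_frequencies(align_as_printed(table1), "minus10")
    assert freqs[2]["A"] == pytest.approx(10 / 14)
    assert freqs[2]["A"] + freqs[2]["T"] == pytest.approx(12 / 14)


def test_unknown_region_errors(table1):
    with pytest.raises(ValueError, match="region"):
        column_frequencies(anchor_align(table1), "minus20")


def test_consensus_identity_at_full_threshold():
    seq = "TGCGTC" + "AAA" + "T" * 13 + "CGAA" + "GTAC" + "TA"
    aligned = anchor_align(make_set(*([seq] * 4)), name="x")
    cons = derive_consensus(aligned, threshold=1.0)
    assert cons.minus35_consensus == "TGCGTCAAA"
    assert cons.minus10_consensus == "CGAA"
    assert cons.downstream_consensus == "TA"


def test_table1_consensus_reproduces_printed_cores(table1):
    cons = derive_consensus(align_as_printed(table1), threshold=0.85)
    assert cons.minus35_consensus.endswith("AAA")
    assert cons.minus35_consensus[0] == "C"  # the conserved 5' C
    assert cons.minus10_consensus == "CGWA"


def test_sigI6_consensus_has_CGAA_and_extension_C(m6):
    assert m6.consensus.minus10_consensus == "CGAA"
    # CNNAAA: the C sits three columns 5' of the AAA triad
    assert m6.consensus.minus35_consensus[3] == "C"
    assert m6.consensus.minus35_consensus.endswith("AAA")
    assert m6.consensus.downstream_consensus == "TW"


def test_sigI3_consensus_matches_degenerate_tetrad(m3):
    assert m3.consensus.minus10_consensus == "CGWA"
    # C-rich extension: CC at the CCCYY positions fully conserved
    assert m3.consensus.minus35_consensus[1:3] == "CC"


def test_consensus_threshold_validation(table1):
    with pytest.raises(ValueError, match="threshold"):
        derive_consensus(anchor_align(table1), threshold=1.5)


def test_consensus_never_contradicts_frequency_maxima(m6, m3):
    from sigiscan.motif_model import iupac_bases

    for model in (m6, m3):
        for region, pwm in (("minus35", model.pwm_minus35),
                            ("minus10", model.pwm_minus10),
                            ("downstream", model.pwm_downstream)):
            cons = model.consensus_string(region)
            for sym, col in zip(cons, pwm):
                if sym == "N":
                    continue
                best = max(col, key=col.get)
                assert best in iupac_bases(sym)


# --- model construction ------------------------------------------------------

def test_pwm_pseudocount_zero_matches_counts():
    aligned = anchor_align(make_set(*(["AAA" + "T" * 13 + "CGAA"] * 4)), name="x")
    model = build_model(aligned, pseudocount=0.0)
    assert model.pwm_minus10[0]["C"] == pytest.approx(1.0)
    mixed = anchor_align(make_set("AAA" + "T" * 13 + "CGAA",
                                  "AAA" + "T" * 13 + "CGTA"), name="x")
    model = build_model(mixed, pseudocount=0.0)
    assert model.pwm_minus10[2]["A"] == pytest.approx(0.5)
    assert model.pwm_minus10[2]["T"] == pytest.approx(0.5)


def test_spacer_distribution_plus_one_smoothing(v6_aligned):
    """Spacer counts {13: 2, 14: 8} smooth to 3/12 and 9/12."""
    model = build_model(v6_aligned)
    assert 2.0 ** model.spacer_logprob[13] == pytest.approx(3 / 12)
    assert 2.0 ** model.spacer_logprob[14] == pytest.approx(9 / 12)


def test_pwm_columns_normalized(m6):
    for pwm in (m6.pwm_minus35, m6.pwm_minus10, m6.pwm_downstream):
        for col in pwm:
            assert sum(col.values()) == pytest.approx(1.0, abs=1e-9)


def test_model_yaml_round_trip(tmp_path, m6):
    from sigiscan.motif_model import BipartiteMotifModel

    path = tmp_path / "m6.yaml"
    m6.save(path)
    back = BipartiteMotifModel.load(path)
    assert back.pwm_minus10 == m6.pwm_minus10
    assert back.spacer_logprob == m6.spacer_logprob
    assert back.min_score == m6.min_score
    assert back.consensus.minus10_consensus == m6.consensus.minus10_consensus


# --- information content and logos -------------------------------------------

@pytest.mark.parametrize("column, bits", [
    ({"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0}, 2.0),
    ({"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}, 0.0),
    ({"A": 0.5, "C": 0.5, "G": 0.0, "T": 0.0}, 1.0),
])
def test_information_content_analytic(column, bits):
    assert information_content([column])[0] == pytest.approx(bits)


def test_information_content_validates_sums():
    with pytest.raises(ValueError, match="sum to 1"):
        information_content([{"A": 0.5, "C": 0.0, "G": 0.0, "T": 0.0}])


def test_small_sample_correction_subtracts_term():
    col = [{"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0}]
    corrected = information_content(col, small_sample_correction=True, n=10)[0]
    assert corrected == pytest.approx(2.0 - 3 / (2 * math.log(2) * 10))


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
def test_information_content_bounds(weights):
    col = np.array(weights) / sum(weights)
    ic = information_content(col.reshape(1, 4))
    assert 0.0 <= ic[0] <= 2.0


def test_logo_heights_for_perfect_and_uniform_columns():
    perfect = [{"A": 0.0, "C": 1.0, "G": 0.0, "T": 0.0}] * 4
    rows = logo_matrix(perfect)
    assert all(r[2]["C"] == pytest.approx(2.0) for r in rows)
    uniform = [{b: 0.25 for b in "ACGT"}] * 3
    assert all(h == 0.0 for _, _, hs in logo_matrix(uniform) for h in hs.values())


def test_logo_tsv_round_trip(tmp_path, m6):
    path = tmp_path / "logo.tsv"
    write_logo(m6, path)
    assert read_logo(path) == logo_matrix(m6)  # bit-exact via repr


# --- IUPAC helpers -----------------------------------------------------------

@pytest.mark.parametrize("seq, pattern, ok", [
    ("CGAA", "CGWA", True),
    ("CGTA", "CGWA", True),
    ("CGCA", "CGWA", False),
    ("CGCA", "CGNA", True),
    ("CGA", "CGWA", False),
])
def test_matches_iupac(seq, pattern, ok):
    assert matches_iupac(seq, pattern) is ok


def test_consensus_from_pwm_calls_degenerate_symbols():
    pwm = [{"A": 0.5, "T": 0.4, "C": 0.05, "G": 0.05},
           {"A": 0.95, "T": 0.02, "C": 0.02, "G": 0.01},
           {"A": 0.3, "T": 0.3, "C": 0.3, "G": 0.1}]
    assert consensus_from_pwm(pwm, threshold=0.85) == "WAN"


def test_consensus_column_frequency_degenerate():
    f = {"A": 0.7, "T": 0.2, "C": 0.1, "G": 0.0}
    assert consensus_column_frequency(f, "W") == pytest.approx(0.9)
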