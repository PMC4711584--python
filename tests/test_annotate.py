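"""Promoter annotation, classification and variant rescoring."""

import math

import numpy as np
import pytest

from sigiscan.annotate import (
    annotate_promoter,
    classify_promoter,
    iter_placements,
    rescore_variant,
    score_site,
)
from sigiscan.motif_model import (
    BipartiteMotifModel,
    MotifSpec,
    anchor_align,
    build_model,
)
from sigiscan.seed_corpus import load_seed_set


def uniform_model(name="uniform"):
    spec = MotifSpec()
    ncols35 = spec.minus35_extension_len + spec.core35_len
    uni = {b: 0.25 for b in "ACGT"}
    return BipartiteMotifModel(
        name=name, spec=spec,
        pwm_minus35=[dict(uni) for _ in range(ncols35)],
        pwm_minus10=[dict(uni) for _ in range(4)],
        pwm_downstream=[dict(uni) for _ in range(2)],
        spacer_logprob={13: math.log2(0.5), 14: math.log2(0.5)},
        background=dict(uni), min_score=0.0)


def sharp_model(name="sharp"):
    """Near-consensus PWM over CGACAC AAA / CGAA / TA, uniform background."""
    spec = MotifSpec()

    def col(base, p=0.91):
        rest = (1 - p) / 3
        return {b: (p if b == base else rest) for b in "ACGT"}

    return BipartiteMotifModel(
        name=name, spec=spec,
        pwm_minus35=[col(b) for b in "CGACACAAA"],
        pwm_minus10=[col(b) for b in "CGAA"],
        pwm_downstream=[col(b) for b in "TA"],
        spacer_logprob={13: math.log2(0.25), 14: math.log2(0.75)},
        background={b: 0.25 for b in "ACGT"}, min_score=5.0)


def test_uniform_model_scores_spacer_term_only():
    m = uniform_model()
    seq = "A" * 40
    assert score_site(seq, m, minus10_start=24, spacer_len=14) == pytest.approx(0.0)
    assert score_site(seq, m, minus10_start=23, spacer_len=13) == pytest.approx(0.0)


def test_consensus_sequence_scores_sum_of_column_maxima():
    m = sharp_model()
    seq = "CGACACAAA" + "T" * 14 + "CGAA" + "GGGG" + "TA"
    expected = 15 * math.log2(0.91 / 0.25)  # 9 + 4 + 2 consensus columns
    assert score_site(seq, m, minus10_start=24, spacer_len=14) == pytest.approx(expected)


def test_score_site_out_of_bounds_errors():
    m = uniform_model()
    with pytest.raises(ValueError, match="bounds"):
        score_site("A" * 30, m, minus10_start=28, spacer_len=13)
    with pytest.raises(ValueError, match="spacer"):
        score_site("A" * 40, m, minus10_start=24, spacer_len=20)


def test_brute_force_recomputation_from_serialized_model(tmp_path, m6):
    """Independent oracle: re-sum the log-odds from the YAML document."""
    import yaml

    path = tmp_path / "m.yaml"
    m6.save(path)
    doc = yaml.safe_load(path.read_text())
    seed = load_seed_set("ct_candidates_table2").get("xyn10Z")
    seq = seed.sequence
    s10, spacer = 26, 14
    q = doc["background"]
    cols = (list(doc["pwm_minus35"]) + list(doc["pwm_minus10"])
            + list(doc["pwm_downstream"]))
    positions = (list(range(s10 - spacer - 9, s10 - spacer))       # ext+core
                 + list(range(s10, s10 + 4))                        # -10
                 + list(range(s10 + 8, s10 + 10)))                  # downstream
    expected = sum(math.log2(col[seq[p - 1]] / q[seq[p - 1]])
                   for col, p in zip(cols, positions))
    expected += (doc["spacer_logprob"][spacer]
                 - max(doc["spacer_logprob"].values()))
    assert score_site(seq, m6, s10, spacer) == pytest.approx(expected, abs=1e-9)


def test_xyn10Z_annotation_layout(m6):
    seed = load_seed_set("ct_candidates_table2").get("xyn10Z")
    ann = annotate_promoter(seed.sequence, m6)
    assert ann is not None
    assert ann.minus10_pos == (26, 29) and ann.minus10_seq == "CGAA"
    assert ann.spacer_len == 14
    assert ann.downstream_pos == (34, 35) and ann.downstream_seq == "TA"


def test_random_sequence_without_tetrad_is_rejected(m6):
    rng = np.random.default_rng(7)
    for _ in range(10):
        seq = "".join(rng.choice(list("AT"), size=40))  # no C/G at all
        assert annotate_promoter(seq, m6) is None


def test_all_validated_seeds_annotate_under_their_model(m6, m3):
    for set_name, model in (("sigI6_validated", m6), ("sigI3_validated", m3)):
        for seed in load_seed_set(set_name):
            assert annotate_promoter(seed.sequence, model) is not None


def test_annotation_oracle_equivalence_small_sequences(m6):
    """Exhaustive brute force over every placement agrees with the search."""
    rng = np.random.default_rng(11)
    bases = list("ACGT")
    for _ in range(25):
        seq = "".join(rng.choice(bases, p=[0.305, 0.195, 0.195, 0.305],
                                 size=rng.integers(40, 200)))
        best = max(
            ((score_site(seq, m6, s10, sp), s10, -sp)
             for s10, sp in iter_placements(seq, m6.spec)),
            default=None)
        ann = annotate_promoter(seq, m6, min_score=float("-inf"))
        assert ann.score == pytest.approx(best[0])
        assert (ann.minus10_pos[0], -ann.spacer_len) == (best[1], best[2])


def test_cipA_recognized_by_both_models(m6, m3):
    cipA = load_seed_set("ct_candidates_table2").get("cipA")
    ranked = classify_promoter(cipA.sequence, [m6, m3])
    assert {name for name, _ in ranked} == {"sigI6", "sigI3"}


def test_pl11_ranks_sigI3_first(m6, m3):
    """The C-rich extension of pl11 matches the sigma-I3 signature."""
    pl11 = load_seed_set("ct_candidates_table2").get("pl11")
    ranked = classify_promoter(pl11.sequence, [m6, m3])
    assert ranked and ranked[0][0] == "sigI3"


def test_model_consensus_classifies_under_itself(m6):
    seq = ("ACGACAC" + "AAA" + "T" * 14 + "CGAA" + "TATA" + "TA" + "ACGT")
    ranked = classify_promoter(seq, [m6])
    assert len(ranked) == 1 and ranked[0][0] == "sigI6"


def test_sequence_failing_all_models_gives_empty_list(m6, m3):
    assert classify_promoter("AT" * 20, [m6, m3]) == []


def test_classify_requires_models(m6):
    with pytest.raises(ValueError, match="model"):
        classify_promoter("ACGT" * 10, [])


def test_monotonic_degradation_at_consensus_columns(m6):
    """Replacing a consensus base never raises the score and strictly
    lowers it where the column is non-uniform."""
    seed = load_seed_set("ct_candidates_table2").get("xyn10Z")
    seq = seed.sequence
    ann = annotate_promoter(seq, m6)
    for pos in range(ann.minus10_pos[0], ann.minus10_pos[1] + 1):
        for alt in "ACGT":
            if alt == seq[pos - 1]:
                continue
            eff = rescore_variant(seq, m6, pos, alt)
            assert eff.delta_score < 0


def test_minus10_mutations_are_deleterious(m6):
    seed = load_seed_set("ct_candidates_table2").get("xyn10Z")
    eff = rescore_variant(seed.sequence, m6, 26, "T")  # C of CGAA
    assert eff.delta_score < -2
    assert eff.hits_consensus_column
    assert eff.column_label == "-10 col 1"


def test_spacer_mutation_is_score_neutral(m6):
    """Spacer bases are unscored, so substitutions there cost nothing."""
    seed = load_seed_set("ct_candidates_table2").get("xyn10Z")
    ann = annotate_promoter(seed.sequence, m6)
    pos = ann.minus35_pos[1] + 3  # inside the spacer
    ref = seed.sequence[pos - 1]
    alt = "G" if ref != "G" else "C"
    eff = rescore_variant(seed.sequence, m6, pos, alt)
    assert eff.delta_score == pytest.approx(0.0)
    assert not eff.hits_consensus_column
    assert eff.column_label == "spacer/flank"


def test_extension_mutation_consensus_flag_matches_frequencies(m6):
    """The CGA extension columns sit below the 85% threshold, so mutating
    them is scored but not flagged as consensus; the C at -3 is flagged."""
    seed = load_seed_set("ct_candidates_table2").get("xyn10Z")
    ann = annotate_promoter(seed.sequence, m6)
    ext_start = ann.minus35_pos[0] - m6.spec.minus35_extension_len
    cons = m6.consensus.minus35_consensus
    for col in range(m6.spec.minus35_extension_len):
        pos = ext_start + col
        ref = seed.sequence[pos - 1]
        alt = "G" if ref != "G" else "C"
        eff = rescore_variant(seed.sequence, m6, pos, alt)
        assert eff.hits_consensus_column == (cons[col] != "N")


def test_variant_validation(m6):
    seed = load_seed_set("ct_candidates_table2").get("xyn10Z")
    with pytest.raises(ValueError, match="equals"):
        rescore_variant(seed.sequence, m6, 26, "C")
    with pytest.raises(ValueError, match="position"):
        rescore_variant(seed.sequence, m6, 999, "A")


def test_non_iupac_sequence_rejected(m6):
    with pytest.raises(ValueError, match="non-IUPAC"):
        annotate_promoter("ACGT" * 9 + "XY", m6)


def test_ambiguity_codes_scored_as_background_average(m6):
    """An N at a scored column contributes the background-weighted mean."""
    seed = load_seed_set("ct_candidates_table2").get("xyn10Z")
    seq_n = seed.sequence[:25] + "N" + seed.sequence[26:]
    s_ref = score_site(seed.sequence, m6, 26, 14)
    s_n = score_site(seq_n, m6, 26, 14)
    assert s_n < s_ref  # averaging over bases dilutes the consensus C
    assert math.isfinite(s_n)
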