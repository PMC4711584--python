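"""Locate and score bipartite promoter elements within single sequences.

Scoring is summed log2-odds of the PWM columns (extension + -35 core, -10
core, downstream element) against the model background, plus a spacer
penalty of ``spacer_logprob(k) - max_k spacer_logprob`` (zero for the modal
spacer length).  Annotation evaluates every (-10 position x allowed spacer)
placement exhaustively and keeps the best; variant rescoring holds the
wild-type placement fixed so score changes are attributable to columns, as
in a promoter mutational scan read against a logo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .motif_model import (
    BASES,
    BipartiteMotifModel,
    MotifSpec,
    AlignedPromoterSet,
    iupac_bases,
)


@dataclass(frozen=True)
class PromoterAnnotation:
    """Located promoter elements within one sequence (1-based inclusive spans).

    ``minus35_pos`` spans the core triad only; the scored extension columns
    lie immediately 5' of it.  ``spacer_len`` is the gap between the -35
    core end and the -10 start.
    """

    sequence: str
    model_name: str
    minus35_pos: tuple[int, int]
    minus10_pos: tuple[int, int]
    downstream_pos: tuple[int, int]
    spacer_len: int
    score: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValueError("annotation score must be finite")
        if not (self.minus35_pos[1] < self.minus10_pos[0] <= self.minus10_pos[1]
                < self.downstream_pos[0]):
            raise ValueError("element spans must be ordered 5'->3' without overlap")
        if self.spacer_len != self.minus10_pos[0] - self.minus35_pos[1] - 1:
            raise ValueError("spacer_len inconsistent with element spans")

    def element(self, which: str) -> str:
        span = {"minus35": self.minus35_pos, "minus10": self.minus10_pos,
                "downstream": self.downstream_pos}[which]
        return self.sequence[span[0] - 1:span[1]]

    @property
    def minus35_seq(self) -> str:
        return self.element("minus35")

    @property
    def minus10_seq(self) -> str:
        return self.element("minus10")

    @property
    def downstream_seq(self) -> str:
        return self.element("downstream")


@dataclass(frozen=True)
class VariantEffect:
    """Score effect of a single-base substitution under a fixed placement."""

    position: int
    ref_base: str
    alt_base: str
    delta_score: float
    hits_consensus_column: bool
    column_label: str


def _column_logodds(column: Mapping[str, float], background: Mapping[str, float],
                    symbol: str) -> float:
    """log2-odds of one PWM column for a possibly degenerate base symbol.

    IUPAC codes are scored as the background-weighted average over the
    covered bases, for both the foreground and the background term.
    """
    bases = iupac_bases(symbol)
    if len(bases) == 1:
        return math.log2(column[bases[0]] / background[bases[0]])
    wsum = sum(background[b] for b in bases)
    p_eff = sum(background[b] * column[b] for b in bases) / wsum
    q_eff = sum(background[b] * background[b] for b in bases) / wsum
    return math.log2(p_eff / q_eff)


def score_site(sequence: str, model: BipartiteMotifModel, minus10_start: int,
               spacer_len: int) -> float:
    """Score one placement, identified by its -10 start (1-based) and spacer.

    The placement must fit entirely within the sequence, including the -35
    extension columns and the downstream element.
    """
    spec = model.spec
    if not spec.spacer_min <= spacer_len <= spec.spacer_max:
        raise ValueError(f"spacer {spacer_len} outside model range "
                         f"[{spec.spacer_min}, {spec.spacer_max}]")
    seq = sequence.upper()
    ext_start = minus10_start - spacer_len - spec.core35_len - spec.minus35_extension_len
    down_end = (minus10_start + spec.core10_len - 1
                + spec.downstream_offset + spec.downstream_len)
    if ext_start < 1 or down_end > len(seq):
        raise ValueError("placement out of sequence bounds")

    q = model.background
    score = 0.0
    pos = ext_start
    for col in model.pwm_minus35:
        score += _column_logodds(col, q, seq[pos - 1])
        pos += 1
    pos = minus10_start
    for col in model.pwm_minus10:
        score += _column_logodds(col, q, seq[pos - 1])
        pos += 1
    pos = minus10_start + spec.core10_len + spec.downstream_offset
    for col in model.pwm_downstream:
        score += _column_logodds(col, q, seq[pos - 1])
        pos += 1
    score += model.spacer_logprob[spacer_len] - model.max_spacer_logprob
    return score


def iter_placements(sequence: str, spec: MotifSpec) -> Iterable[tuple[int, int]]:
    """All (minus10_start, spacer_len) placements fitting in the sequence."""
    n = len(sequence)
    for spacer in range(spec.spacer_min, spec.spacer_max + 1):
        first = 1 + spec.minus35_extension_len + spec.core35_len + spacer
        last = n - spec.core10_len - spec.downstream_offset - spec.downstream_len + 1
        for s10 in range(first, last + 1):
            yield s10, spacer


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - set(IUPAC_OK)
    if bad:
        raise ValueError(f"sequence contains non-IUPAC characters: {sorted(bad)}")
    return seq


IUPAC_OK = set("ACGTRYSWKMBDHVN")


def _annotation_for(seq: str, model: BipartiteMotifModel, s10: int,
                    spacer: int, score: float) -> PromoterAnnotation:
    spec = model.spec
    m35 = s10 - spacer - spec.core35_len
    d0 = s10 + spec.core10_len + spec.downstream_offset
    return PromoterAnnotation(
        sequence=seq, model_name=model.name,
        minus35_pos=(m35, m35 + spec.core35_len - 1),
        minus10_pos=(s10, s10 + spec.core10_len - 1),
        downstream_pos=(d0, d0 + spec.downstream_len - 1),
        spacer_len=spacer, score=score)


def annotate_promoter(sequence: str, model: BipartiteMotifModel,
                      min_score: float | None = None) -> PromoterAnnotation | None:
    """Best-scoring promoter placement in a sequence, or None below threshold.

    Ties are broken toward the 3'-most -10 position, then the smaller
    spacer.  ``min_score`` defaults to the model's calibrated threshold;
    pass ``-inf`` to always get the best placement.
    """
    seq = _validate_sequence(sequence)
    cutoff = model.min_score if min_score is None else min_score
    if cutoff is None:
        raise ValueError(f"model {model.name!r} has no calibrated min_score; "
                         "pass min_score explicitly")
    best: tuple[float, int, int] | None = None  # (score, s10, -spacer) maximized
    for s10, spacer in iter_placements(seq, model.spec):
        s = score_site(seq, model, s10, spacer)
        key = (s, s10, -spacer)
        if best is None or key > best:
            best = key
    if best is None or best[0] < cutoff:
        return None
    score, s10, neg_spacer = best
    return _annotation_for(seq, model, s10, -neg_spacer, score)


def classify_promoter(sequence: str, models: Sequence[BipartiteMotifModel],
                      ) -> list[tuple[str, float]]:
    """Rank models by their best annotation score on the sequence.

    Models yielding no annotation (best score below their threshold) are
    omitted; an empty list means no model recognizes the sequence.
    """
    if not models:
        raise ValueError("need at least one model")
    ranked = []
    for model in models:
        ann = annotate_promoter(sequence, model)
        if ann is not None:
            ranked.append((model.name, ann.score))
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return ranked


def _column_label_at(ann: PromoterAnnotation, spec: MotifSpec,
                     position: int) -> tuple[str | None, int]:
    """(region, 1-based column) covering the position, or (None, 0)."""
    ext_start = ann.minus35_pos[0] - spec.minus35_extension_len
    if ext_start <= position < ann.minus35_pos[0]:
        return "minus35_ext", position - ext_start + 1
    if ann.minus35_pos[0] <= position <= ann.minus35_pos[1]:
        return "minus35_core", position - ann.minus35_pos[0] + 1
    if ann.minus10_pos[0] <= position <= ann.minus10_pos[1]:
        return "minus10", position - ann.minus10_pos[0] + 1
    if ann.downstream_pos[0] <= position <= ann.downstream_pos[1]:
        return "downstream", position - ann.downstream_pos[0] + 1
    return None, 0


def rescore_variant(sequence: str, model: BipartiteMotifModel, position: int,
                    alt_base: str, re_search: bool = False,
                    min_score: float | None = None) -> VariantEffect:
    """Score change from a point substitution in a promoter sequence.

    The wild-type placement is held fixed by default so the effect is
    attributable to the mutated column; ``re_search=True`` instead re-runs
    the full placement search on the variant (modelling a promoter that may
    be rescued by an alternative register).  ``hits_consensus_column`` is
    True when the position falls in a column whose trained consensus symbol
    is not N.
    """
    seq = _validate_sequence(sequence)
    if not 1 <= position <= len(seq):
        raise ValueError(f"position {position} outside sequence of length {len(seq)}")
    alt = alt_base.upper()
    if alt not in BASES:
        raise ValueError(f"alt_base must be one of {BASES}")
    ref = seq[position - 1]
    if alt == ref:
        raise ValueError("alt_base equals the reference base")

    wt_ann = annotate_promoter(seq, model, min_score=float("-inf"))
    assert wt_ann is not None  # -inf cutoff always yields a placement
    var_seq = seq[:position - 1] + alt + seq[position:]
    if re_search:
        var_ann = annotate_promoter(var_seq, model, min_score=float("-inf"))
        var_score = var_ann.score
    else:
        var_score = score_site(var_seq, model, wt_ann.minus10_pos[0], wt_ann.spacer_len)

    spec = model.spec
    region, col = _column_label_at(wt_ann, spec, position)
    labels = {"minus35_ext": "-35 ext col", "minus35_core": "-35 col",
              "minus10": "-10 col", "downstream": "downstream col"}
    if region is None:
        label = "spacer/flank"
        hits = False
    else:
        label = f"{labels[region]} {col}"
        hits = False
        cons = model.consensus_string({"minus35_ext": "minus35", "minus35_core": "minus35",
                                       "minus10": "minus10", "downstream": "downstream"}[region])
        if cons is not None:
            if region == "minus35_core":
                idx = spec.minus35_extension_len + col - 1
            elif region == "minus35_ext":
                idx = col - 1
            else:
                idx = col - 1
            hits = cons[idx] != "N"
    return VariantEffect(position=position, ref_base=ref, alt_base=alt,
                         delta_score=var_score - wt_ann.score,
                         hits_consensus_column=hits, column_label=label)


def calibrate_min_score(model: BipartiteMotifModel, aligned: AlignedPromoterSet,
                        margin: float = 1.0) -> BipartiteMotifModel:
    """Set the hit-calling threshold from the model's own training seeds.

    The threshold is the minimum best-placement score over the anchored
    seeds minus ``margin`` (default one point), so every training promoter
    is recovered with headroom.  Returns the model (mutated in place).
    """
    scores = []
    for a in aligned.anchored:
        ann = annotate_promoter(a.seed.sequence, model, min_score=float("-inf"))
        scores.append(ann.score)
    if not scores:
        raise ValueError("cannot calibrate from an empty alignment")
    model.min_score = min(scores) - margin
    return model
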