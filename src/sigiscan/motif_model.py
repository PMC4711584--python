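"""Bipartite -35/-10 promoter motif models with a variable spacer.

The promoter class modelled here is the clostridial sigma-I family motif:
an "extended -35" AAA triad (with up to six 5' extension columns that carry
factor-specific information, e.g. the C of CNNAAA for sigma-I6 or the
CCCYY run for sigma-I3), a 13-14 nt spacer, a -10 tetrad whose printed
consensus is CGWA, and a TW dinucleotide four bases downstream of the -10.

Three representations are provided:

* :class:`AlignedPromoterSet` - seeds anchored on the two cores, either by
  deterministic re-anchoring (:func:`anchor_align`) or by trusting the
  printed gapped alignment (:func:`align_as_printed`);
* :class:`ConsensusMotif` - per-column IUPAC consensus at a conservation
  threshold (default 85%), limited to 2-fold degenerate symbols;
* :class:`BipartiteMotifModel` - position weight matrices with background
  pseudocounts plus a smoothed spacer-length distribution, scored as summed
  log2-odds (see :mod:`sigiscan.annotate`).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .seed_corpus import PromoterSeed, PromoterSeedSet

BASES = ("A", "C", "G", "T")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
# 2-fold degenerate codes, the only ones consensus calling may emit.
TWOFOLD = {"K": "GT", "M": "AC", "R": "AG", "S": "CG", "W": "AT", "Y": "CT"}
# Tie-break order for equally-covering 2-fold codes: prefer the pair that is
# a priori more frequent in a low-GC genome (W first, S last), then
# alphabetically within the mixed weak/strong pairs.
TWOFOLD_PRECEDENCE = ("W", "K", "M", "R", "Y", "S")


def iupac_bases(symbol: str) -> str:
    try:
        return IUPAC[symbol.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {symbol!r}") from None


def matches_iupac(sequence: str, pattern: str) -> bool:
    """True if ``sequence`` (concrete bases) matches the IUPAC ``pattern``."""
    if len(sequence) != len(pattern):
        return False
    return all(b in iupac_bases(p) for b, p in zip(sequence.upper(), pattern))


def background_from_gc(gc: float) -> dict[str, float]:
    if not 0.0 < gc < 1.0:
        raise ValueError("GC fraction must lie in (0, 1)")
    return {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}


#: Genomic background matched to the low-GC C. thermocellum chromosome.
DEFAULT_BACKGROUND = background_from_gc(0.39)


@dataclass(frozen=True)
class MotifSpec:
    """Geometry and anchor patterns of the bipartite motif.

    ``minus10_core`` is the consensus label of the -10 tetrad (CGWA);
    ``minus10_anchor`` is the pattern used to *locate* the tetrad when
    anchoring seeds.  It defaults to CGNA because the seed alignments place
    tetrads with C or G at the third position (e.g. the sigI4 promoter pair)
    in the -10 block, while the derived consensus over the set is still CGWA.
    """

    minus35_core: str = "AAA"
    minus10_core: str = "CGWA"
    minus10_anchor: str = "CGNA"
    spacer_min: int = 13
    spacer_max: int = 14
    minus35_extension_len: int = 6
    downstream_offset: int = 4
    downstream_len: int = 2

    def __post_init__(self) -> None:
        if self.spacer_min > self.spacer_max:
            raise ValueError("spacer_min must be <= spacer_max")
        if min(self.spacer_min, self.minus35_extension_len,
               self.downstream_offset, self.downstream_len) < 0:
            raise ValueError("spec lengths must be non-negative")
        for pat in (self.minus35_core, self.minus10_core, self.minus10_anchor):
            if not pat:
                raise ValueError("core patterns must be non-empty")
            for sym in pat:
                iupac_bases(sym)
        if len(self.minus10_anchor) != len(self.minus10_core):
            raise ValueError("minus10_anchor must have the length of minus10_core")

    @property
    def core35_len(self) -> int:
        return len(self.minus35_core)

    @property
    def core10_len(self) -> int:
        return len(self.minus10_core)

    def placement_len(self, spacer_len: int) -> int:
        """Total span covered by one placement at the given spacer length."""
        return (self.minus35_extension_len + self.core35_len + spacer_len
                + self.core10_len + self.downstream_offset + self.downstream_len)

    @property
    def min_placement_len(self) -> int:
        return self.placement_len(self.spacer_min)


#: Default spec; the sigma-I6 and sigma-I3 models share the geometry and
#: differ only in their training seed sets.
DEFAULT_SPEC = MotifSpec()

REGIONS = ("minus35_ext", "minus35_core", "minus10", "downstream")


@dataclass(frozen=True)
class AnchoredSeed:
    """A seed with its cores located in gapless 1-based coordinates."""

    seed: PromoterSeed
    minus35_start: int  # first base of the AAA core
    minus10_start: int
    spacer_len: int

    def region_span(self, region: str, spec: MotifSpec) -> tuple[int, int]:
        """1-based inclusive span of a region within the gapless sequence.

        Extension spans may start below 1 for short seeds; callers must clip.
        """
        if region == "minus35_core":
            return self.minus35_start, self.minus35_start + spec.core35_len - 1
        if region == "minus35_ext":
            return (self.minus35_start - spec.minus35_extension_len,
                    self.minus35_start - 1)
        if region == "minus10":
            return self.minus10_start, self.minus10_start + spec.core10_len - 1
        if region == "downstream":
            start = (self.minus10_start + spec.core10_len + spec.downstream_offset)
            return start, start + spec.downstream_len - 1
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")

    def region_sequence(self, region: str, spec: MotifSpec) -> str:
        """Region bases; positions outside the seed are returned as '.'"""
        seq = self.seed.sequence
        start, end = self.region_span(region, spec)
        out = []
        for pos in range(start, end + 1):
            out.append(seq[pos - 1] if 1 <= pos <= len(seq) else ".")
        return "".join(out)


@dataclass(frozen=True)
class AlignedPromoterSet:
    name: str
    spec: MotifSpec
    anchored: tuple[AnchoredSeed, ...]
    rejected: tuple[tuple[PromoterSeed, str], ...] = ()

    def __len__(self) -> int:
        return len(self.anchored)

    @property
    def spacer_lengths(self) -> tuple[int, ...]:
        return tuple(a.spacer_len for a in self.anchored)

    @property
    def rejected_names(self) -> tuple[str, ...]:
        return tuple(seed.key for seed, _ in self.rejected)


def _find_anchor(sequence: str, spec: MotifSpec,
                 gap_after: Iterable[int] = ()) -> tuple[int, int, int] | None:
    """Locate the 3'-most -10 anchor with a -35 core at an allowed spacer.

    Returns 1-based (minus35_start, minus10_start, spacer_len) or None.
    Preference is the 3'-most -10 tetrad, then the largest spacer (the
    published alignments left-justify the -35 triad within poly-A runs).

    ``gap_after`` lists gapless indices k where the stored alignment places
    a gap between bases k and k+1.  Printed gaps shorten the spacer, so a
    placement whose printed spacer width (gapless spacer + gaps inside it)
    would exceed ``spacer_max``, or whose cores a gap would interrupt, is
    not considered.
    """
    gap_counts = Counter(gap_after)
    n = len(sequence)
    k10 = spec.core10_len
    k35 = spec.core35_len
    for s10 in range(n - k10 + 1, 0, -1):  # 1-based, 3'-most first
        if not matches_iupac(sequence[s10 - 1:s10 - 1 + k10], spec.minus10_anchor):
            continue
        for spacer in range(spec.spacer_max, spec.spacer_min - 1, -1):
            s35 = s10 - spacer - k35
            if s35 < 1:
                continue
            if not matches_iupac(sequence[s35 - 1:s35 - 1 + k35], spec.minus35_core):
                continue
            m35_end = s35 + k35 - 1
            if any(s35 <= k < m35_end or s10 <= k < s10 + k10 - 1
                   for k in gap_counts):
                continue  # printed gap interrupts a core
            gaps_in_spacer = sum(v for k, v in gap_counts.items()
                                 if m35_end <= k <= s10 - 1)
            if spacer + gaps_in_spacer > spec.spacer_max:
                continue  # printed spacer would be too wide
            return s35, s10, spacer
    return None


def _gap_positions(aligned_sequence: str) -> tuple[int, ...]:
    """Gapless indices k such that a gap sits between bases k and k+1."""
    out = []
    k = 0
    for ch in aligned_sequence:
        if ch == "-":
            out.append(k)
        else:
            k += 1
    return tuple(out)


def anchor_align(seeds: PromoterSeedSet | Iterable[PromoterSeed],
                 spec: MotifSpec = DEFAULT_SPEC,
                 name: str | None = None) -> AlignedPromoterSet:
    """Deterministically anchor each seed on its -10 and -35 cores.

    Gap characters in the stored alignment are ignored (they only shorten
    spacers); anchoring operates on the gapless sequence.  Seeds with no
    valid placement are reported in ``rejected`` with a reason, never
    silently dropped.
    """
    seed_list = tuple(seeds)
    if not seed_list:
        raise ValueError("empty seed set")
    set_name = name or getattr(seeds, "name", "aligned")
    anchored, rejected = [], []
    for seed in seed_list:
        hit = _find_anchor(seed.sequence, spec, _gap_positions(seed.aligned_sequence))
        if hit is None:
            reason = (f"no {spec.minus35_core}/{spec.minus10_anchor} placement with "
                      f"spacer in [{spec.spacer_min}, {spec.spacer_max}]")
            rejected.append((seed, reason))
        else:
            s35, s10, spacer = hit
            anchored.append(AnchoredSeed(seed=seed, minus35_start=s35,
                                         minus10_start=s10, spacer_len=spacer))
    return AlignedPromoterSet(name=set_name, spec=spec,
                              anchored=tuple(anchored), rejected=tuple(rejected))


def align_as_printed(seeds: PromoterSeedSet,
                     spec: MotifSpec = DEFAULT_SPEC) -> AlignedPromoterSet:
    """Build an alignment that trusts the printed gapped layout.

    All seeds of the set must share one aligned width, with gaps confined to
    the spacer.  The -10 block's alignment columns are taken from the rows
    that anchor unambiguously (they must agree); the -35 core then sits
    ``spacer_max`` columns 5' of the -10 because gaps pad shorter spacers.
    Rows that would fail re-anchoring (degenerate cores) are retained at the
    printed columns - this reproduces the published consensus row exactly.
    """
    widths = {len(s.aligned_sequence) for s in seeds}
    if len(widths) != 1:
        raise ValueError(f"printed alignment has ragged widths {sorted(widths)}")

    # Map each anchorable row's gapless -10 start back to its gapped column.
    col_votes: Counter[int] = Counter()
    for seed in seeds:
        hit = _find_anchor(seed.sequence, spec, _gap_positions(seed.aligned_sequence))
        if hit is None:
            continue
        _s35, s10, _spacer = hit
        gapless = 0
        for col, ch in enumerate(seed.aligned_sequence, start=1):
            if ch != "-":
                gapless += 1
                if gapless == s10:
                    col_votes[col] += 1
                    break
    if not col_votes:
        raise ValueError("no seed in the set anchors; cannot infer printed columns")
    col10, votes = col_votes.most_common(1)[0]
    if votes != sum(col_votes.values()):
        raise ValueError(f"anchored rows disagree on the printed -10 column: {dict(col_votes)}")
    col35 = col10 - spec.spacer_max - spec.core35_len

    anchored = []
    for seed in seeds:
        aligned = seed.aligned_sequence
        gaps_before = lambda col: aligned.count("-", 0, col - 1)  # noqa: E731
        m10 = col10 - gaps_before(col10)
        m35 = col35 - gaps_before(col35)
        anchored.append(AnchoredSeed(seed=seed, minus35_start=m35, minus10_start=m10,
                                     spacer_len=m10 - m35 - spec.core35_len))
    return AlignedPromoterSet(name=f"{seeds.name}:printed", spec=spec,
                              anchored=tuple(anchored))


def column_frequencies(aligned: AlignedPromoterSet, region: str) -> list[dict[str, float]]:
    """Per-column base fractions for one region, 5'->3'.

    Seeds too short to cover an extension column are excluded from that
    column's denominator.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    if not aligned.anchored:
        raise ValueError("alignment holds no anchored seeds")
    spec = aligned.spec
    ncol = {"minus35_ext": spec.minus35_extension_len,
            "minus35_core": spec.core35_len,
            "minus10": spec.core10_len,
            "downstream": spec.downstream_len}[region]
    out: list[dict[str, float]] = []
    for col in range(ncol):
        counts = Counter()
        for a in aligned.anchored:
            ch = a.region_sequence(region, spec)[col]
            if ch in BASES:
                counts[ch] += 1
        total = sum(counts.values())
        if total == 0:
            out.append({b: 0.25 for b in BASES})  # uncovered column: uninformative
        else:
            out.append({b: counts[b] / total for b in BASES})
    return out


@dataclass(frozen=True)
class ConsensusMotif:
    minus35_consensus: str  # extension + core columns
    minus10_consensus: str
    downstream_consensus: str
    threshold: float
    column_frequencies: dict[str, tuple[dict[str, float], ...]]

    def region_consensus(self, region: str) -> str:
        if region == "minus35_ext":
            return self.minus35_consensus[:-len(self.column_frequencies["minus35_core"])]
        if region == "minus35_core":
            return self.minus35_consensus[len(self.column_frequencies["minus35_ext"]):]
        if region == "minus10":
            return self.minus10_consensus
        if region == "downstream":
            return self.downstream_consensus
        raise ValueError(f"unknown region {region!r}")


def _call_column(freqs: Mapping[str, float], threshold: float,
                 allow_degenerate: bool) -> str:
    best_base = max(BASES, key=lambda b: (freqs[b], b))
    if freqs[best_base] >= threshold:
        return best_base
    if allow_degenerate:
        best_sym, best_frac = None, -1.0
        for sym in TWOFOLD_PRECEDENCE:
            frac = sum(freqs[b] for b in TWOFOLD[sym])
            if frac >= threshold and frac > best_frac + 1e-12:
                best_sym, best_frac = sym, frac
        if best_sym is not None:
            return best_sym
    return "N"


def derive_consensus(aligned: AlignedPromoterSet, threshold: float = 0.85,
                     allow_degenerate: bool = True) -> ConsensusMotif:
    """Call a degenerate consensus at a per-column conservation threshold.

    A column is assigned the single base whose fraction meets the threshold;
    failing that, the 2-fold IUPAC symbol whose two bases jointly meet it
    (the pair with the larger combined fraction wins, alphabetical symbol on
    ties); otherwise N.  Codes covering three bases are never emitted.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if len(aligned) < 2:
        raise ValueError("consensus calling needs at least 2 anchored seeds")
    freqs = {region: tuple(column_frequencies(aligned, region)) for region in REGIONS}
    call = {region: "".join(_call_column(f, threshold, allow_degenerate)
                            for f in freqs[region]) for region in REGIONS}
    return ConsensusMotif(
        minus35_consensus=call["minus35_ext"] + call["minus35_core"],
        minus10_consensus=call["minus10"],
        downstream_consensus=call["downstream"],
        threshold=threshold,
        column_frequencies=freqs,
    )


def consensus_from_pwm(pwm: Sequence[Mapping[str, float]], threshold: float = 0.85,
                       allow_degenerate: bool = True) -> str:
    """IUPAC consensus string called directly from PWM column probabilities."""
    return "".join(_call_column(col, threshold, allow_degenerate) for col in pwm)


def consensus_column_frequency(freqs: Mapping[str, float], symbol: str) -> float:
    """Fraction of seeds covered by an IUPAC consensus symbol at one column."""
    return sum(freqs[b] for b in iupac_bases(symbol))


@dataclass
class BipartiteMotifModel:
    """Probabilistic form of the bipartite motif: PWMs + spacer distribution.

    ``pwm_minus35`` covers the extension columns followed by the core; all
    PWM columns are base->probability mappings that sum to one.  Scores are
    summed log2-odds against ``background`` plus a spacer-length penalty of
    ``spacer_logprob[k] - max(spacer_logprob)`` (zero for the modal spacer).
    """

    name: str
    spec: MotifSpec
    pwm_minus35: list[dict[str, float]]
    pwm_minus10: list[dict[str, float]]
    pwm_downstream: list[dict[str, float]]
    spacer_logprob: dict[int, float]
    background: dict[str, float]
    min_score: float | None = None
    consensus: ConsensusMotif | None = None
    training_n: int = 0

    def __post_init__(self) -> None:
        for label, pwm in (("minus35", self.pwm_minus35), ("minus10", self.pwm_minus10),
                           ("downstream", self.pwm_downstream)):
            for i, col in enumerate(pwm):
                if abs(sum(col.values()) - 1.0) > 1e-9:
                    raise ValueError(f"{label} PWM column {i} does not sum to 1")
        total = sum(math.pow(2.0, lp) for lp in self.spacer_logprob.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("spacer probabilities do not sum to 1")
        if abs(sum(self.background.values()) - 1.0) > 1e-9:
            raise ValueError("background does not sum to 1")

    @property
    def max_spacer_logprob(self) -> float:
        return max(self.spacer_logprob.values())

    def pwm(self, region: str) -> list[dict[str, float]]:
        if region == "minus35":
            return self.pwm_minus35
        if region == "minus10":
            return self.pwm_minus10
        if region == "downstream":
            return self.pwm_downstream
        raise ValueError(f"unknown PWM region {region!r}")

    def consensus_string(self, region: str) -> str | None:
        if self.consensus is None:
            return None
        if region == "minus35":
            return self.consensus.minus35_consensus
        return self.consensus.region_consensus(region)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        doc = {
            "name": self.name,
            "spec": {k: getattr(self.spec, k) for k in (
                "minus35_core", "minus10_core", "minus10_anchor", "spacer_min",
                "spacer_max", "minus35_extension_len", "downstream_offset",
                "downstream_len")},
            "pwm_minus35": [dict(c) for c in self.pwm_minus35],
            "pwm_minus10": [dict(c) for c in self.pwm_minus10],
            "pwm_downstream": [dict(c) for c in self.pwm_downstream],
            "spacer_logprob": {int(k): float(v) for k, v in self.spacer_logprob.items()},
            "background": dict(self.background),
            "min_score": self.min_score,
            "training_n": self.training_n,
        }
        if self.consensus is not None:
            doc["consensus"] = {
                "minus35": self.consensus.minus35_consensus,
                "minus10": self.consensus.minus10_consensus,
                "downstream": self.consensus.downstream_consensus,
                "threshold": self.consensus.threshold,
            }
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "BipartiteMotifModel":
        consensus = None
        if "consensus" in doc:
            c = doc["consensus"]
            consensus = ConsensusMotif(
                minus35_consensus=c["minus35"], minus10_consensus=c["minus10"],
                downstream_consensus=c["downstream"], threshold=c["threshold"],
                column_frequencies={},
            )
        return cls(
            name=doc["name"], spec=MotifSpec(**doc["spec"]),
            pwm_minus35=[{b: float(p) for b, p in col.items()} for col in doc["pwm_minus35"]],
            pwm_minus10=[{b: float(p) for b, p in col.items()} for col in doc["pwm_minus10"]],
            pwm_downstream=[{b: float(p) for b, p in col.items()} for col in doc["pwm_downstream"]],
            spacer_logprob={int(k): float(v) for k, v in doc["spacer_logprob"].items()},
            background={b: float(p) for b, p in doc["background"].items()},
            min_score=doc.get("min_score"), consensus=consensus,
            training_n=int(doc.get("training_n", 0)),
        )

    def save(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "BipartiteMotifModel":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_model(aligned: AlignedPromoterSet, pseudocount: float = 0.5,
                background: Mapping[str, float] | None = None,
                name: str | None = None,
                consensus_threshold: float = 0.85) -> BipartiteMotifModel:
    """Estimate PWMs and the spacer distribution from an anchored alignment.

    Column probabilities are ``(count_b + 4*pseudocount*q_b) / (n + 4*pseudocount)``
    with q the background, i.e. the pseudocount mass is spread proportionally
    to the background.  Spacer lengths get +1 smoothing over the allowed range.
    The hit-calling threshold ``min_score`` is left unset; calibrate it with
    :func:`sigiscan.annotate.calibrate_min_score`.
    """
    if not aligned.anchored:
        raise ValueError("cannot build a model from an empty alignment")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    q = dict(background) if background is not None else dict(DEFAULT_BACKGROUND)
    if any(q.get(b, 0.0) <= 0 for b in BASES):
        raise ValueError("background must be positive on all four bases")
    spec = aligned.spec

    def pwm_for(regions: Sequence[str]) -> list[dict[str, float]]:
        cols: list[dict[str, float]] = []
        for region in regions:
            ncol = {"minus35_ext": spec.minus35_extension_len,
                    "minus35_core": spec.core35_len,
                    "minus10": spec.core10_len,
                    "downstream": spec.downstream_len}[region]
            for col in range(ncol):
                counts = Counter()
                for a in aligned.anchored:
                    ch = a.region_sequence(region, spec)[col]
                    if ch in BASES:
                        counts[ch] += 1
                n = sum(counts.values())
                denom = n + 4.0 * pseudocount
                if denom == 0:
                    cols.append({b: q[b] for b in BASES})
                    continue
                raw = {b: (counts[b] + 4.0 * pseudocount * q[b]) / denom for b in BASES}
                norm = sum(raw.values())
                cols.append({b: raw[b] / norm for b in BASES})
        return cols

    spacer_counts = Counter(aligned.spacer_lengths)
    smoothed = {k: spacer_counts.get(k, 0) + 1
                for k in range(spec.spacer_min, spec.spacer_max + 1)}
    total = sum(smoothed.values())
    spacer_logprob = {k: math.log2(v / total) for k, v in smoothed.items()}

    consensus = None
    if len(aligned) >= 2:
        consensus = derive_consensus(aligned, threshold=consensus_threshold)

    return BipartiteMotifModel(
        name=name or aligned.name, spec=spec,
        pwm_minus35=pwm_for(["minus35_ext", "minus35_core"]),
        pwm_minus10=pwm_for(["minus10"]),
        pwm_downstream=pwm_for(["downstream"]),
        spacer_logprob=spacer_logprob, background={b: q[b] for b in BASES},
        consensus=consensus, training_n=len(aligned),
    )


def information_content(frequencies: Sequence[Mapping[str, float]] | np.ndarray,
                        small_sample_correction: bool = False,
                        n: int | None = None) -> np.ndarray:
    """Per-column information content in bits: IC = 2 - H(column).

    With ``small_sample_correction`` the standard correction term
    e(n) = 3 / (2 ln2 n) is subtracted (clipped at zero).
    """
    if isinstance(frequencies, np.ndarray):
        mat = np.asarray(frequencies, dtype=float)
    else:
        mat = np.array([[col[b] for b in BASES] for col in frequencies], dtype=float)
    if mat.ndim != 2 or mat.shape[1] != 4:
        raise ValueError("frequencies must be a (columns x 4) table")
    sums = mat.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("every frequency column must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(mat > 0, mat * np.log2(mat), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    if small_sample_correction:
        if not n or n <= 0:
            raise ValueError("small-sample correction needs the sample size n")
        ic = ic - 3.0 / (2.0 * math.log(2.0) * n)
    return np.clip(ic, 0.0, 2.0)


def logo_matrix(model_or_freqs, small_sample_correction: bool = False,
                n: int | None = None) -> list[tuple[str, int, dict[str, float]]]:
    """Rows of (region, column index, base->height) with height = p * IC."""
    if isinstance(model_or_freqs, BipartiteMotifModel):
        blocks = [("minus35", model_or_freqs.pwm_minus35),
                  ("minus10", model_or_freqs.pwm_minus10),
                  ("downstream", model_or_freqs.pwm_downstream)]
    else:
        blocks = [("motif", list(model_or_freqs))]
    rows = []
    for region, cols in blocks:
        ic = information_content(cols, small_sample_correction, n)
        for i, col in enumerate(cols, start=1):
            rows.append((region, i, {b: col[b] * float(ic[i - 1]) for b in BASES}))
    return rows


def write_logo(model_or_freqs, path: str | Path, render: str | Path | None = None,
               small_sample_correction: bool = False, n: int | None = None) -> None:
    """Write a WebLogo-style letter-height matrix as TSV.

    Heights are p_b * IC(column) in bits.  If ``render`` names an image path
    a stacked-bar rendering is drawn with matplotlib (optional; the TSV is
    the canonical output and round-trips bit-exactly via repr precision).
    """
    rows = logo_matrix(model_or_freqs, small_sample_correction, n)
    with Path(path).open("w") as fh:
        fh.write("region\tcolumn\tA\tC\tG\tT\n")
        for region, idx, heights in rows:
            fh.write(f"{region}\t{idx}\t" +
                     "\t".join(repr(heights[b]) for b in BASES) + "\n")
    if render is not None:
        _render_logo(rows, render)


def read_logo(path: str | Path) -> list[tuple[str, int, dict[str, float]]]:
    rows = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["region", "column", "A", "C", "G", "T"]:
            raise ValueError(f"{path}: not a logo matrix TSV")
        for line in fh:
            region, idx, *vals = line.rstrip("\n").split("\t")
            rows.append((region, int(idx), dict(zip(BASES, map(float, vals)))))
    return rows


def _render_logo(rows, path) -> None:  # pragma: no cover - cosmetic output
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(rows)), 2.5))
    for x, (region, _idx, heights) in enumerate(rows):
        bottom = 0.0
        for b in sorted(BASES, key=lambda b: heights[b]):
            if heights[b] <= 0:
                continue
            ax.bar(x, heights[b], bottom=bottom, color=colors[b], width=0.8)
            bottom += heights[b]
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    ax.set_xticks(range(len(rows)))
    ax.set_xticklabels([f"{r[0][:3]}{r[1]}" for r in rows], rotation=90, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
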