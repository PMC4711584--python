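"""Ready-made sigma-I6 and sigma-I3 promoter models.

Both models share the default bipartite geometry (AAA / 13-14 nt spacer /
CGWA / TW four bases downstream, with six -35 extension columns) and differ
only in their training seeds: the reporter-validated promoter sets packaged
with the library (ten sigma-I6 promoters, four sigma-I3 promoters).
"""

from __future__ import annotations

from typing import Mapping

from .annotate import calibrate_min_score
from .motif_model import (
    DEFAULT_SPEC,
    AlignedPromoterSet,
    BipartiteMotifModel,
    MotifSpec,
    anchor_align,
    build_model,
)
from .seed_corpus import load_seed_set


def model_from_seed_set(set_name: str, spec: MotifSpec = DEFAULT_SPEC,
                        pseudocount: float = 0.5,
                        background: Mapping[str, float] | None = None,
                        margin: float = 1.0,
                        name: str | None = None) -> BipartiteMotifModel:
    """Anchor a packaged seed set, fit a model, and calibrate its threshold."""
    seeds = load_seed_set(set_name)
    aligned = anchor_align(seeds, spec)
    if aligned.rejected:
        names = ", ".join(aligned.rejected_names)
        raise ValueError(f"seed set {set_name!r} has non-anchoring seeds: {names}")
    model = build_model(aligned, pseudocount=pseudocount, background=background,
                        name=name or set_name)
    return calibrate_min_score(model, aligned, margin=margin)


def sigI6_model(**kwargs) -> BipartiteMotifModel:
    """Model of the sigma-I6 promoter class (consensus CNNAAA / CGAA)."""
    return model_from_seed_set("sigI6_validated", name="sigI6", **kwargs)


def sigI3_model(**kwargs) -> BipartiteMotifModel:
    """Model of the sigma-I3 promoter class (C-rich -35 extension / CGWA)."""
    return model_from_seed_set("sigI3_validated", name="sigI3", **kwargs)


def aligned_seed_set(set_name: str, spec: MotifSpec = DEFAULT_SPEC) -> AlignedPromoterSet:
    return anchor_align(load_seed_set(set_name), spec)
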