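"""Genome-wide scanning of upstream regions for sigma-I promoter candidates.

For each annotated gene the upstream window is extracted in coding-strand
orientation (optionally capped at neighbouring features), every placement
is scored under a bipartite motif model, and hits above the model threshold
are reported best-first with 5'UTR-like distances and genomic spans.
Ortholog support compares each hit's consensus-column bases with the best
hit upstream of the ortholog in a second genome.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotate import PromoterAnnotation, _annotation_for, iter_placements, score_site
from .genome_io import GeneAnnotation, GenomeRecord, UpstreamRegion, extract_upstream
from .motif_model import BipartiteMotifModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanParams:
    window: int = 1000
    min_score: float | None = None  # None -> model.min_score
    cap_at_features: bool = True
    max_hits_per_gene: int = 1

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.max_hits_per_gene < 1:
            raise ValueError("max_hits_per_gene must be >= 1")


@dataclass(frozen=True)
class CandidateHit:
    """A scored promoter prediction tied to a gene.

    ``utr_5p`` is the distance (nt) from the first base 3' of the downstream
    element to the gene start; ``genomic_start``/``genomic_end`` map the full
    scored span (extension through downstream element) back to plus-strand
    replicon coordinates.
    """

    gene_id: str
    gene_name: str | None
    model_name: str
    annotation: PromoterAnnotation
    utr_5p: int
    replicon_id: str
    genomic_start: int
    genomic_end: int
    strand: str
    ortholog_support: str | None = None  # supported / unsupported / no_ortholog
    ortholog_identity: float | None = None

    @property
    def score(self) -> float:
        return self.annotation.score


def scan_region(region: UpstreamRegion, model: BipartiteMotifModel,
                params: ScanParams = ScanParams(),
                gene: GeneAnnotation | None = None) -> list[CandidateHit]:
    """Score every placement in one upstream region and return accepted hits.

    Hits at or above the threshold are sorted best-first and reduced by
    greedy non-overlap selection to at most ``max_hits_per_gene``.
    """
    cutoff = params.min_score if params.min_score is not None else model.min_score
    if cutoff is None:
        raise ValueError("no min_score: calibrate the model or set ScanParams.min_score")
    seq = region.sequence
    spec = model.spec
    scored: list[tuple[float, int, int]] = []
    for s10, spacer in iter_placements(seq, spec):
        s = score_site(seq, model, s10, spacer)
        if s >= cutoff:
            scored.append((s, s10, spacer))
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))

    hits: list[CandidateHit] = []
    taken: list[tuple[int, int]] = []
    for s, s10, spacer in scored:
        ann = _annotation_for(seq, model, s10, spacer, s)
        ext_start = ann.minus35_pos[0] - spec.minus35_extension_len
        span = (ext_start, ann.downstream_pos[1])
        if any(not (span[1] < a or span[0] > b) for a, b in taken):
            continue
        taken.append(span)
        g1 = region.to_genomic(span[0])
        g2 = region.to_genomic(span[1])
        hits.append(CandidateHit(
            gene_id=region.gene_id,
            gene_name=gene.name if gene is not None else None,
            model_name=model.name, annotation=ann,
            utr_5p=len(seq) - ann.downstream_pos[1],
            replicon_id=region.replicon_id,
            genomic_start=min(g1, g2), genomic_end=max(g1, g2),
            strand=region.strand))
        if len(hits) >= params.max_hits_per_gene:
            break
    return hits


def scan_genome(genome: GenomeRecord, annotation: Sequence[GeneAnnotation],
                model: BipartiteMotifModel,
                params: ScanParams = ScanParams()) -> list[CandidateHit]:
    """Scan the upstream window of every annotated gene; deterministic order.

    Output is sorted by (score desc, gene_id).  Genes whose upstream region
    degenerates to zero length (immediately abutting a neighbour) yield no
    hits.
    """
    for g in annotation:
        if g.replicon_id != genome.replicon_id:
            raise ValueError(f"annotation references missing replicon {g.replicon_id!r}")
    hits: list[CandidateHit] = []
    caps = annotation if params.cap_at_features else None
    for gene in annotation:
        try:
            region = extract_upstream(genome, gene, window=params.window,
                                      cap_at_features=caps)
        except ValueError:
            continue  # zero-length upstream region
        hits.extend(scan_region(region, model, params, gene=gene))
    hits.sort(key=lambda h: (-h.score, h.gene_id))
    return hits


def _consensus_columns(model: BipartiteMotifModel,
                       ann: PromoterAnnotation) -> list[tuple[int, str]]:
    """(sequence position, consensus symbol) for every non-N consensus column."""
    if model.consensus is None:
        raise ValueError(f"model {model.name!r} carries no consensus")
    spec = model.spec
    cols: list[tuple[int, str]] = []
    ext_start = ann.minus35_pos[0] - spec.minus35_extension_len
    for i, sym in enumerate(model.consensus.minus35_consensus):
        if sym != "N":
            cols.append((ext_start + i, sym))
    for i, sym in enumerate(model.consensus.minus10_consensus):
        if sym != "N":
            cols.append((ann.minus10_pos[0] + i, sym))
    for i, sym in enumerate(model.consensus.downstream_consensus):
        if sym != "N":
            cols.append((ann.downstream_pos[0] + i, sym))
    return cols


def ortholog_support(hits: Sequence[CandidateHit], genome_b: GenomeRecord,
                     annotation_b: Sequence[GeneAnnotation],
                     ortholog_map: Mapping[str, str], model: BipartiteMotifModel,
                     params: ScanParams = ScanParams(),
                     min_element_identity: float = 1.0) -> list[CandidateHit]:
    """Fill ortholog-conservation fields on a list of hits.

    For each hit whose gene has an ortholog, the ortholog's upstream region
    is scanned with the same model; the hit is ``supported`` iff an ortholog
    hit exists whose bases at the model's consensus (non-N) columns match
    the query's at >= ``min_element_identity`` of those columns (IUPAC
    symbols compare by base-set overlap of the two concrete bases, i.e.
    equality).  ``ortholog_identity`` records the best such fraction.
    """
    genes_b = {g.gene_id: g for g in annotation_b}
    out: list[CandidateHit] = []
    for hit in hits:
        ortho_id = ortholog_map.get(hit.gene_id)
        if ortho_id is None:
            out.append(replace(hit, ortholog_support="no_ortholog"))
            continue
        gene_b = genes_b.get(ortho_id)
        if gene_b is None:
            logger.warning("ortholog %s of %s missing from annotation; marked no_ortholog",
                           ortho_id, hit.gene_id)
            out.append(replace(hit, ortholog_support="no_ortholog"))
            continue
        region_b = extract_upstream(genome_b, gene_b, window=params.window,
                                    cap_at_features=annotation_b if params.cap_at_features else None)
        # compare against every acceptable placement upstream of the ortholog
        bparams = ScanParams(window=params.window, min_score=params.min_score,
                             cap_at_features=params.cap_at_features,
                             max_hits_per_gene=max(4, params.max_hits_per_gene))
        ortho_hits = scan_region(region_b, model, bparams, gene=gene_b)
        query_cols = _consensus_columns(model, hit.annotation)
        best_identity = None
        for oh in ortho_hits:
            ortho_cols = _consensus_columns(model, oh.annotation)
            matches = sum(
                1 for (qp, _), (op, _) in zip(query_cols, ortho_cols)
                if hit.annotation.sequence[qp - 1] == oh.annotation.sequence[op - 1]
            )
            identity = matches / len(query_cols) if query_cols else 0.0
            if best_identity is None or identity > best_identity:
                best_identity = identity
        if best_identity is not None and best_identity >= min_element_identity:
            support = "supported"
        else:
            support = "unsupported"
        out.append(replace(hit, ortholog_support=support,
                           ortholog_identity=best_identity))
    return out


HIT_COLUMNS = ("gene_id", "name", "model", "score", "minus35_seq", "spacer_len",
               "minus10_seq", "downstream_seq", "utr_5p", "replicon", "start",
               "end", "strand", "ortholog_support", "ortholog_identity")


def write_hits_tsv(hits: Iterable[CandidateHit], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(HIT_COLUMNS)
        for h in hits:
            a = h.annotation
            w.writerow([
                h.gene_id, h.gene_name or "", h.model_name, f"{h.score:.4f}",
                a.minus35_seq, a.spacer_len, a.minus10_seq, a.downstream_seq,
                h.utr_5p, h.replicon_id, h.genomic_start, h.genomic_end, h.strand,
                h.ortholog_support or "",
                "" if h.ortholog_identity is None else f"{h.ortholog_identity:.3f}",
            ])


def write_bed(hits: Sequence[CandidateHit], path: str | Path) -> None:
    """BED6 export of promoter spans (0-based half-open; score scaled 0-1000)."""
    scores = [h.score for h in hits]
    lo = min(scores, default=0.0)
    hi = max(scores, default=1.0)
    span = (hi - lo) or 1.0
    with Path(path).open("w") as fh:
        for h in hits:
            bed_score = int(round(1000 * (h.score - lo) / span))
            fh.write("\t".join([
                h.replicon_id, str(h.genomic_start - 1), str(h.genomic_end),
                h.gene_id, str(bed_score), h.strand]) + "\n")
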