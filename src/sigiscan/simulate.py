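"""Synthetic genomes with planted promoter instances and a known truth table.

The generator emulates the context the promoter models are meant for: a
low-GC (default 39% GC) bacterial chromosome where genes alternate with
intergenic gaps and a chosen fraction of genes carries one promoter
instance, sampled from a bipartite motif model, ending a known distance
upstream of the gene start on the coding strand.  Genes sit on both strands
so strand handling is exercised end to end.  Everything is driven by a
single integer seed and is byte-reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome_io import GeneAnnotation, GenomeRecord, reverse_complement
from .motif_model import BASES, BipartiteMotifModel, consensus_from_pwm
from .scan import CandidateHit


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic genome.

    Defaults model a small low-GC chromosome: 20 genes of 300-900 nt
    separated by 320-500 nt intergenic gaps, 40% of genes with a planted
    promoter ending 20-120 nt before the start codon.  The intergenic
    minimum must leave room for two planted sites plus offsets (one for a
    minus-strand gene on the left of a gap, one for a plus-strand gene on
    its right), which the constructor validates.
    """

    n_genes: int = 20
    genome_gc: float = 0.39
    gene_len_range: tuple[int, int] = (300, 900)
    intergenic_len_range: tuple[int, int] = (320, 500)
    planted_fraction: float = 0.4
    plant_offset_range: tuple[int, int] = (20, 120)
    seed: int = 0
    replicon_id: str = "synth1"

    def __post_init__(self) -> None:
        if not 0 < self.genome_gc < 1:
            raise ValueError("genome_gc must lie in (0, 1)")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must lie in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for lo, hi in (self.gene_len_range, self.intergenic_len_range,
                       self.plant_offset_range):
            if not 0 <= lo <= hi:
                raise ValueError("ranges must satisfy 0 <= lo <= hi")

    def validate_against(self, model: BipartiteMotifModel) -> None:
        need = 2 * (self.plant_offset_range[1]
                    + model.spec.placement_len(model.spec.spacer_max))
        if self.planted_fraction > 0 and self.intergenic_len_range[0] < need:
            raise ValueError(
                f"intergenic_len_range too small to hold planted sites: need >= {need} nt"
            )


@dataclass(frozen=True)
class TruthRecord:
    gene_id: str
    planted: bool
    instance_sequence: str | None = None  # coding-strand orientation
    replicon_id: str | None = None
    genomic_start: int | None = None  # 1-based inclusive, plus strand
    genomic_end: int | None = None
    strand: str | None = None
    spacer_len: int | None = None
    offset_to_gene: int | None = None


def generate_background(length: int, gc: float, seed: int | np.random.Generator) -> str:
    """i.i.d. background DNA with p(G)=p(C)=gc/2, p(A)=p(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 < gc < 1:
        raise ValueError("gc must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=length, p=probs))


def _sample_column(col: Mapping[str, float], rng: np.random.Generator) -> str:
    probs = np.array([col[b] for b in BASES], dtype=float)
    return rng.choice(list(BASES), p=probs / probs.sum())


def sample_site(model: BipartiteMotifModel,
                seed: int | np.random.Generator) -> tuple[str, int]:
    """Draw one full promoter instance (extension..downstream element).

    Bases are drawn per column from the PWMs, the spacer length from the
    model's spacer distribution, and spacer / downstream-offset fill from
    the model background.  Returns (sequence, spacer_len).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = model.spec
    spacers = sorted(model.spacer_logprob)
    sp_probs = np.array([2.0 ** model.spacer_logprob[k] for k in spacers])
    spacer = int(rng.choice(spacers, p=sp_probs / sp_probs.sum()))
    qprobs = np.array([model.background[b] for b in BASES])
    qprobs = qprobs / qprobs.sum()

    def fill(n: int) -> str:
        return "".join(rng.choice(list(BASES), size=n, p=qprobs)) if n else ""

    parts = ["".join(_sample_column(c, rng) for c in model.pwm_minus35),
             fill(spacer),
             "".join(_sample_column(c, rng) for c in model.pwm_minus10),
             fill(spec.downstream_offset),
             "".join(_sample_column(c, rng) for c in model.pwm_downstream)]
    return "".join(parts), spacer


def generate_genome(config: SyntheticConfig, model: BipartiteMotifModel,
                    ) -> tuple[GenomeRecord, list[GeneAnnotation], list[TruthRecord]]:
    """Build one linear replicon with annotated genes and planted promoters.

    Layout is gap, gene, gap, gene, ..., gap.  Roughly half the genes land
    on each strand; ``round(n_genes * planted_fraction)`` genes, chosen at
    random, receive one sampled instance ending ``offset_to_gene`` nt before
    their start codon on the coding strand.  Planted instances are written
    verbatim into the chromosome at the recorded span.
    """
    config.validate_against(model)
    rng = np.random.default_rng(config.seed)

    gene_lens = rng.integers(config.gene_len_range[0], config.gene_len_range[1] + 1,
                             size=config.n_genes)
    gap_lens = rng.integers(config.intergenic_len_range[0],
                            config.intergenic_len_range[1] + 1,
                            size=config.n_genes + 1)
    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    n_planted = int(round(config.n_genes * config.planted_fraction))
    planted_idx = set(rng.choice(config.n_genes, size=n_planted, replace=False).tolist())

    total_len = int(gene_lens.sum() + gap_lens.sum())
    chrom = list(generate_background(total_len, config.genome_gc, rng))

    genes: list[GeneAnnotation] = []
    pos = 1  # 1-based cursor
    spans: list[tuple[int, int]] = []  # gene spans in order
    for i in range(config.n_genes):
        pos += int(gap_lens[i])
        start, end = pos, pos + int(gene_lens[i]) - 1
        genes.append(GeneAnnotation(replicon_id=config.replicon_id, start=start,
                                    end=end, gene_id=f"g{i + 1:03d}",
                                    strand=str(strands[i])))
        spans.append((start, end))
        pos = end + 1

    truth: list[TruthRecord] = []
    for i, gene in enumerate(genes):
        if i not in planted_idx:
            truth.append(TruthRecord(gene_id=gene.gene_id, planted=False))
            continue
        instance, spacer = sample_site(model, rng)
        offset = int(rng.integers(config.plant_offset_range[0],
                                  config.plant_offset_range[1] + 1))
        L = len(instance)
        if gene.strand == "+":
            g_end = gene.start - offset - 1
            g_start = g_end - L + 1
            chrom[g_start - 1:g_end] = list(instance)
        else:
            g_start = gene.end + offset + 1
            g_end = g_start + L - 1
            chrom[g_start - 1:g_end] = list(reverse_complement(instance))
        truth.append(TruthRecord(
            gene_id=gene.gene_id, planted=True, instance_sequence=instance,
            replicon_id=config.replicon_id, genomic_start=g_start, genomic_end=g_end,
            strand=gene.strand, spacer_len=spacer, offset_to_gene=offset))

    genome = GenomeRecord(replicon_id=config.replicon_id, sequence="".join(chrom),
                          circular=False)
    return genome, genes, truth


def ortholog_genome(genome: GenomeRecord, truth: Sequence[TruthRecord],
                    mutation_rate: float, seed: int,
                    replicon_suffix: str = "_ortho",
                    ) -> tuple[GenomeRecord, list[TruthRecord]]:
    """Emit an ortholog copy of a synthetic genome.

    The chromosome is copied and each planted promoter span is re-written
    with per-base substitutions at ``mutation_rate`` (0 keeps the promoters
    identical, exercising the 'supported' path; high rates break consensus
    columns and exercise 'unsupported').
    """
    if not 0 <= mutation_rate <= 1:
        raise ValueError("mutation_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    chrom = list(genome.sequence)
    truth_b: list[TruthRecord] = []
    for rec in truth:
        if not rec.planted:
            truth_b.append(rec)
            continue
        plus_seq = chrom[rec.genomic_start - 1:rec.genomic_end]
        mutated = []
        for b in plus_seq:
            if rng.random() < mutation_rate:
                mutated.append(str(rng.choice([x for x in BASES if x != b])))
            else:
                mutated.append(b)
        chrom[rec.genomic_start - 1:rec.genomic_end] = mutated
        coding = "".join(mutated)
        if rec.strand == "-":
            coding = reverse_complement(coding)
        truth_b.append(TruthRecord(
            gene_id=rec.gene_id, planted=True, instance_sequence=coding,
            replicon_id=rec.replicon_id + replicon_suffix if rec.replicon_id else None,
            genomic_start=rec.genomic_start, genomic_end=rec.genomic_end,
            strand=rec.strand, spacer_len=rec.spacer_len,
            offset_to_gene=rec.offset_to_gene))
    ortho = GenomeRecord(replicon_id=genome.replicon_id + replicon_suffix,
                         sequence="".join(chrom), circular=genome.circular)
    return ortho, truth_b


TRUTH_COLUMNS = ("gene_id", "planted", "instance_sequence", "replicon_id",
                 "genomic_start", "genomic_end", "strand", "spacer_len",
                 "offset_to_gene")


def write_truth_tsv(truth: Sequence[TruthRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TRUTH_COLUMNS)
        for r in truth:
            w.writerow(["" if getattr(r, c) is None else getattr(r, c)
                        for c in TRUTH_COLUMNS])


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    out = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(TruthRecord(
                gene_id=row["gene_id"], planted=row["planted"] == "True",
                instance_sequence=row["instance_sequence"] or None,
                replicon_id=row["replicon_id"] or None,
                genomic_start=int(row["genomic_start"]) if row["genomic_start"] else None,
                genomic_end=int(row["genomic_end"]) if row["genomic_end"] else None,
                strand=row["strand"] or None,
                spacer_len=int(row["spacer_len"]) if row["spacer_len"] else None,
                offset_to_gene=int(row["offset_to_gene"]) if row["offset_to_gene"] else None))
    return out


def evaluate_recovery(hits: Sequence[CandidateHit], truth: Sequence[TruthRecord],
                      model: BipartiteMotifModel | None = None,
                      consensus_threshold: float = 0.85) -> dict:
    """Recall/precision of a scan against the truth table.

    A hit is a true positive when its gene carries a planted instance and
    the hit's genomic span overlaps the truth span.  With ``model`` given,
    ``consensus_recovered`` additionally checks that the degenerate
    consensus derived from the recovered -35/-10/downstream elements equals
    the consensus implied by the generating model's PWMs at the same
    threshold.
    """
    truth_by_gene = {t.gene_id: t for t in truth}
    hit_genes = {h.gene_id for h in hits}
    if hit_genes and not hit_genes & set(truth_by_gene):
        raise ValueError("hits and truth share no gene ids")

    planted = [t for t in truth if t.planted]
    tp_hits: list[CandidateHit] = []
    fp = 0
    recovered_genes = set()
    for h in hits:
        t = truth_by_gene.get(h.gene_id)
        if (t is not None and t.planted
                and not (h.genomic_end < t.genomic_start
                         or h.genomic_start > t.genomic_end)):
            tp_hits.append(h)
            recovered_genes.add(h.gene_id)
        else:
            fp += 1
    recall = len(recovered_genes) / len(planted) if planted else float("nan")
    precision = len(tp_hits) / len(hits) if hits else float("nan")

    result = {"recall": recall, "precision": precision,
              "n_planted": len(planted), "n_hits": len(hits),
              "false_positives": fp, "consensus_recovered": None}
    if model is not None and tp_hits:
        # consensus over recovered elements, region by region
        def hit_region_seq(h: CandidateHit, region: str) -> str:
            a = h.annotation
            if region == "minus35":
                start = a.minus35_pos[0] - model.spec.minus35_extension_len
                return a.sequence[start - 1:a.minus35_pos[1]]
            if region == "minus10":
                return a.minus10_seq
            return a.downstream_seq

        ok = True
        for region, pwm in (("minus35", model.pwm_minus35),
                            ("minus10", model.pwm_minus10),
                            ("downstream", model.pwm_downstream)):
            seqs = [hit_region_seq(h, region) for h in tp_hits]
            freqs = []
            for col in range(len(pwm)):
                counts = {b: 0 for b in BASES}
                for s in seqs:
                    if s[col] in counts:
                        counts[s[col]] += 1
                n = sum(counts.values()) or 1
                freqs.append({b: counts[b] / n for b in BASES})
            observed = consensus_from_pwm(freqs, consensus_threshold)
            expected = consensus_from_pwm(pwm, consensus_threshold)
            if observed != expected:
                ok = False
        result["consensus_recovered"] = ok
    return result
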