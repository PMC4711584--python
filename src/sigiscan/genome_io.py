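"""Genome and annotation I/O plus upstream-region extraction.

Genomes are read with Bio.SeqIO (FASTA or GenBank flat file); annotations
come from GFF3 or a simple gene TSV.  All external coordinates are 1-based
inclusive, GFF3-style.  Upstream regions are returned in coding-strand
orientation, ending immediately before the gene start, optionally truncated
at neighbouring features, and wrapping around circular replicons.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for malformed annotation files."""


@dataclass(frozen=True)
class GenomeRecord:
    replicon_id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"replicon {self.replicon_id!r}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"replicon {self.replicon_id!r}: non-ACGTN characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class GeneAnnotation:
    """A gene on a replicon, 1-based inclusive coordinates."""

    replicon_id: str
    start: int
    end: int
    gene_id: str
    strand: str
    name: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise AnnotationError(
                f"gene {self.gene_id!r}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id!r}: unknown strand symbol {self.strand!r}"
            )


@dataclass(frozen=True)
class UpstreamRegion:
    """Coding-strand-oriented sequence ending just before the start codon.

    ``genomic_start``/``genomic_end`` give the replicon span (1-based
    inclusive, plus-strand coordinates); on circular replicons the span may
    wrap, in which case genomic_start > genomic_end.
    """

    gene_id: str
    replicon_id: str
    sequence: str
    strand: str
    genomic_start: int
    genomic_end: int
    truncated: bool

    def __len__(self) -> int:
        return len(self.sequence)

    def to_genomic(self, pos: int) -> int:
        """Map a 1-based position within ``sequence`` to replicon coordinates."""
        if not 1 <= pos <= len(self.sequence):
            raise ValueError(f"position {pos} outside region of length {len(self)}")
        if self.strand == "+":
            g = self.genomic_start + pos - 1
        else:
            g = self.genomic_end - pos + 1
        return g


def _normalize(seq: str) -> str:
    return str(seq).upper().replace("U", "T")


def read_genome(path: str | Path, fmt: str | None = None) -> list[GenomeRecord]:
    """Read a FASTA or GenBank genome into one record per replicon.

    ``fmt`` defaults from the file suffix (.gb/.gbk/.gbff -> genbank, else
    fasta).  Sequences are uppercased and U is mapped to T.  GenBank records
    are flagged circular when the LOCUS topology says so; FASTA defaults to
    linear.
    """
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".gbff") else "fasta"
    if fmt not in ("fasta", "genbank"):
        raise ValueError(f"unsupported genome format {fmt!r}")
    try:
        records = list(SeqIO.parse(str(path), fmt))
    except Exception as exc:  # Bio.SeqIO error types vary by format
        raise ValueError(f"{path}: failed to parse as {fmt}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no sequence records found")
    out = []
    for rec in records:
        circular = False
        if fmt == "genbank":
            circular = rec.annotations.get("topology", "linear") == "circular"
        out.append(GenomeRecord(replicon_id=rec.id, sequence=_normalize(rec.seq),
                                circular=circular))
    return out


def write_fasta(records: Iterable[GenomeRecord], path: str | Path,
                width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(f">{rec.replicon_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


_TSV_COLUMNS = ("gene_id", "replicon_id", "start", "end", "strand")


def read_annotation(path: str | Path, dialect: str | None = None,
                    feature_types: Sequence[str] = ("gene",)) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 or a gene TSV.

    ``dialect`` is inferred from the suffix when omitted (.gff/.gff3 ->
    gff3, else gene_tsv).  GFF3 rows are filtered to ``feature_types``;
    coordinates are kept exactly as printed (1-based inclusive).  Records
    are returned sorted by (replicon_id, start); duplicate gene ids, start >
    end and unknown strand symbols are errors.
    """
    path = Path(path)
    if dialect is None:
        dialect = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "gene_tsv"
    if dialect == "gff3":
        genes = _read_gff3(path, feature_types)
    elif dialect == "gene_tsv":
        genes = _read_gene_tsv(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    seen: dict[str, int] = {}
    for lineno, g in genes:
        if g.gene_id in seen:
            raise AnnotationError(
                f"{path}: duplicate gene_id {g.gene_id!r} (lines {seen[g.gene_id]} and {lineno})"
            )
        seen[g.gene_id] = lineno
    return sorted((g for _, g in genes), key=lambda g: (g.replicon_id, g.start))


def _read_gff3(path: Path, feature_types: Sequence[str]) -> list[tuple[int, GeneAnnotation]]:
    genes = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in feature_types:
                continue
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            gene_id = attr_map.get("ID") or attr_map.get("locus_tag")
            if not gene_id:
                raise AnnotationError(f"{path}:{lineno}: feature lacks an ID attribute")
            try:
                gene = GeneAnnotation(replicon_id=seqid, start=int(start), end=int(end),
                                      gene_id=gene_id, strand=strand,
                                      name=attr_map.get("Name"))
            except (AnnotationError, ValueError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from None
            genes.append((lineno, gene))
    return genes


def _read_gene_tsv(path: Path) -> list[tuple[int, GeneAnnotation]]:
    genes = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise AnnotationError(f"{path}: empty file")
        missing = [c for c in _TSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise AnnotationError(f"{path}: missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            strand = row["strand"].strip()
            # tolerate the typographic minus sign used in some tables
            strand = {"−": "-"}.get(strand, strand)
            try:
                gene = GeneAnnotation(
                    replicon_id=row["replicon_id"].strip(), start=int(row["start"]),
                    end=int(row["end"]), gene_id=row["gene_id"].strip(),
                    strand=strand, name=(row.get("name") or "").strip() or None)
            except (AnnotationError, ValueError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from None
            genes.append((lineno, gene))
    return genes


def write_gff3(genes: Iterable[GeneAnnotation], path: str | Path,
               source: str = "sigiscan") -> None:
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.replicon_id, g.start)):
            attrs = f"ID={g.gene_id}"
            if g.name:
                attrs += f";Name={g.name}"
            fh.write("\t".join([g.replicon_id, source, "gene", str(g.start),
                                str(g.end), ".", g.strand, ".", attrs]) + "\n")


def extract_upstream(genome: GenomeRecord, gene: GeneAnnotation, window: int = 1000,
                     cap_at_features: Iterable[GeneAnnotation] | None = None,
                     ) -> UpstreamRegion:
    """Extract the coding-strand upstream region of a gene.

    For a plus-strand gene the region is genome[start-window .. start-1];
    for a minus-strand gene it is the reverse complement of
    genome[end+1 .. end+window].  The window is shortened (``truncated``
    set) at the nearest boundary of any feature in ``cap_at_features`` or at
    the replicon edge of a linear replicon; circular replicons wrap instead.
    A zero-length result (gene abutting the cap) is an error.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if gene.replicon_id != genome.replicon_id:
        raise ValueError(
            f"gene {gene.gene_id!r} lies on {gene.replicon_id!r}, not {genome.replicon_id!r}"
        )
    n = len(genome)
    if gene.end > n:
        raise ValueError(f"gene {gene.gene_id!r} extends past the replicon end")

    truncated = False
    if gene.strand == "+":
        lo = gene.start - window  # may be < 1
        hi = gene.start - 1
        if cap_at_features:
            for f in cap_at_features:
                if f.gene_id == gene.gene_id or f.replicon_id != gene.replicon_id:
                    continue
                if f.end < gene.start and f.end + 1 > lo:
                    lo, truncated = f.end + 1, True
        if lo < 1 and not genome.circular:
            lo, truncated = 1, True
        if hi < lo:
            raise ValueError(f"gene {gene.gene_id!r}: zero-length upstream region")
        seq = _slice_wrapping(genome, lo, hi)
        g_start, g_end = _wrap_pos(lo, n), _wrap_pos(hi, n)
    else:
        lo = gene.end + 1
        hi = gene.end + window  # may exceed n
        if cap_at_features:
            for f in cap_at_features:
                if f.gene_id == gene.gene_id or f.replicon_id != gene.replicon_id:
                    continue
                if f.start > gene.end and f.start - 1 < hi:
                    hi, truncated = f.start - 1, True
        if hi > n and not genome.circular:
            hi, truncated = n, True
        if hi < lo:
            raise ValueError(f"gene {gene.gene_id!r}: zero-length upstream region")
        seq = reverse_complement(_slice_wrapping(genome, lo, hi))
        g_start, g_end = _wrap_pos(lo, n), _wrap_pos(hi, n)

    return UpstreamRegion(gene_id=gene.gene_id, replicon_id=genome.replicon_id,
                          sequence=seq, strand=gene.strand,
                          genomic_start=g_start, genomic_end=g_end, truncated=truncated)


def _wrap_pos(pos: int, n: int) -> int:
    return (pos - 1) % n + 1


def _slice_wrapping(genome: GenomeRecord, lo: int, hi: int) -> str:
    """1-based inclusive slice; out-of-range positions wrap (circular only)."""
    n = len(genome)
    if 1 <= lo and hi <= n:
        return genome.sequence[lo - 1:hi]
    if not genome.circular:
        raise ValueError("slice outside a linear replicon")
    if hi - lo + 1 > n:
        raise ValueError("window exceeds replicon length on a circular replicon")
    return "".join(genome.sequence[(p - 1) % n] for p in range(lo, hi + 1))
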