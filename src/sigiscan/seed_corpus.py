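"""Packaged promoter seed sets for the clostridial sigma-I promoter family.

The package ships, as plain TSV fixtures, the published alignments of
putative sigma-I promoters of *Clostridium thermocellum* DSM 1313 and
*C. straminisolvens* JCM 21531 (seven *sigI* operon promoters per organism)
and the 33 predicted sigma-I-dependent promoters of *C. thermocellum*
cellulosomal genes, together with the reporter-validated sigma-I6 and
sigma-I3 subsets.  Aligned sequences keep their original gap characters so
the printed alignment layout is reproducible before any re-anchoring.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

VALID_SEQ_CHARS = set("ACGT-")

# Reporter-validated gene sets.  The negative-control rows of the published
# activity tables (sigI3 for the sigma-I6 assay, sigI6 for the sigma-I3
# assay) are excluded by construction.
SIGI6_VALIDATED_GENES = (
    "xyn10Z", "xyn11B", "cipA", "cel9V", "sigI6",
    "xyn10Y", "cseP", "sigI1", "rsgI5", "xyn10D",
)
SIGI3_VALIDATED_GENES = ("pl11", "ce12", "cipA", "sigI3")


class SeedTableError(ValueError):
    """Raised for malformed seed tables or unknown set names."""


@dataclass(frozen=True)
class PromoterSeed:
    """One aligned promoter record.

    ``aligned_sequence`` may contain ``-`` gap characters (only within the
    spacer of the printed alignments); ``sequence`` strips them.
    ``validated_by`` is a frozenset of sigma-factor labels because the cipA
    promoter is recognized by both sigma-I6 and sigma-I3.
    """

    gene_name: str
    locus_tags: tuple[str, ...]
    organism: str
    aligned_sequence: str
    utr_5p: int | None = None
    validated_by: frozenset[str] = field(default_factory=frozenset)
    tss_offset: int | None = None
    atcc27405_status: str = "intact"
    description: str = ""

    def __post_init__(self) -> None:
        bad = set(self.aligned_sequence) - VALID_SEQ_CHARS
        if bad:
            raise SeedTableError(
                f"seed {self.gene_name!r}: invalid sequence characters {sorted(bad)}"
            )
        if not self.sequence:
            raise SeedTableError(f"seed {self.gene_name!r}: empty sequence")

    @property
    def sequence(self) -> str:
        """Gapless promoter sequence, 5'->3' on the coding strand."""
        return self.aligned_sequence.replace("-", "")

    @property
    def key(self) -> str:
        return f"{self.organism}:{self.gene_name}"


@dataclass(frozen=True)
class PromoterSeedSet:
    name: str
    seeds: tuple[PromoterSeed, ...]
    consensus_note: str | None = None

    def __post_init__(self) -> None:
        keys = [s.key for s in self.seeds]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise SeedTableError(f"duplicate seed names in set {self.name!r}: {dupes}")

    def __len__(self) -> int:
        return len(self.seeds)

    def __iter__(self):
        return iter(self.seeds)

    def get(self, gene_name: str, organism: str = "Ct") -> PromoterSeed:
        for s in self.seeds:
            if s.gene_name == gene_name and s.organism == organism:
                return s
        raise KeyError(f"{organism}:{gene_name} not in set {self.name!r}")

    def subset(self, name: str, seeds: Iterable[PromoterSeed]) -> "PromoterSeedSet":
        return PromoterSeedSet(name=name, seeds=tuple(seeds),
                               consensus_note=self.consensus_note)


_CORE_COLUMNS = ("gene_name", "locus_tags", "organism", "aligned_sequence",
                 "utr_5p", "validated_by")


def _row_to_seed(row: dict, lineno: int) -> PromoterSeed:
    try:
        utr = row.get("utr_5p", "")
        tss = row.get("tss_offset", "")
        return PromoterSeed(
            gene_name=row["gene_name"].strip(),
            locus_tags=tuple(t.strip() for t in row["locus_tags"].split(",") if t.strip()),
            organism=row["organism"].strip(),
            aligned_sequence=row["aligned_sequence"].strip().upper(),
            utr_5p=int(utr) if utr not in ("", None) else None,
            validated_by=frozenset(
                v for v in (row.get("validated_by") or "none").split("+") if v != "none"
            ),
            tss_offset=int(tss) if tss not in ("", None) else None,
            atcc27405_status=(row.get("atcc27405_status") or "intact").strip(),
            description=(row.get("description") or "").strip(),
        )
    except SeedTableError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with row context
        raise SeedTableError(f"row {lineno}: {exc}") from exc


def parse_seed_table(path: str | Path, name: str | None = None,
                     consensus_note: str | None = None) -> PromoterSeedSet:
    """Parse a promoter seed TSV into a :class:`PromoterSeedSet`.

    The file must carry at least the columns ``gene_name``, ``locus_tags``,
    ``organism``, ``aligned_sequence``, ``utr_5p`` and ``validated_by``;
    extra columns are preserved where the dataclass has a field for them.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SeedTableError(f"{path}: empty file")
        missing = [c for c in _CORE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SeedTableError(f"{path}: missing columns {missing}")
        seeds = []
        for lineno, row in enumerate(reader, start=2):
            try:
                seeds.append(_row_to_seed(row, lineno))
            except SeedTableError as exc:
                raise SeedTableError(f"{path}: {exc}") from None
    return PromoterSeedSet(name=name or path.stem, seeds=tuple(seeds),
                           consensus_note=consensus_note)


def write_seed_table(seed_set: PromoterSeedSet, path: str | Path) -> None:
    """Serialize a seed set back to TSV (round-trips with parse_seed_table)."""
    cols = list(_CORE_COLUMNS) + ["tss_offset", "atcc27405_status", "description"]
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for s in seed_set:
            writer.writerow([
                s.gene_name, ",".join(s.locus_tags), s.organism, s.aligned_sequence,
                "" if s.utr_5p is None else s.utr_5p,
                "+".join(sorted(s.validated_by)) or "none",
                "" if s.tss_offset is None else s.tss_offset,
                s.atcc27405_status, s.description,
            ])


def _data_path(fname: str) -> Path:
    return Path(str(resources.files("sigiscan.data").joinpath(fname)))


def load_manifest() -> dict[str, dict]:
    with _data_path("manifest.tsv").open(newline="") as fh:
        return {row["set_name"]: row for row in csv.DictReader(fh, delimiter="\t")}


def available_sets() -> tuple[str, ...]:
    return tuple(load_manifest())


def load_seed_set(name: str) -> PromoterSeedSet:
    """Load one of the packaged promoter seed sets.

    Available names: ``ct_sigI_table1`` / ``cs_sigI_table1`` (the organism
    halves of the 14-row sigma-I operon promoter alignment), ``sigI_table1``
    (all 14 rows), ``ct_candidates_table2`` (the 33 predicted cellulosomal
    promoters), and the reporter-validated subsets ``sigI6_validated`` and
    ``sigI3_validated``.
    """
    manifest = load_manifest()
    if name not in manifest:
        raise SeedTableError(
            f"unknown seed set {name!r}; available sets: {', '.join(sorted(manifest))}"
        )
    note = manifest[name]["consensus_note"]
    t1 = parse_seed_table(_data_path("table1_sigI_promoters.tsv"))
    t2 = parse_seed_table(_data_path("table2_candidates.tsv"))

    if name == "sigI_table1":
        seeds = t1.seeds
    elif name == "ct_sigI_table1":
        seeds = tuple(s for s in t1 if s.organism == "Ct")
    elif name == "cs_sigI_table1":
        seeds = tuple(s for s in t1 if s.organism == "Cs")
    elif name == "ct_candidates_table2":
        seeds = t2.seeds
    elif name in ("sigI6_validated", "sigI3_validated"):
        genes = SIGI6_VALIDATED_GENES if name == "sigI6_validated" else SIGI3_VALIDATED_GENES
        pool = {s.gene_name: s for s in list(t2) + [s for s in t1 if s.organism == "Ct"]}
        seeds = tuple(pool[g] for g in genes)
    else:  # pragma: no cover - manifest and branches kept in sync
        raise SeedTableError(f"set {name!r} listed in manifest but not implemented")

    expected = int(manifest[name]["row_count"])
    if len(seeds) != expected:
        raise SeedTableError(
            f"fixture integrity: set {name!r} has {len(seeds)} seeds, manifest says {expected}"
        )
    return PromoterSeedSet(name=name, seeds=seeds, consensus_note=note)


def distinct_ct_candidates() -> PromoterSeedSet:
    """Union of distinct C. thermocellum candidate promoters screened in the
    reporter assays: the 7 sigI operon promoters plus the 33 cellulosomal
    candidates (40 records in total)."""
    t1 = load_seed_set("ct_sigI_table1")
    t2 = load_seed_set("ct_candidates_table2")
    return PromoterSeedSet(name="ct_all_candidates", seeds=t1.seeds + t2.seeds)
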