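"""Domain types and flat-file I/O for CNV, gene and orthology tables.

All coordinates are 0-based half-open internally. dbVar-style input
(1-based inclusive) is converted at the boundary; BED output is native.
Only autosomes are modelled: the analysed call sets are human autosomal
germline CNVs, so sex chromosomes are rejected at ingest.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

MIN_CNV_LENGTH = 50
MAX_CHROM_FRACTION = 0.1

AUTOSOMES = tuple(str(i) for i in range(1, 23))

#: GRCh37 primary-assembly autosome lengths in bp.
GRCH37_AUTOSOME_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566,
}

#: The 13 mammalian genomes surveyed for copy-number conservation.
MAMMAL_SPECIES: tuple[str, ...] = (
    "bos_taurus", "callithrix_jacchus", "canis_familiaris", "equus_caballus",
    "felis_catus", "gorilla_gorilla", "macaca_mulatta", "mus_musculus",
    "oryctolagus_cuniculus", "ovis_aries", "pan_troglodytes",
    "rattus_norvegicus", "sus_scrofa",
)


class CnvType(str, enum.Enum):
    GAIN = "gain"
    LOSS = "loss"


class Interpretation(str, enum.Enum):
    BENIGN = "benign"
    PATHOGENIC = "pathogenic"


class OrthologyStatus(str, enum.Enum):
    ONE2ONE = "one2one"
    ONE2MANY = "one2many"
    NONE = "none"


@dataclass(frozen=True)
class GenomeBuild:
    """A named set of chromosome lengths, the denominator for genome fractions."""

    name: str
    chrom_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {chrom}")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


#: Bundled GRCh37 autosomal build.
GRCH37 = GenomeBuild("GRCh37", GRCH37_AUTOSOME_LENGTHS)


@dataclass(frozen=True)
class CnvRecord:
    """One CNV call: an autosomal interval with type and clinical interpretation.

    Coordinates are 0-based half-open. The minimum call length is 50 bp;
    the ≤10%-of-chromosome upper bound is enforced at ingest, where the
    chromosome length is known.
    """

    id: str
    chromosome: str
    start: int
    end: int
    cnv_type: CnvType
    interpretation: Interpretation
    study: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "cnv_type", CnvType(self.cnv_type))
        object.__setattr__(self, "interpretation", Interpretation(self.interpretation))
        if self.chromosome not in AUTOSOMES:
            raise ValueError(
                f"CNV {self.id}: chromosome {self.chromosome!r} is not autosomal"
            )
        if not self.start < self.end:
            raise ValueError(f"CNV {self.id}: start {self.start} >= end {self.end}")
        if self.length < MIN_CNV_LENGTH:
            raise ValueError(
                f"CNV {self.id}: length {self.length} < {MIN_CNV_LENGTH} bp minimum"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene with the positional and functional attributes
    used by the dosage-class enrichment battery.

    hi_score is the probability of loss-of-function intolerance (a proxy for
    haploinsufficiency); max_expression is the maximum median RPKM over
    tissues. Either may be None when the source table lacks the column.
    ``ancestral`` marks genes inferred present in the mammalian common
    ancestor, the universe for conservation scoring.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    flags: Mapping[str, bool] = field(default_factory=dict)
    hi_score: float | None = None
    max_expression: float | None = None
    ancestral: bool = True

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.hi_score is not None and not 0.0 <= self.hi_score <= 1.0:
            raise ValueError(f"gene {self.gene_id}: hi_score outside [0,1]")
        if self.max_expression is not None and self.max_expression < 0:
            raise ValueError(f"gene {self.gene_id}: negative max_expression")

    def flag(self, name: str) -> bool:
        return bool(self.flags.get(name, False))

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class OrthologyProfile:
    """Per-species orthology status of one human gene (or one group of
    recent human in-paralogues treated as a single ancestral unit)."""

    unit_id: str
    statuses: Mapping[str, OrthologyStatus]
    group_members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "statuses",
            {sp: OrthologyStatus(s) for sp, s in self.statuses.items()},
        )
        if len(self.statuses) != len(MAMMAL_SPECIES) and len(self.statuses) != 13:
            raise ValueError(
                f"profile {self.unit_id}: expected 13 species, got {len(self.statuses)}"
            )
        if not self.group_members:
            object.__setattr__(self, "group_members", (self.unit_id,))


# ---------------------------------------------------------------------------
# Readers / writers


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_cnv_table(
    path: str | Path,
    dialect: str = "dbvar_tsv",
    build: GenomeBuild = GRCH37,
) -> list[CnvRecord]:
    """Read a CNV call table, applying the ingestion filters.

    Dialects: ``dbvar_tsv`` (1-based inclusive coordinates, converted here)
    and ``bed_like`` (already 0-based half-open). Rows shorter than 50 bp or
    longer than a tenth of their chromosome are dropped, as are non-autosomal
    rows. Returns records sorted by (chromosome, start).
    """
    if dialect not in ("dbvar_tsv", "bed_like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(
        df, ["id", "chrom", "start", "end", "type", "interpretation"], str(path)
    )
    records: list[CnvRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        chrom = str(row.chrom).removeprefix("chr")
        if chrom not in AUTOSOMES:
            continue  # sex chromosomes / contigs dropped silently
        if chrom not in build.chrom_lengths:
            raise ValueError(f"{path}:{i}: chromosome {chrom!r} not in build {build.name}")
        try:
            start = int(row.start)
            end = int(row.end)
            cnv_type = CnvType(str(row.type).lower())
            interpretation = Interpretation(str(row.interpretation).lower())
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{i}: unparsable row ({exc})") from exc
        if dialect == "dbvar_tsv":
            start -= 1  # 1-based inclusive -> 0-based half-open
        if end <= start:
            raise ValueError(f"{path}:{i}: empty or inverted interval")
        length = end - start
        if length < MIN_CNV_LENGTH:
            continue
        if length > MAX_CHROM_FRACTION * build.chrom_lengths[chrom]:
            continue
        study = str(getattr(row, "study", "")) if hasattr(row, "study") else ""
        records.append(
            CnvRecord(
                id=str(row.id), chromosome=chrom, start=start, end=end,
                cnv_type=cnv_type, interpretation=interpretation, study=study,
            )
        )
    records.sort(key=lambda r: (int(r.chromosome), r.start, r.end, r.id))
    return records


_GENE_REQUIRED = ["gene_id", "chrom", "start", "end", "strand"]
_GENE_FLAGS = [
    "developmental", "complex_member", "ohnologue", "omim_disease",
    "dosage_sensitive",
]


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a flat protein-coding gene table (0-based half-open coordinates).

    Optional attribute columns (developmental, complex_member, ohnologue,
    omim_disease, ancestral, hi_score, max_expression) default to
    false/absent when missing. Duplicate gene ids are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, _GENE_REQUIRED, str(path))
    dupes = df["gene_id"][df["gene_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"{path}: duplicate gene_id {dupes.iloc[0]!r}")
    genes: list[GeneRecord] = []
    for i, row in df.iterrows():
        try:
            start, end = int(row["start"]), int(row["end"])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed coordinates for {row['gene_id']}") from exc
        flags = {
            name: str(row[name]).lower() in ("1", "true", "yes")
            for name in _GENE_FLAGS
            if name in df.columns and pd.notna(row[name])
        }
        hi = float(row["hi_score"]) if "hi_score" in df.columns and pd.notna(row["hi_score"]) else None
        expr = (
            float(row["max_expression"])
            if "max_expression" in df.columns and pd.notna(row["max_expression"])
            else None
        )
        ancestral = (
            str(row["ancestral"]).lower() in ("1", "true", "yes")
            if "ancestral" in df.columns and pd.notna(row["ancestral"])
            else True
        )
        genes.append(
            GeneRecord(
                gene_id=str(row["gene_id"]),
                chromosome=str(row["chrom"]).removeprefix("chr"),
                start=start, end=end, strand=str(row["strand"]),
                flags=flags, hi_score=hi, max_expression=expr, ancestral=ancestral,
            )
        )
    genes.sort(key=lambda g: (g.chromosome, g.start, g.end, g.gene_id))
    return genes


def read_orthology_table(
    path: str | Path,
    species_list: Sequence[str] = MAMMAL_SPECIES,
) -> list[OrthologyProfile]:
    """Read long-format orthology rows (human_gene, species, status).

    A (gene, species) pair absent from the file is recorded as ``none``
    (no orthologue detected). ``many2many`` or any other token is rejected:
    residual many-to-many relations must be resolved upstream by recent
    paralogue grouping.
    """
    if len(species_list) != 13:
        raise ValueError(f"species_list must name 13 genomes, got {len(species_list)}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, ["human_gene", "species", "status"], str(path))
    species_set = set(species_list)
    by_gene: dict[str, dict[str, OrthologyStatus]] = {}
    for _, row in df.iterrows():
        species = str(row["species"])
        if species not in species_set:
            raise ValueError(f"{path}: species {species!r} not in species list")
        try:
            status = OrthologyStatus(str(row["status"]))
        except ValueError as exc:
            raise ValueError(
                f"{path}: unknown status {row['status']!r} for {row['human_gene']} "
                "(many2many must be resolved by paralogue grouping upstream)"
            ) from exc
        by_gene.setdefault(str(row["human_gene"]), {})[species] = status
    profiles = []
    for gene_id in sorted(by_gene):
        statuses = {
            sp: by_gene[gene_id].get(sp, OrthologyStatus.NONE) for sp in species_list
        }
        profiles.append(OrthologyProfile(unit_id=gene_id, statuses=statuses))
    return profiles


def write_bed(
    intervals: Iterable[tuple],
    path: str | Path,
) -> None:
    """Write BED4/BED5 lines (0-based half-open), sorted by (chrom, start).

    Each tuple is (chromosome, start, end, name) or
    (chromosome, start, end, name, score).
    """
    rows = sorted(intervals, key=lambda t: (_chrom_key(t[0]), t[1], t[2]))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    """Read the BED4/BED5 files written by :func:`write_bed`."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            rest = parts[3:4] + [int(parts[4])] * (len(parts) > 4)
            out.append(tuple([chrom, start, end, *rest]))
    return out


def _chrom_key(chrom: str):
    return (0, int(chrom)) if str(chrom).isdigit() else (1, str(chrom))
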