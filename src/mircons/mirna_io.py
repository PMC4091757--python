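"""Readers and writers for every external format the pipeline touches.

Formats: miRBase-dialect FASTA (mature and hairpin), the disease
association TSV, the family mapping TSV, Newick trees, and the
28-column integrated resource TSV. All readers accept either a path or
an open text stream; TSV is the canonical tabular dialect (disease
phenotype names contain commas).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO, Union

import pandas as pd
from Bio import SeqIO

from .sequences import contains_n, normalize_sequence
from .trees import PhyloTree

log = logging.getLogger(__name__)

Source = Union[str, Path, TextIO]

#: miRBase species prefixes used throughout: human plus the five
#: domestic animals of the study.
DEFAULT_ANIMAL_SPECIES: list[tuple[str, str]] = [
    ("bta", "cow"),
    ("gga", "chicken"),
    ("ssc", "pig"),
    ("eca", "horse"),
    ("cfa", "dog"),
]

HUMAN_CODE = "hsa"


@dataclass(frozen=True)
class SpeciesTable:
    """Ordered animal species roster (code, common name); human excluded."""

    species: tuple[tuple[str, str], ...] = tuple(DEFAULT_ANIMAL_SPECIES)

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.species]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate species codes")
        if HUMAN_CODE in codes:
            raise ValueError("human (hsa) cannot be listed as an animal species")

    @property
    def codes(self) -> list[str]:
        return [c for c, _ in self.species]

    def name_of(self, code: str) -> str:
        return dict(self.species)[code]


@dataclass
class MatureRecord:
    """One mature miRNA: ~22-nt processed sequence with miRBase naming."""

    mirna_id: str
    accession: str
    species_code: str
    sequence: str
    arm: str  # 5p | 3p | unspecified

    @classmethod
    def from_parts(cls, mirna_id: str, accession: str, sequence: str) -> "MatureRecord":
        seq = normalize_sequence(sequence)
        species = mirna_id.split("-", 1)[0]
        if mirna_id.endswith("-5p"):
            arm = "5p"
        elif mirna_id.endswith("-3p"):
            arm = "3p"
        else:
            arm = "unspecified"
        if not 16 <= len(seq) <= 28:
            log.warning("mature miRNA %s has atypical length %d", mirna_id, len(seq))
        return cls(mirna_id, accession, species, seq, arm)


@dataclass
class PrecursorRecord:
    """One pre-miRNA hairpin sequence, optionally tagged with its family."""

    pre_id: str
    accession: str
    species_code: str
    sequence: str
    family_id: str = ""

    @classmethod
    def from_parts(cls, pre_id: str, accession: str, sequence: str,
                   family_id: str = "") -> "PrecursorRecord":
        seq = normalize_sequence(sequence)
        species = pre_id.split("-", 1)[0]
        return cls(pre_id, accession, species, seq, family_id)


@dataclass
class DiseaseAssociation:
    """One human miRNA <-> disease link backed by a Pubmed article.

    Standardized vocabulary fields (OMIM/OMIA, Disease Ontology, BRENDA
    Tissue Ontology) are carried as opaque strings; no live ontology
    resolution happens in this package.
    """

    mirna_id: str
    disease_name: str
    pmid: int
    experiment: str = ""
    tissue: str = ""
    standardized: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pmid <= 0:
            raise ValueError(f"pmid must be positive, got {self.pmid}")
        if not self.mirna_id.startswith(HUMAN_CODE + "-"):
            raise ValueError(f"disease association for non-human miRNA {self.mirna_id}")


def _as_handle(source: Source) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8")
    return source


def known_species_codes(table: SpeciesTable | None = None) -> set[str]:
    table = table or SpeciesTable()
    return {HUMAN_CODE, *table.codes}


def read_mirna_fasta(source: Source, kind: str = "mature",
                     species_table: SpeciesTable | None = None,
                     ) -> list[MatureRecord] | list[PrecursorRecord]:
    """Parse a miRBase-dialect FASTA.

    The header's first whitespace token is the miRNA ID and the second,
    if present, the accession; any further tokens (species name, free
    description) are ignored. Sequences are normalized to uppercase RNA.
    Records with an empty sequence or a non-IUPAC character are rejected
    with a logged warning and parsing continues; a header with no ID
    token is a hard error.
    """
    if kind not in ("mature", "precursor"):
        raise ValueError(f"kind must be 'mature' or 'precursor', got {kind!r}")
    known = known_species_codes(species_table)
    records: list = []
    handle = _as_handle(source)
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            tokens = rec.description.split()
            if not tokens:
                raise ValueError("malformed FASTA header: no ID token")
            mirna_id = tokens[0]
            accession = tokens[1] if len(tokens) > 1 else ""
            raw = str(rec.seq)
            if not raw:
                log.warning("empty sequence for %s; record skipped", mirna_id)
                continue
            try:
                if kind == "mature":
                    record = MatureRecord.from_parts(mirna_id, accession, raw)
                else:
                    record = PrecursorRecord.from_parts(mirna_id, accession, raw)
            except ValueError as exc:
                log.warning("rejected record %s: %s", mirna_id, exc)
                continue
            if contains_n(record.sequence):
                log.warning("sequence of %s contains N; excluded from exact "
                            "matching and distance columns", mirna_id)
            if record.species_code not in known:
                log.warning("unknown species prefix %r for %s",
                            record.species_code, mirna_id)
            records.append(record)
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    return records


def write_fasta(records: Iterable[MatureRecord | PrecursorRecord]) -> str:
    """Serialize records as single-line FASTA, ``>id accession`` headers."""
    lines = []
    for rec in records:
        rid = rec.mirna_id if isinstance(rec, MatureRecord) else rec.pre_id
        header = f">{rid} {rec.accession}".rstrip()
        lines.append(header)
        lines.append(rec.sequence)
    return "\n".join(lines) + ("\n" if lines else "")


_STANDARD_OPTIONAL = (
    "omim_omia_name", "omim_omia_id", "do_term", "bto_name", "bto_id",
)


def read_disease_table(source: Source) -> list[DiseaseAssociation]:
    """Parse the HMDD-style disease association TSV.

    Mandatory columns: ``mirna_id``, ``disease``, ``pmid``. Multiple
    diseases in one cell are split on the pipe character, each yielding
    its own association with the same Pubmed ID. Rows with a
    non-integer pmid are rejected individually.
    """
    handle = _as_handle(source)
    try:
        df = pd.read_csv(handle, sep="\t", dtype=str).fillna("")
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    for col in ("mirna_id", "disease", "pmid"):
        if col not in df.columns:
            raise ValueError(f"disease table missing mandatory column {col!r}")
    out: list[DiseaseAssociation] = []
    for _, row in df.iterrows():
        try:
            pmid = int(row["pmid"])
        except ValueError:
            log.warning("non-integer pmid %r for %s; row skipped",
                        row["pmid"], row["mirna_id"])
            continue
        standardized = {k: row[k] for k in _STANDARD_OPTIONAL
                        if k in df.columns and row[k]}
        for disease in str(row["disease"]).split("|"):
            disease = disease.strip()
            if not disease:
                continue
            try:
                out.append(DiseaseAssociation(
                    mirna_id=row["mirna_id"],
                    disease_name=disease,
                    pmid=pmid,
                    experiment=row.get("experiment", ""),
                    tissue=row.get("tissue", ""),
                    standardized=standardized,
                ))
            except ValueError as exc:
                log.warning("rejected association row: %s", exc)
    return out


def read_family_map(source: Source) -> dict[str, list[str]]:
    """Parse the ``family_id<TAB>pre_id`` mapping into family -> members."""
    handle = _as_handle(source)
    families: dict[str, list[str]] = {}
    try:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"family map line {lineno}: expected 2 columns")
            family_id, pre_id = parts
            families.setdefault(family_id, []).append(pre_id)
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    return families


def write_family_map(families: dict[str, list[str]]) -> str:
    lines = [f"{fam}\t{pre}" for fam in families for pre in families[fam]]
    return "\n".join(lines) + ("\n" if lines else "")


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree as Newick, branch lengths to six decimals."""
    for node in tree.root.walk():
        if node.length < 0:
            raise ValueError("negative branch length in tree")
    return tree.to_newick()


#: The 28 integrated-resource fields, grouped MicroRNA (1-8),
#: Location (9-11), Reference (12-15), Disease (16-24), Target (25-28).
RESOURCE_COLUMNS: list[str] = [
    "mature_mirna_id",          # 1
    "mature_mirna_acc",         # 2
    "mature_sequence",          # 3
    "premirna_id",              # 4
    "premirna_acc",             # 5
    "premirna_sequence",        # 6
    "family_id",                # 7
    "family_acc",               # 8
    "chromosome",               # 9
    "genomic_coordinates",      # 10 (start-end, 1-based inclusive)
    "strand",                   # 11
    "pubmed_id",                # 12
    "pmc_id",                   # 13
    "pubmed_title",             # 14
    "pubmed_date",              # 15
    "disease_phenotype",        # 16
    "relevance_in_animal",      # 17
    "omim_omia_name",           # 18
    "omim_omia_id",             # 19
    "disease_ontology",         # 20
    "tissue_cell_type",         # 21
    "bto_name",                 # 22
    "bto_id",                   # 23
    "association_method",       # 24
    "target_gene",              # 25
    "animal_ortholog",          # 26
    "reciprocal_identity",      # 27
    "orthology_confidence",     # 28
]


def write_resource_table(records: Iterable) -> str:
    """Serialize validated resource records as the 28-column TSV."""
    from .resource_integrate import ResourceRecord, validate_record

    lines = ["\t".join(RESOURCE_COLUMNS)]
    for rec in records:
        if not isinstance(rec, ResourceRecord):
            raise TypeError("write_resource_table expects ResourceRecord items")
        violations = validate_record(rec)
        if violations:
            raise ValueError(
                f"refusing to write invalid record {rec.mature_mirna_id}: "
                + "; ".join(violations)
            )
        lines.append("\t".join(str(getattr(rec, c)) for c in RESOURCE_COLUMNS))
    return "\n".join(lines) + "\n"


def read_resource_table(source: Source) -> pd.DataFrame:
    """Read the resource TSV back into a DataFrame (28 string columns)."""
    handle = _as_handle(source)
    try:
        df = pd.read_csv(handle, sep="\t", dtype=str).fillna("")
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    if list(df.columns) != RESOURCE_COLUMNS:
        raise ValueError("resource table does not have the 28 expected columns")
    return df
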