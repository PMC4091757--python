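"""Integration of all pipeline outputs into the 28-field resource records.

The record grain is one (animal mature miRNA, human homolog, disease
association) triple — the finest grain the integrated table supports.
Fields group as MicroRNA (1-8), Location (9-11), Reference (12-15),
Disease (16-24) and Target (25-28); ontology names and IDs are opaque
pass-through strings, and genomic coordinates (1-based inclusive) are
pass-through data, never computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .homolog_match import HdmacMap
from .mirna_io import (
    HUMAN_CODE,
    DiseaseAssociation,
    MatureRecord,
    PrecursorRecord,
    RESOURCE_COLUMNS,
)
from .ortholog_map import OrthologPair

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicLocation:
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def coordinates(self) -> str:
        return f"{self.start}-{self.end}"


@dataclass
class ResourceRecord:
    """One integrated animal disease-miRNA entry (the 28 table fields).

    ``human_homolog`` links the record back to the human disease miRNA
    it derives from; it is bookkeeping, not one of the serialized
    columns.
    """

    mature_mirna_id: str
    mature_mirna_acc: str = ""
    mature_sequence: str = ""
    premirna_id: str = ""
    premirna_acc: str = ""
    premirna_sequence: str = ""
    family_id: str = ""
    family_acc: str = ""
    chromosome: str = ""
    genomic_coordinates: str = ""
    strand: str = ""
    pubmed_id: int = 0
    pmc_id: str = ""
    pubmed_title: str = ""
    pubmed_date: str = ""
    disease_phenotype: str = ""
    relevance_in_animal: str = ""
    omim_omia_name: str = ""
    omim_omia_id: str = ""
    disease_ontology: str = ""
    tissue_cell_type: str = ""
    bto_name: str = ""
    bto_id: str = ""
    association_method: str = ""
    target_gene: str = ""
    animal_ortholog: str = ""
    reciprocal_identity: str = ""
    orthology_confidence: str = ""
    human_homolog: str = field(default="", repr=False)

    @property
    def species_code(self) -> str:
        return self.mature_mirna_id.split("-", 1)[0]


# Table field numbers for violation messages, keyed by attribute.
_FIELD_NUMBERS = {name: i + 1 for i, name in enumerate(RESOURCE_COLUMNS)}


def validate_record(r: ResourceRecord,
                    hdmac: HdmacMap | None = None) -> list[str]:
    """Return human-readable invariant violations (empty when valid)."""
    violations: list[str] = []

    def flag(attr: str, msg: str) -> None:
        violations.append(f"field {_FIELD_NUMBERS[attr]} ({attr}): {msg}")

    if not r.mature_mirna_id:
        flag("mature_mirna_id", "missing")
    elif r.species_code == HUMAN_CODE:
        flag("mature_mirna_id", "must be an animal miRNA, got human prefix")
    if r.mature_sequence and not set(r.mature_sequence) <= set("ACGUN"):
        flag("mature_sequence", "not a normalized RNA sequence")
    if r.genomic_coordinates:
        try:
            start, end = map(int, r.genomic_coordinates.split("-"))
            if start > end:
                flag("genomic_coordinates", f"start {start} > end {end}")
        except ValueError:
            flag("genomic_coordinates", "expected start-end integers")
    if r.strand and r.strand not in ("+", "-"):
        flag("strand", "must be + or -")
    if r.pubmed_id <= 0:
        flag("pubmed_id", "pmid must be a positive integer")
    if hdmac is not None and r.human_homolog:
        hits = hdmac.matches.get(r.human_homolog, [])
        if r.mature_mirna_id not in {aid for aid, _ in hits}:
            flag("mature_mirna_id",
                 f"not an exact-match counterpart of {r.human_homolog}")
    return violations


def build_resource(
    hdmac: HdmacMap,
    diseases: Sequence[DiseaseAssociation],
    calls: Sequence | None = None,
    locations: Mapping[str, GenomicLocation] | None = None,
    orthologs: Sequence[OrthologPair] | None = None,
    *,
    animal_records: Iterable[MatureRecord] | None = None,
    precursors: Mapping[str, PrecursorRecord] | None = None,
    targets: Mapping[str, str] | None = None,
) -> list[ResourceRecord]:
    """Join the pipeline outputs into one record per (animal, human, disease).

    ``locations`` maps animal mature IDs to genomic locations,
    ``precursors`` maps animal mature IDs to their hairpin records, and
    ``targets`` maps human miRNA IDs to the gene they target; targets
    are serialized only for species where the gene has an ortholog that
    passed the reciprocal-identity filter. Disease associations whose
    human miRNA has no animal counterpart are excluded (counted in the
    log, not an error).
    """
    locations = locations or {}
    precursors = precursors or {}
    targets = targets or {}
    animal_by_id = {r.mirna_id: r for r in (animal_records or [])}
    kept_orthologs = {(p.human_gene, p.species_code): p
                      for p in (orthologs or [])}

    if not diseases:
        log.warning("empty disease table: no resource records produced")

    dropped = 0
    records: list[ResourceRecord] = []
    for assoc in diseases:
        hits = hdmac.matches.get(assoc.mirna_id)
        if not hits:
            dropped += 1
            continue
        hrec = hdmac.human_records[assoc.mirna_id]
        for animal_id, species in hits:
            arec = animal_by_id.get(animal_id)
            pre = precursors.get(animal_id)
            loc = locations.get(animal_id)
            rec = ResourceRecord(
                mature_mirna_id=animal_id,
                mature_mirna_acc=arec.accession if arec else "",
                mature_sequence=hrec.sequence,  # identical by construction
                premirna_id=pre.pre_id if pre else "",
                premirna_acc=pre.accession if pre else "",
                premirna_sequence=pre.sequence if pre else "",
                family_id=pre.family_id if pre else "",
                chromosome=loc.chromosome if loc else "",
                genomic_coordinates=loc.coordinates() if loc else "",
                strand=loc.strand if loc else "",
                pubmed_id=assoc.pmid,
                disease_phenotype=assoc.disease_name,
                tissue_cell_type=assoc.tissue,
                association_method=assoc.experiment,
                omim_omia_name=assoc.standardized.get("omim_omia_name", ""),
                omim_omia_id=assoc.standardized.get("omim_omia_id", ""),
                disease_ontology=assoc.standardized.get("do_term", ""),
                bto_name=assoc.standardized.get("bto_name", ""),
                bto_id=assoc.standardized.get("bto_id", ""),
                human_homolog=assoc.mirna_id,
            )
            gene = targets.get(assoc.mirna_id, "")
            pair = kept_orthologs.get((gene, species)) if gene else None
            if pair is not None:
                rec.target_gene = pair.human_gene
                rec.animal_ortholog = pair.animal_gene
                rec.reciprocal_identity = (
                    f"{min(pair.identity_h2a, pair.identity_a2h):.1f}")
                rec.orthology_confidence = str(pair.confidence)
            records.append(rec)
    if dropped:
        log.info("%d disease associations had no animal counterpart", dropped)
    records.sort(key=lambda r: (r.species_code, r.mature_mirna_id, r.pubmed_id,
                                r.disease_phenotype))
    return records


def summarize_resource(records: Sequence[ResourceRecord]) -> dict:
    """Distinct-entity counts over the integrated records."""
    per_species: dict[str, int] = {}
    for sp in sorted({r.species_code for r in records}):
        per_species[sp] = sum(1 for r in records if r.species_code == sp)
    return {
        "n_records": len(records),
        "distinct_animal_mirnas": len({r.mature_mirna_id for r in records}),
        "distinct_human_mirnas": len({r.human_homolog for r in records
                                      if r.human_homolog}),
        "distinct_diseases": len({r.disease_phenotype for r in records}),
        "distinct_pmids": len({r.pubmed_id for r in records}),
        "per_species_records": per_species,
    }
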