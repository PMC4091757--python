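"""Exact-match homology between human disease miRNAs and animal miRNAs.

A human disease-associated mature miRNA counts as having an animal
counterpart (an HDMAC) when at least one animal mature miRNA sequence
is 100% identical to it after normalization — full length, no
mismatches, no offset. Matching is on sequence alone; IDs, arms and
family labels are annotation. Sequences containing N can never certify
identity and are excluded from matching.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .mirna_io import HUMAN_CODE, MatureRecord, SpeciesTable
from .sequences import contains_n
from .sequences import normalize_sequence  # noqa: F401  (canonical entry point)

log = logging.getLogger(__name__)


@dataclass
class HdmacMap:
    """Human miRNA ID -> list of (animal miRNA ID, species code) matches."""

    matches: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    human_records: dict[str, MatureRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.matches)

    def matched_pairs(self) -> int:
        """Number of distinct (human, species) pairs with >=1 match."""
        return sum(len({sp for _, sp in hits}) for hits in self.matches.values())

    def animal_ids(self, species: str | None = None) -> set[str]:
        return {aid for hits in self.matches.values()
                for aid, sp in hits if species is None or sp == species}


def find_exact_homologs(human: Iterable[MatureRecord],
                        animals: Iterable[MatureRecord]) -> HdmacMap:
    """Map each human mature miRNA to every 100%-identical animal mature.

    Human records must all carry the ``hsa-`` prefix and animal records
    must not; empty inputs are allowed. A human ID appears in the map
    only if it has at least one match.
    """
    human = list(human)
    animals = list(animals)
    for rec in human:
        if rec.species_code != HUMAN_CODE:
            raise ValueError(f"non-human record {rec.mirna_id} in human set")
    for rec in animals:
        if rec.species_code == HUMAN_CODE:
            raise ValueError(f"human record {rec.mirna_id} in animal set")

    by_seq: dict[str, list[MatureRecord]] = {}
    for rec in human:
        if contains_n(rec.sequence):
            continue
        by_seq.setdefault(rec.sequence, []).append(rec)

    result = HdmacMap()
    for arec in animals:
        if contains_n(arec.sequence):
            continue
        for hrec in by_seq.get(arec.sequence, ()):
            result.matches.setdefault(hrec.mirna_id, []).append(
                (arec.mirna_id, arec.species_code))
            result.human_records[hrec.mirna_id] = hrec
    # restore human input order for determinism
    order = {r.mirna_id: i for i, r in enumerate(human)}
    result.matches = dict(sorted(result.matches.items(),
                                 key=lambda kv: order[kv[0]]))
    return result


@dataclass
class PresenceMatrix:
    """Human disease miRNA x species boolean conservation matrix.

    ``table`` is indexed by human miRNA ID with one boolean column per
    animal species; ``species_count`` is the per-row number of species
    in which a counterpart exists.
    """

    table: pd.DataFrame

    @property
    def species_count(self) -> pd.Series:
        return self.table.sum(axis=1).astype(int)

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self) -> str:
        """Serialize with +/- cells and a total column."""
        df = self.table.replace({True: "+", False: "-"})
        df["total_animal_species"] = self.species_count
        return df.to_csv(sep="\t", index_label="human_mirna_id")

    @classmethod
    def from_tsv(cls, text: str) -> "PresenceMatrix":
        import io

        df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, dtype=str)
        df = df.drop(columns=[c for c in df.columns
                              if c == "total_animal_species"])
        return cls((df == "+"))


def build_presence_matrix(hdmac: HdmacMap,
                          species: SpeciesTable | None = None) -> PresenceMatrix:
    """Tabulate presence/absence of each mapped human miRNA per species."""
    species = species or SpeciesTable()
    rows = {}
    for hid, hits in hdmac.matches.items():
        present = {sp for _, sp in hits}
        rows[hid] = [code in present for code in species.codes]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=species.codes,
                                   dtype=bool)
    return PresenceMatrix(table)


def filter_conserved(matrix: PresenceMatrix, mode: str) -> list[str]:
    """Select human miRNAs by conservation pattern.

    ``all_species``: a counterpart exists in every animal column.
    ``mammals_only``: counterparts in every mammalian column but not in
    chicken (``gga``), which must be one of the columns.
    """
    df = matrix.table
    if mode == "all_species":
        mask = df.all(axis=1)
    elif mode == "mammals_only":
        if "gga" not in df.columns:
            raise ValueError("mammals_only mode requires a gga column")
        mammal_cols = [c for c in df.columns if c != "gga"]
        mask = df[mammal_cols].all(axis=1) & ~df["gga"]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return list(df.index[mask])


def coverage_stats(hdmac: HdmacMap, totals: Mapping[str, int],
                   ) -> dict[str, tuple[int, float]]:
    """Per-species matched miRNA counts and percentage of the species total.

    ``totals`` maps species code -> total number of known mature miRNAs
    for that species (ID-level counts). Every species occurring in the
    map must have a total.
    """
    matched: dict[str, set[str]] = {}
    for hits in hdmac.matches.values():
        for aid, sp in hits:
            matched.setdefault(sp, set()).add(aid)
    missing = set(matched) - set(totals)
    if missing:
        raise ValueError(f"species in map missing from totals: {sorted(missing)}")
    out = {}
    for sp, total in totals.items():
        if total <= 0:
            raise ValueError(f"non-positive total for species {sp}")
        count = len(matched.get(sp, ()))
        out[sp] = (count, 100.0 * count / total)
    return out


def length_distribution(records: Iterable[MatureRecord],
                        ) -> tuple[dict[str, Counter], dict[str, int]]:
    """Histogram of mature lengths per species, plus per-species mode.

    Ties on the modal length resolve to the smallest length.
    """
    hist: dict[str, Counter] = {}
    for rec in records:
        hist.setdefault(rec.species_code, Counter())[len(rec.sequence)] += 1
    modes = {sp: min(c, key=lambda ln: (-c[ln], ln)) for sp, c in hist.items()}
    return hist, modes
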