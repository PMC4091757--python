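"""Reciprocal percent identity and the one-to-one >70% ortholog filter.

Human miRNA-target proteins are compared with candidate animal
orthologs by one full-length global alignment; percent identity is
computed twice, once with each sequence's full length as the
denominator, so terminal gaps penalize the shorter side. A candidate
pair is retained only when it is one-to-one within its species and
both identities strictly exceed 70%.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

from Bio.Align import substitution_matrices

from .align_phylo import GAP, ScoringScheme, global_align
from .sequences import check_protein

RECIPROCAL_IDENTITY_THRESHOLD = 70.0


@lru_cache(maxsize=1)
def protein_scheme() -> ScoringScheme:
    """BLOSUM62 substitution scores with affine gap penalties (-10/-1)."""
    blosum = substitution_matrices.load("BLOSUM62")
    table = {(a, b): float(blosum[a][b])
             for a in blosum.alphabet for b in blosum.alphabet}
    return ScoringScheme(gap_open=-10.0, gap_extend=-1.0,
                         alphabet="protein", substitution_table=table)


@dataclass
class OrthologPair:
    """A candidate human gene <-> animal gene couple with identities."""

    human_gene: str
    animal_gene: str
    species_code: str
    identity_h2a: float  # % identical positions over human full length
    identity_a2h: float  # % identical positions over animal full length
    one_to_one: bool = True
    confidence: int = 0  # Ensembl-style 0 (low) / 1 (high), pass-through

    def __post_init__(self) -> None:
        for v in (self.identity_h2a, self.identity_a2h):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"identity {v} outside [0, 100]")
        if self.confidence not in (0, 1):
            raise ValueError("confidence must be 0 or 1")


def percent_identity(a: str, b: str,
                     scheme: ScoringScheme | None = None,
                     ) -> tuple[float, float]:
    """Reciprocal percent identity from one full-length global alignment.

    Returns ``(identity_a2b, identity_b2a)`` where identity_a2b uses
    ``len(a)`` as denominator and identity_b2a uses ``len(b)``.
    """
    a = check_protein(a)
    b = check_protein(b)
    scheme = scheme or protein_scheme()
    aln = global_align(a, b, scheme)
    identical = sum(1 for x, y in zip(aln.aligned_a, aln.aligned_b)
                    if x == y and x != GAP)
    return 100.0 * identical / len(a), 100.0 * identical / len(b)


def filter_orthologs(pairs: Iterable[OrthologPair]) -> list[OrthologPair]:
    """Keep one-to-one pairs with both identities strictly above 70%.

    One-to-one status is recomputed within the input: a pair qualifies
    only if its human gene maps to exactly one animal gene of that
    species and that animal gene maps back to exactly one human gene.
    """
    pairs = list(pairs)
    human_deg = Counter((p.human_gene, p.species_code) for p in pairs)
    animal_deg = Counter((p.animal_gene, p.species_code) for p in pairs)
    kept = []
    for p in pairs:
        one_to_one = (human_deg[(p.human_gene, p.species_code)] == 1
                      and animal_deg[(p.animal_gene, p.species_code)] == 1)
        p.one_to_one = one_to_one
        if (one_to_one
                and p.identity_h2a > RECIPROCAL_IDENTITY_THRESHOLD
                and p.identity_a2h > RECIPROCAL_IDENTITY_THRESHOLD):
            kept.append(p)
    return kept
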