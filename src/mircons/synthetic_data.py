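"""Synthetic miRBase/HMDD-style fixtures with recorded ground truth.

The generator evolves pre-miRNA families down a fixed six-species tree
(((((human, pig), (horse, dog)), cow), chicken)) under a no-indel
uniform point-substitution model: each site mutates independently with
the branch's probability, to one of the three alternative bases chosen
uniformly (a Jukes–Cantor-like scheme with a closed-form collision
probability). Mature arms are carved from a fixed hairpin window and,
with a configurable probability, an animal's mature arm is overwritten
with the human sequence so that exact-match counterparts are planted
with known ground truth. Disease associations, target proteins at
controlled identity levels, and candidate ortholog pairs complete the
bundle, so every pipeline stage can be exercised offline against known
expected outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mirna_io import (
    DiseaseAssociation,
    MatureRecord,
    PrecursorRecord,
    SpeciesTable,
    write_family_map,
    write_fasta,
)

RNA_BASES = np.array(list("ACGU"))
AA_BASES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Fixed species topology ((((hsa,ssc),(eca,cfa)),bta),gga); each entry
#: is (branch name, children). Leaf branch names are the species codes.
TREE_TOPOLOGY: tuple = (
    ("gga", ()),
    ("mammal-root", (
        ("bta", ()),
        ("mammal-core", (
            ("hsa-ssc", (("hsa", ()), ("ssc", ()))),
            ("eca-cfa", (("eca", ()), ("cfa", ()))),
        )),
    )),
)

LEAVES = ("hsa", "ssc", "eca", "cfa", "bta", "gga")

#: Default per-branch substitution probabilities. Terminal mammal
#: branches are short (1%), internal mammal branches shorter (0.5%),
#: the cow branch slightly longer (2%) and the chicken branch much
#: longer (6%), reflecting the bird-mammal split: mammalian pre-miRNA
#: pairs then fall below the 5% divergence threshold in expectation
#: while human-chicken pairs fall above it.
DEFAULT_BRANCH_PROBS: dict[str, float] = {
    "hsa": 0.01, "ssc": 0.01, "eca": 0.01, "cfa": 0.01,
    "bta": 0.02, "gga": 0.06,
    "hsa-ssc": 0.005, "eca-cfa": 0.005,
    "mammal-core": 0.005, "mammal-root": 0.01,
}

DISEASE_POOL = [
    "breast cancer", "type 2 diabetes mellitus", "glioblastoma",
    "hepatocellular carcinoma", "acute myocardial infarction",
    "chronic lymphocytic leukemia", "colorectal cancer", "osteosarcoma",
    "pulmonary hypertension", "rheumatoid arthritis", "melanoma",
    "gastric cancer", "Alzheimer disease", "dilated cardiomyopathy",
    "ovarian cancer", "psoriasis", "asthma", "pancreatic cancer",
    "multiple sclerosis", "prostate cancer", "endometriosis",
    "chronic hepatitis B", "nephrotic syndrome", "sepsis",
    "ulcerative colitis", "epilepsy", "osteoarthritis",
    "non-small cell lung cancer", "heart failure", "muscular dystrophy",
]

TISSUE_POOL = ["serum", "plasma", "liver", "heart", "brain",
               "skeletal muscle", "kidney", "lung"]


@dataclass
class SimConfig:
    """Generator settings; the defaults are the simulated study conditions."""

    seed: int = 0
    branch_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BRANCH_PROBS))
    n_families: int = 50
    pre_length: int = 90
    mature_length: int = 22
    mature_arm: str = "3p"
    fraction_exact_mature: float = 0.5
    diseases_per_mirna: tuple[int, int] = (1, 3)  # inclusive range
    protein_length: int = 300
    target_identity_levels: tuple[float, ...] = (100.0, 98.0, 71.0, 70.0, 60.0)

    def __post_init__(self) -> None:
        for name, p in self.branch_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"branch probability {name}={p} outside [0,1]")
        if not 0.0 <= self.fraction_exact_mature <= 1.0:
            raise ValueError("fraction_exact_mature outside [0,1]")
        if self.pre_length <= 0 or self.mature_length <= 0:
            raise ValueError("lengths must be positive")
        if self.mature_length >= self.pre_length:
            raise ValueError("mature_length must be below pre_length")
        if self.mature_arm not in ("5p", "3p"):
            raise ValueError("mature_arm must be 5p or 3p")
        missing = set(DEFAULT_BRANCH_PROBS) - set(self.branch_probs)
        if missing:
            raise ValueError(f"branch_probs missing branches {sorted(missing)}")


def evolve_seq(seq: str, p_sub: float, rng: np.random.Generator) -> str:
    """Mutate each site independently with probability ``p_sub``.

    A mutated site becomes one of the three other bases uniformly;
    length is preserved and there are no indels.
    """
    if not 0.0 <= p_sub <= 1.0:
        raise ValueError(f"p_sub {p_sub} outside [0, 1]")
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < p_sub
    if hit.any():
        idx = {b: i for i, b in enumerate(RNA_BASES)}
        cur = np.array([idx[b] for b in arr[hit]])
        # offset 1..3 from the current base, modulo 4, never 0
        offs = rng.integers(1, 4, size=hit.sum())
        arr[hit] = RNA_BASES[(cur + offs) % 4]
    return "".join(arr)


def expected_pairwise_divergence(p_1: float, p_2: float) -> float:
    """Expected p-distance between two leaves with lineage probabilities.

    Under the uniform substitution model a site differs between the
    leaves with probability ``p1(1-p2) + p2(1-p1) + (2/3) p1 p2``: the
    last term is the chance both lineages mutated yet to different
    bases. For a multi-edge lineage, compose the per-edge probabilities
    with :func:`compose_path` first.
    """
    if not (0.0 <= p_1 <= 1.0 and 0.0 <= p_2 <= 1.0):
        raise ValueError("probabilities must be in [0, 1]")
    return p_1 * (1 - p_2) + p_2 * (1 - p_1) + (2.0 / 3.0) * p_1 * p_2


def compose_path(probs: list[float] | tuple[float, ...]) -> float:
    """Net substitution probability along consecutive branches.

    By the symmetry of the uniform model, chaining two edges follows
    the same collision formula as two independent lineages.
    """
    total = 0.0
    for p in probs:
        total = expected_pairwise_divergence(total, p)
    return total


def _leaf_root_paths() -> dict[str, list[str]]:
    paths: dict[str, list[str]] = {}

    def rec(children: tuple, above: list[str]) -> None:
        for branch, sub in children:
            if not sub:
                paths[branch] = [branch] + above
            else:
                rec(sub, [branch] + above)

    rec(TREE_TOPOLOGY, [])
    return paths


_LEAF_PATHS = _leaf_root_paths()


def expected_leaf_divergence(sp_a: str, sp_b: str,
                             branch_probs: dict[str, float] | None = None,
                             ) -> float:
    """Closed-form expected p-distance between two species' hairpins."""
    branch_probs = branch_probs or DEFAULT_BRANCH_PROBS
    pa, pb = _LEAF_PATHS[sp_a], _LEAF_PATHS[sp_b]
    lineage_a = [branch_probs[x] for x in pa if x not in pb]
    lineage_b = [branch_probs[x] for x in pb if x not in pa]
    return expected_pairwise_divergence(compose_path(lineage_a),
                                        compose_path(lineage_b))


@dataclass
class FamilyTruth:
    family_id: str
    ancestor: str
    leaf_sequences: dict[str, str]
    substitutions_per_branch: dict[str, int]
    planted_copies: list[str]  # species whose mature arm was overwritten


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    families: list[FamilyTruth] = field(default_factory=list)
    # (human mature ID, animal mature ID) pairs with identical sequences
    expected_matches: list[tuple[str, str]] = field(default_factory=list)
    # (animal mature ID, human mature ID, disease, pmid) planted triples
    planted_triples: list[tuple[str, str, str, int]] = field(default_factory=list)
    associations: list[DiseaseAssociation] = field(default_factory=list)
    protein_identities: dict[str, float] = field(default_factory=dict)
    expected_kept_genes: list[str] = field(default_factory=list)
    targets: dict[str, str] = field(default_factory=dict)

    def expected_match_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for hid, aid in self.expected_matches:
            out.setdefault(hid, []).append(aid)
        return out


def _mature_window(config: SimConfig) -> slice:
    # a 3-nt flank mimics the hairpin arm offsets of real precursors
    if config.mature_arm == "5p":
        return slice(3, 3 + config.mature_length)
    start = config.pre_length - 3 - config.mature_length
    return slice(start, start + config.mature_length)


def simulate_family(config: SimConfig, family_index: int,
                    rng: np.random.Generator,
                    ) -> tuple[list[PrecursorRecord], list[MatureRecord], FamilyTruth]:
    """Evolve one pre-miRNA family down the species tree.

    Returns the per-species precursor and mature records (human first)
    plus the ground-truth slice: ancestral sequence, realized
    substitution counts per branch, and which animal matures were
    planted as exact copies of the human arm.
    """
    number = 100 + family_index
    family_id = f"mir-{number}"
    ancestor = "".join(rng.choice(RNA_BASES, size=config.pre_length))
    leaf_seqs: dict[str, str] = {}
    subs: dict[str, int] = {}

    def rec(children: tuple, seq: str) -> None:
        for branch, sub in children:
            evolved = evolve_seq(seq, config.branch_probs[branch], rng)
            subs[branch] = sum(1 for x, y in zip(seq, evolved) if x != y)
            if not sub:
                leaf_seqs[branch] = evolved
            else:
                rec(sub, evolved)

    rec(TREE_TOPOLOGY, ancestor)

    window = _mature_window(config)
    human_pre = leaf_seqs["hsa"]
    human_mature = human_pre[window]
    planted: list[str] = []
    for sp in LEAVES:
        if sp == "hsa":
            continue
        if rng.random() < config.fraction_exact_mature:
            seq = leaf_seqs[sp]
            leaf_seqs[sp] = seq[:window.start] + human_mature + seq[window.stop:]
            planted.append(sp)

    precursors, matures = [], []
    for k, sp in enumerate(LEAVES):
        pre_id = f"{sp}-mir-{number}"
        mat_id = f"{sp}-miR-{number}-{config.mature_arm}"
        acc_n = 1000 + family_index * 10 + k
        precursors.append(PrecursorRecord(
            pre_id, f"MI{acc_n:07d}", sp, leaf_seqs[sp], family_id))
        matures.append(MatureRecord(
            mat_id, f"MIMAT{acc_n:07d}", sp, leaf_seqs[sp][window],
            config.mature_arm))
    truth = FamilyTruth(family_id, ancestor, dict(leaf_seqs), subs, planted)
    return precursors, matures, truth


@dataclass
class SimBundle:
    """An in-memory fixture bundle, writable as plain-text files."""

    config: SimConfig
    human_mature: list[MatureRecord]
    animal_mature: list[MatureRecord]
    precursors: list[PrecursorRecord]
    families: dict[str, list[str]]
    associations: list[DiseaseAssociation]
    human_proteins: dict[str, str]
    animal_proteins: dict[str, str]
    candidate_pairs: list[dict]
    truth: GroundTruth

    def disease_table_tsv(self) -> str:
        """Serialize associations, piping together same-pmid diseases."""
        grouped: dict[tuple[str, int], list[DiseaseAssociation]] = {}
        for a in self.associations:
            grouped.setdefault((a.mirna_id, a.pmid), []).append(a)
        lines = ["mirna_id\tdisease\tpmid\texperiment\ttissue"]
        for (mid, pmid), group in grouped.items():
            diseases = "|".join(a.disease_name for a in group)
            lines.append(f"{mid}\t{diseases}\t{pmid}\t"
                         f"{group[0].experiment}\t{group[0].tissue}")
        return "\n".join(lines) + "\n"

    def pairs_tsv(self) -> str:
        lines = ["human_gene\tanimal_gene\tspecies\tconfidence"]
        for p in self.candidate_pairs:
            lines.append(f"{p['human_gene']}\t{p['animal_gene']}\t"
                         f"{p['species']}\t{p['confidence']}")
        return "\n".join(lines) + "\n"

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "mature_human.fasta").write_text(write_fasta(self.human_mature))
        (out / "mature_animal.fasta").write_text(write_fasta(self.animal_mature))
        (out / "precursors.fasta").write_text(write_fasta(self.precursors))
        (out / "families.tsv").write_text(write_family_map(self.families))
        (out / "diseases.tsv").write_text(self.disease_table_tsv())
        (out / "proteins_human.fasta").write_text(_protein_fasta(self.human_proteins))
        (out / "proteins_animal.fasta").write_text(_protein_fasta(self.animal_proteins))
        (out / "ortholog_pairs.tsv").write_text(self.pairs_tsv())
        (out / "ground_truth.json").write_text(self._truth_json())

    def _truth_json(self) -> str:
        payload = dataclasses.asdict(self.truth)
        payload["families"] = [dataclasses.asdict(f) for f in self.truth.families]
        payload["associations"] = [
            {"mirna_id": a.mirna_id, "disease": a.disease_name, "pmid": a.pmid}
            for a in self.truth.associations]
        return json.dumps(payload, indent=1, sort_keys=True)


def _protein_fasta(proteins: dict[str, str]) -> str:
    return "".join(f">{name}\n{seq}\n" for name, seq in proteins.items())


def _mutate_protein(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    for p in pos:
        choices = [a for a in AA_BASES if a != arr[p]]
        arr[p] = choices[rng.integers(0, len(choices))]
    return "".join(arr)


def simulate_dataset(config: SimConfig | None = None) -> SimBundle:
    """Generate the full fixture bundle deterministically from the seed."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()

    human_mature: list[MatureRecord] = []
    animal_mature: list[MatureRecord] = []
    precursors: list[PrecursorRecord] = []
    families: dict[str, list[str]] = {}
    for i in range(config.n_families):
        pre, mat, fam_truth = simulate_family(config, i, rng)
        truth.families.append(fam_truth)
        precursors.extend(pre)
        families[fam_truth.family_id] = [p.pre_id for p in pre]
        for rec in mat:
            (human_mature if rec.species_code == "hsa"
             else animal_mature).append(rec)

    # realized exact matches, established by direct all-pairs comparison
    for hrec in human_mature:
        for arec in animal_mature:
            if hrec.sequence == arec.sequence:
                truth.expected_matches.append((hrec.mirna_id, arec.mirna_id))

    # disease associations for every human mature miRNA
    lo, hi = config.diseases_per_mirna
    for hrec in human_mature:
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(DISEASE_POOL), size=k, replace=False)
        shared_pmid = int(rng.integers(10_000_000, 30_000_000))
        for rank, di in enumerate(chosen):
            # the first two diseases share a pmid (a piped cell in the TSV)
            pmid = shared_pmid if rank < 2 else int(
                rng.integers(10_000_000, 30_000_000))
            assoc = DiseaseAssociation(
                mirna_id=hrec.mirna_id,
                disease_name=DISEASE_POOL[int(di)],
                pmid=pmid,
                experiment="qRT-PCR",
                tissue=TISSUE_POOL[int(rng.integers(0, len(TISSUE_POOL)))],
            )
            truth.associations.append(assoc)

    match_map = truth.expected_match_map()
    for assoc in truth.associations:
        for aid in match_map.get(assoc.mirna_id, ()):
            truth.planted_triples.append(
                (aid, assoc.mirna_id, assoc.disease_name, assoc.pmid))

    # target proteins at controlled identity levels, one gene per level
    human_proteins: dict[str, str] = {}
    animal_proteins: dict[str, str] = {}
    candidate_pairs: list[dict] = []
    species = SpeciesTable().codes
    length = config.protein_length
    for k, level in enumerate(config.target_identity_levels):
        gene = f"GENE{k + 1}"
        sp = species[k % len(species)]
        hseq = "".join(rng.choice(AA_BASES, size=length))
        n_subs = round((100.0 - level) / 100.0 * length)
        aseq = _mutate_protein(hseq, n_subs, rng)
        human_proteins[gene] = hseq
        animal_proteins[f"{gene}_{sp}"] = aseq
        candidate_pairs.append({"human_gene": gene,
                                "animal_gene": f"{gene}_{sp}",
                                "species": sp, "confidence": 1})
        truth.protein_identities[gene] = 100.0 * (length - n_subs) / length
        if truth.protein_identities[gene] > 70.0:
            truth.expected_kept_genes.append(gene)
        if k < len(human_mature):
            truth.targets[human_mature[k].mirna_id] = gene

    # one deliberate one-to-many couple: never passes the 1:1 filter
    sp = species[0]
    hseq = "".join(rng.choice(AA_BASES, size=length))
    human_proteins["GENEX"] = hseq
    for suffix in ("a", "b"):
        aseq = _mutate_protein(hseq, round(0.10 * length), rng)
        animal_proteins[f"GENEX{suffix}_{sp}"] = aseq
        candidate_pairs.append({"human_gene": "GENEX",
                                "animal_gene": f"GENEX{suffix}_{sp}",
                                "species": sp, "confidence": 0})

    return SimBundle(config, human_mature, animal_mature, precursors,
                     families, truth.associations, human_proteins,
                     animal_proteins, candidate_pairs, truth)
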