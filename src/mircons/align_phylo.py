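"""Alignment, divergence and neighbor-joining phylogeny of pre-miRNAs.

The pipeline quantifies hairpin conservation per miRNA family: members
are multiply aligned (progressive alignment over a UPGMA guide tree),
pairwise divergence proportions (p-distances) are taken from the
alignment columns, and a Saitou–Nei neighbor-joining tree summarizes
the family. A human pre-miRNA is called highly conserved in a species
when its smallest divergence to any same-family member of that species
is at most 0.05.

Everything here is deterministic for a fixed input and scoring scheme.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .mirna_io import HUMAN_CODE, PrecursorRecord
from .trees import PhyloTree, TreeNode

log = logging.getLogger(__name__)

GAP = "-"


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores: affine gaps, optional protein substitution table.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``. The
    nucleotide defaults (+2/-1, -5/-2) favor gap-free hairpin
    alignments; in protein mode the pair scores come from
    ``substitution_table`` and match/mismatch are ignored.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    alphabet: str = "nucleotide"
    substitution_table: Mapping[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        if self.substitution_table is None and not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if not self.gap_open <= self.gap_extend <= 0:
            raise ValueError("require gap_open <= gap_extend <= 0")

    def score(self, x: str, y: str) -> float:
        if self.substitution_table is not None:
            tab = self.substitution_table
            return tab[(x, y)] if (x, y) in tab else tab[(y, x)]
        return self.match if x == y else self.mismatch


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")


@dataclass
class Msa:
    """A multiple alignment: equal-length gapped rows with their IDs."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("MSA needs at least one row")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("MSA rows must have equal length")
        if len(self.ids) != len(self.rows):
            raise ValueError("one ID per row required")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


_NEG = float("-inf")
_M, _X, _Y = 0, 1, 2  # substitution / gap-in-b (up) / gap-in-a (left)
_TIE_TOL = 1e-9


def _gotoh(S: np.ndarray, go: float, ge: float,
           ) -> tuple[float, list[tuple[int, int]]]:
    """Affine-gap global alignment (Gotoh) over a precomputed score matrix.

    ``S[i, j]`` is the score of aligning column i of the first profile
    with column j of the second; a gap of length L costs
    ``go + (L - 1) * ge``. Returns the optimal score and the traceback
    as (di, dj) moves. Tie-breaking prefers the diagonal, then the
    vertical (gap in the second sequence), then the horizontal state.

    The three state matrices are filled row-wise with vectorized
    recurrences; the in-row horizontal state uses a running-max
    identity: Y[j] = ge*(j-1) + max_{k<j}(max(M,X)[k] + go - ge*k).
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    steps = np.arange(m + 1, dtype=float)
    X[1:, 0] = go + (np.arange(n) * ge)
    Y[0, 1:] = go + (np.arange(m) * ge)

    for i in range(1, n + 1):
        prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev[:-1] + S[i - 1]
        X[i, 1:] = np.maximum(np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) + go,
                              X[i - 1, 1:] + ge)
        base = np.maximum(M[i], X[i]) + go - ge * steps
        Y[i, 1:] = np.maximum.accumulate(base[:-1]) + ge * (steps[1:] - 1)

    finals = (M[n, m], X[n, m], Y[n, m])
    best = max(finals)
    state = int(np.argmax(np.isclose(finals, best, rtol=0.0, atol=_TIE_TOL)))
    moves: list[tuple[int, int]] = []
    i, j = n, m

    def pick(cands: tuple[float, ...], value: float) -> int:
        for k, c in enumerate(cands):
            if abs(c - value) <= _TIE_TOL:
                return k
        raise AssertionError("traceback failed to find a predecessor")

    while i > 0 or j > 0:
        if state == _M:
            prev = pick((M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]),
                        M[i, j] - S[i - 1, j - 1])
            moves.append((1, 1))
            i, j = i - 1, j - 1
        elif state == _X:
            prev = pick((M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go),
                        X[i, j])
            moves.append((1, 0))
            i -= 1
        else:
            prev = pick((M[i, j - 1] + go, X[i, j - 1] + go, Y[i, j - 1] + ge),
                        Y[i, j])
            moves.append((0, 1))
            j -= 1
        state = prev
    moves.reverse()
    return float(best), moves


def _char_score_matrix(a: str, b: str, scheme: ScoringScheme) -> np.ndarray:
    symbols = sorted(set(a) | set(b))
    lut = {s: i for i, s in enumerate(symbols)}
    table = np.array([[scheme.score(x, y) for y in symbols] for x in symbols])
    ai = np.fromiter((lut[c] for c in a), dtype=int, count=len(a))
    bi = np.fromiter((lut[c] for c in b), dtype=int, count=len(b))
    return table[np.ix_(ai, bi)]


def global_align(a: str, b: str, scheme: ScoringScheme | None = None,
                 ) -> PairwiseAlignment:
    """Optimal end-to-end alignment of two sequences under affine gaps.

    Deterministic tie-breaking: during traceback the diagonal move is
    preferred over the vertical (gap in ``b``) over the horizontal.
    """
    scheme = scheme or ScoringScheme()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if scheme.substitution_table is None:
        allowed = set("ACGUN") if scheme.alphabet == "nucleotide" else None
        if allowed is not None and not (set(a) <= allowed and set(b) <= allowed):
            raise ValueError("sequence alphabet does not match scoring scheme")
    score, moves = _gotoh(_char_score_matrix(a, b, scheme),
                          scheme.gap_open, scheme.gap_extend)
    out_a, out_b = [], []
    i = j = 0
    for di, dj in moves:
        out_a.append(a[i] if di else GAP)
        out_b.append(b[j] if dj else GAP)
        i += di
        j += dj
    return PairwiseAlignment("".join(out_a), "".join(out_b), score)


def p_distance(aligned_a: str, aligned_b: str) -> float:
    """Divergence proportion: mismatches over comparable columns.

    A column is comparable when both rows carry a non-gap, non-N
    symbol. Raises ``ValueError`` when no column is comparable — the
    divergence is then undefined, not 0 or 1.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    comparable = mismatches = 0
    for x, y in zip(aligned_a, aligned_b):
        if x in (GAP, "N") or y in (GAP, "N"):
            continue
        comparable += 1
        if x != y:
            mismatches += 1
    if comparable == 0:
        raise ValueError("no comparable columns between sequences")
    return mismatches / comparable


@dataclass
class DistanceMatrix:
    """Symmetric matrix of divergence proportions with a taxon order."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.values[i, j])

    def __len__(self) -> int:
        return len(self.taxa)


def build_guide_tree(d: DistanceMatrix) -> TreeNode:
    """UPGMA clustering (average linkage) used to order progressive merges.

    Ties resolve to the pair whose clusters contain the smallest
    original taxon indices, so an all-equal matrix produces a
    left-to-right ladder.
    """
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=t) for i, t in enumerate(d.taxa)}
    sizes = {i: 1 for i in range(n)}
    reps = {i: i for i in range(n)}  # smallest original index per cluster
    heights = {i: 0.0 for i in range(n)}
    dist = {(i, j): float(d.values[i, j])
            for i in range(n) for j in range(i + 1, n)}
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        best = min(
            ((dist[(min(i, j), max(i, j))], min(reps[i], reps[j]),
              max(reps[i], reps[j]), i, j)
             for i, j in itertools.combinations(sorted(active), 2)),
        )
        _, _, _, i, j = best
        dij = dist[(min(i, j), max(i, j))]
        h = dij / 2.0
        parent = TreeNode()
        for child in (nodes[i], nodes[j]):
            child.length = max(h - heights[i if child is nodes[i] else j], 0.0)
            parent.add(child)
        nodes[next_id] = parent
        heights[next_id] = h
        sizes[next_id] = sizes[i] + sizes[j]
        reps[next_id] = min(reps[i], reps[j])
        for k in active - {i, j}:
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(next_id, k), max(next_id, k))] = (
                sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    return nodes[next_id - 1]


def _profile_score_matrix(rows_a: list[str], rows_b: list[str],
                          scheme: ScoringScheme) -> np.ndarray:
    """Sum-of-pairs expected score between every column pair.

    Existing gap characters in a column score ``gap_extend`` against a
    residue and 0 against another gap; new gaps inserted during the
    profile merge pay the affine penalties inside the DP itself.
    """
    symbols = sorted({c for row in rows_a + rows_b for c in row} | {GAP})
    lut = {s: i for i, s in enumerate(symbols)}
    k = len(symbols)
    table = np.empty((k, k))
    for x in symbols:
        for y in symbols:
            if x == GAP and y == GAP:
                s = 0.0
            elif x == GAP or y == GAP:
                s = scheme.gap_extend
            else:
                s = scheme.score(x, y)
            table[lut[x], lut[y]] = s

    def counts(rows: list[str]) -> np.ndarray:
        arr = np.zeros((len(rows[0]), k))
        for row in rows:
            idx = np.fromiter((lut[c] for c in row), dtype=int, count=len(row))
            np.add.at(arr, (np.arange(len(row)), idx), 1.0)
        return arr

    ca, cb = counts(rows_a), counts(rows_b)
    return (ca @ table @ cb.T) / (len(rows_a) * len(rows_b))


def _merge_profiles(rows_a: list[str], rows_b: list[str],
                    scheme: ScoringScheme) -> tuple[list[str], list[str]]:
    S = _profile_score_matrix(rows_a, rows_b, scheme)
    _, moves = _gotoh(S, scheme.gap_open, scheme.gap_extend)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for di, dj in moves:
        for r, row in enumerate(rows_a):
            out_a[r].append(row[i] if di else GAP)
        for r, row in enumerate(rows_b):
            out_b[r].append(row[j] if dj else GAP)
        i += di
        j += dj
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_msa(seqs: Sequence[str], scheme: ScoringScheme | None = None,
                    ids: Sequence[str] | None = None) -> Msa:
    """Progressive multiple alignment over a UPGMA guide tree.

    Pairwise p-distances from global alignments order the merges;
    profiles are combined leaf-to-root with sum-of-pairs scoring and
    gaps, once inserted, are never removed ("once a gap, always a
    gap"). With two sequences this reduces to ``global_align``.
    """
    scheme = scheme or ScoringScheme()
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = list(ids) if ids is not None else [f"seq{i}" for i in range(len(seqs))]

    n = len(seqs)
    dm = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        aln = global_align(seqs[i], seqs[j], scheme)
        dm[i, j] = dm[j, i] = p_distance(aln.aligned_a, aln.aligned_b)
    guide = build_guide_tree(DistanceMatrix([str(i) for i in range(n)], dm))

    def rec(node: TreeNode) -> tuple[list[int], list[str]]:
        if node.is_leaf:
            idx = int(node.name)
            return [idx], [seqs[idx]]
        (ia, ra) = rec(node.children[0])
        (ib, rb) = rec(node.children[1])
        ra, rb = _merge_profiles(ra, rb, scheme)
        return ia + ib, ra + rb

    order, rows = rec(guide)
    # restore input order
    paired = sorted(zip(order, rows))
    return Msa([ids[i] for i, _ in paired], [r for _, r in paired])


def msa_distance_matrix(msa: Msa) -> DistanceMatrix:
    """All-pairs p-distances over the rows of a multiple alignment."""
    if len(msa.rows) < 2:
        raise ValueError("need at least 2 rows")
    n = len(msa.rows)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        values[i, j] = values[j, i] = p_distance(msa.rows[i], msa.rows[j])
    return DistanceMatrix(list(msa.ids), values)


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    At each step the pair minimizing
    ``Q(i, j) = (n - 2) d(i, j) - r_i - r_j`` is joined (ties to the
    smallest index pair); branch lengths follow the standard two-point
    formulas, with negative estimates clamped to zero and the deficit
    moved to the sister branch. The result is an unrooted tree rooted
    at a trifurcation for n >= 3.
    """
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        dd = float(d.values[0, 1])
        root = TreeNode()
        root.add(TreeNode(name=d.taxa[0], length=dd / 2.0))
        root.add(TreeNode(name=d.taxa[1], length=dd / 2.0))
        return PhyloTree(root)

    nodes: dict[int, TreeNode] = {i: TreeNode(name=t)
                                  for i, t in enumerate(d.taxa)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(d.values[i, j])
        for i in range(n) for j in range(i + 1, n)}

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = get(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            dist[(k, next_id) if k < next_id else (next_id, k)] = max(
                0.0, (get(i, k) + get(j, k) - dij) / 2.0)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    la = (get(a, b) + get(a, c) - get(b, c)) / 2.0
    lb = get(a, b) - la
    lc = get(a, c) - la
    root = TreeNode()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        nodes[k].length = max(lk, 0.0)
        root.add(nodes[k])
    return PhyloTree(root)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


CONSERVATION_THRESHOLD = 0.05

BIN_ZERO = "zero"
BIN_CONSERVED = "conserved_le_5pct"
BIN_DIVERGED = "diverged_gt_5pct"


def classify_conservation(divergence: float) -> str:
    """Bin a divergence proportion at the 5% conservation threshold.

    Exactly zero substitutions is its own bin; a divergence less than
    or equal to 0.05 is highly conserved; anything above is diverged.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError(f"divergence {divergence} outside [0, 1]")
    if divergence == 0.0:
        return BIN_ZERO
    if divergence <= CONSERVATION_THRESHOLD:
        return BIN_CONSERVED
    return BIN_DIVERGED


def is_highly_conserved(bin_label: str) -> bool:
    return bin_label in (BIN_ZERO, BIN_CONSERVED)


@dataclass
class ConservationCall:
    """Best same-family counterpart of one human pre-miRNA in one species."""

    human_pre_id: str
    animal_pre_id: str
    species_code: str
    divergence: float
    bin: str

    def __post_init__(self) -> None:
        if self.bin != classify_conservation(self.divergence):
            raise ValueError("bin inconsistent with divergence")


def conservation_profile(
    human_pre: Iterable[PrecursorRecord],
    animal_pre: Iterable[PrecursorRecord],
    families: Mapping[str, Sequence[str]],
    scheme: ScoringScheme | None = None,
) -> tuple[list[ConservationCall], dict[str, Counter]]:
    """Per-family conservation calls for every (human pre-miRNA, species).

    Each family is multiply aligned; the divergence of a human member
    toward a species is the minimum p-distance to any same-family
    member of that species (the most conserved counterpart). Families
    with fewer than two present members are skipped with a warning.
    Returns the calls plus per-species bin counts.
    """
    scheme = scheme or ScoringScheme()
    by_id = {r.pre_id: r for r in itertools.chain(human_pre, animal_pre)}
    assigned: dict[str, str] = {}
    for fam, members in families.items():
        for pid in members:
            if pid in assigned:
                raise ValueError(f"pre-miRNA {pid} assigned to multiple families")
            assigned[pid] = fam

    calls: list[ConservationCall] = []
    bin_counts: dict[str, Counter] = {}
    for fam, members in families.items():
        present = [by_id[p] for p in members if p in by_id]
        if len(present) < 2:
            log.warning("family %s has <2 present members; skipped", fam)
            continue
        msa = progressive_msa([r.sequence for r in present], scheme,
                              ids=[r.pre_id for r in present])
        dm = msa_distance_matrix(msa)
        humans = [r for r in present if r.species_code == HUMAN_CODE]
        species_codes = sorted({r.species_code for r in present
                                if r.species_code != HUMAN_CODE})
        for hrec in humans:
            for sp in species_codes:
                candidates = sorted(
                    (dm.get(hrec.pre_id, r.pre_id), r.pre_id)
                    for r in present if r.species_code == sp)
                div, best_id = candidates[0]
                call = ConservationCall(hrec.pre_id, best_id, sp, div,
                                        classify_conservation(div))
                calls.append(call)
                bin_counts.setdefault(sp, Counter())[call.bin] += 1
    return calls, bin_counts
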