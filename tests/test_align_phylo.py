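"""Alignment, p-distance, guide trees, neighbor joining, conservation bins."""

import itertools
import math
import random

import numpy as np
import pytest

from mircons import (
    ConservationCall,
    DistanceMatrix,
    PrecursorRecord,
    ScoringScheme,
    classify_conservation,
    conservation_profile,
    global_align,
    msa_distance_matrix,
    nj_tree,
    p_distance,
    progressive_msa,
)
from mircons.align_phylo import build_guide_tree, is_highly_conserved


def brute_force_score(a: str, b: str, s: ScoringScheme) -> float:
    """Exhaustive enumeration of every global alignment with affine gaps."""
    def rec(i, j, prev):
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            best = max(best, s.score(a[i], b[j]) + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = s.gap_extend if prev == "X" else s.gap_open
            best = max(best, cost + rec(i + 1, j, "X"))
        if j < len(b):
            cost = s.gap_extend if prev == "Y" else s.gap_open
            best = max(best, cost + rec(i, j + 1, "Y"))
        return best
    return rec(0, 0, None)


class TestGlobalAlign:
    def test_identical_no_gaps(self):
        aln = global_align("ACGU", "ACGU")
        assert aln.aligned_a == aln.aligned_b == "ACGU"
        assert aln.score == 4 * ScoringScheme().match

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("ACGU", "")

    def test_alphabet_mismatch(self):
        with pytest.raises(ValueError, match="alphabet"):
            global_align("ACGT", "ACGU")  # T is DNA, not normalized RNA

    def test_degapping_recovers_inputs(self):
        aln = global_align("ACGUACGU", "ACGACG")
        assert aln.aligned_a.replace("-", "") == "ACGUACGU"
        assert aln.aligned_b.replace("-", "") == "ACGACG"
        assert "--" not in [x + y for x, y in
                            zip(aln.aligned_a, aln.aligned_b)]

    def test_score_beats_handmade_alignment(self):
        # hand alignment: ACGU- / ACG-U scores 3*match + 2*gap_open
        s = ScoringScheme()
        aln = global_align("ACGUU", "ACGU", s)
        assert aln.score >= 3 * s.match + 2 * s.gap_open

    def test_matches_exhaustive_oracle(self):
        """DP score equals brute-force enumeration on short random pairs."""
        rng = random.Random(42)
        s = ScoringScheme()
        for _ in range(150):
            a = "".join(rng.choice("ACGU") for _ in range(rng.randint(1, 6)))
            b = "".join(rng.choice("ACGU") for _ in range(rng.randint(1, 6)))
            aln = global_align(a, b, s)
            assert aln.score == pytest.approx(brute_force_score(a, b, s))

    def test_deterministic(self):
        one = global_align("ACGUACGU", "AGGUACGA")
        two = global_align("ACGUACGU", "AGGUACGA")
        assert one == two


class TestPDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACGUACGUACGUACGUACGU", "ACGUACGUACGUACGUACGU", 0.0),
        ("ACGU", "ACGA", 0.25),
        ("AC-GU", "ACAGU", 0.0),
        ("NCGU", "ACGU", 0.0),  # N column not comparable
    ])
    def test_examples(self, a, b, expected):
        assert p_distance(a, b) == pytest.approx(expected)

    def test_no_comparable_columns_is_error(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance("A--", "-AA")

    def test_symmetry_and_range(self):
        rng = random.Random(3)
        for _ in range(50):
            a = "".join(rng.choice("ACGU-") for _ in range(12)) + "A"
            b = "".join(rng.choice("ACGU-") for _ in range(12)) + "A"
            d = p_distance(a, b)
            assert d == p_distance(b, a)
            assert 0.0 <= d <= 1.0


class TestGuideTree:
    def test_two_taxa_cherry(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 0.2], [0.2, 0]]))
        root = build_guide_tree(d)
        assert sorted(c.name for c in root.children) == ["a", "b"]

    def test_ultrametric_topology_recovered(self):
        # ((a,b),(c,d)) with heights 0.1 and 0.2, root at 0.3
        taxa = ["a", "b", "c", "d"]
        m = np.array([
            [0.0, 0.2, 0.6, 0.6],
            [0.2, 0.0, 0.6, 0.6],
            [0.6, 0.6, 0.0, 0.4],
            [0.6, 0.6, 0.4, 0.0]])
        root = build_guide_tree(DistanceMatrix(taxa, m))
        clades = {frozenset(c.name for c in child.leaves())
                  for child in root.children}
        assert clades == {frozenset("ab"), frozenset("cd")}

    def test_equal_distances_ladder_by_index(self):
        taxa = ["t0", "t1", "t2", "t3"]
        m = np.full((4, 4), 0.5)
        np.fill_diagonal(m, 0.0)
        root = build_guide_tree(DistanceMatrix(taxa, m))
        # ladder: ((t0,t1),t2),t3 merged in index order
        depths = {}

        def rec(node, depth):
            if node.is_leaf:
                depths[node.name] = depth
            for c in node.children:
                rec(c, depth + 1)
        rec(root, 0)
        assert depths["t0"] == depths["t1"] == 3
        assert depths["t2"] == 2 and depths["t3"] == 1


class TestProgressiveMsa:
    def test_identical_sequences_gap_free(self):
        seq = "ACGUACGUACGUACGUACGU"
        msa = progressive_msa([seq] * 4)
        assert all(row == seq for row in msa.rows)
        dm = msa_distance_matrix(msa)
        assert np.all(dm.values == 0)

    def test_two_sequences_equal_global_align(self):
        a, b = "ACGUACGUAC", "ACGACGUC"
        msa = progressive_msa([a, b])
        aln = global_align(a, b)
        assert msa.rows == [aln.aligned_a, aln.aligned_b]

    def test_planted_family_gap_free_and_column_homologous(self, bundle):
        """No-indel families align without gaps, columns map to ancestor."""
        truth = bundle.truth.families[0]
        seqs = [truth.leaf_sequences[sp]
                for sp in ("hsa", "ssc", "eca", "cfa", "bta", "gga")]
        msa = progressive_msa(seqs)
        assert msa.n_columns == len(truth.ancestor)
        assert msa.rows == seqs  # gap-free, order preserved

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            progressive_msa(["ACGU"])


class TestMsaDistanceMatrix:
    def test_matches_direct_p_distance(self):
        msa = progressive_msa(["ACGUACGUAC", "ACGACGUC"])
        dm = msa_distance_matrix(msa)
        assert dm.values[0, 1] == pytest.approx(
            p_distance(msa.rows[0], msa.rows[1]))

    def test_symmetric_zero_diagonal(self):
        rng = random.Random(5)
        seqs = ["".join(rng.choice("ACGU") for _ in range(30))
                for _ in range(4)]
        dm = msa_distance_matrix(progressive_msa(seqs))
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)


def random_additive_matrix(rng: random.Random, n_leaves: int):
    """Random binary tree with positive branch lengths -> path-length matrix."""
    nodes = [(i, None) for i in range(n_leaves)]  # (id, parent placeholder)
    parent = {}
    lengths = {}
    next_id = n_leaves
    ids = list(range(n_leaves))
    while len(ids) > 1:
        i = ids.pop(rng.randrange(len(ids)))
        j = ids.pop(rng.randrange(len(ids)))
        for k in (i, j):
            parent[k] = next_id
            lengths[k] = rng.uniform(0.05, 1.0)
        ids.append(next_id)
        next_id += 1
    root = ids[0]

    def path_to_root(k):
        out = []
        while k != root:
            out.append(k)
            k = parent[k]
        return out

    m = np.zeros((n_leaves, n_leaves))
    for a, b in itertools.combinations(range(n_leaves), 2):
        pa, pb = path_to_root(a), path_to_root(b)
        shared = set(pa) & set(pb)
        dist = sum(lengths[k] for k in pa + pb if k not in shared)
        m[a, b] = m[b, a] = dist
    return DistanceMatrix([f"t{i}" for i in range(n_leaves)], m)


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 0.1], [0.1, 0]]))
        tree = nj_tree(d)
        assert tree.leaf_distances()[("a", "b")] == pytest.approx(0.1)

    def test_three_taxa_closed_form(self):
        dab, dac, dbc = 0.3, 0.5, 0.6
        d = DistanceMatrix(["a", "b", "c"], np.array(
            [[0, dab, dac], [dab, 0, dbc], [dac, dbc, 0]]))
        tree = nj_tree(d)
        (a_node,) = [n for n in tree.root.children if n.name == "a"]
        assert a_node.length == pytest.approx((dab + dac - dbc) / 2)

    def test_additive_matrices_reconstructed_exactly(self):
        """NJ on additive input reproduces all pairwise path lengths."""
        rng = random.Random(7)
        for trial in range(20):
            d = random_additive_matrix(rng, rng.randint(5, 8))
            tree = nj_tree(d)
            paths = tree.leaf_distances()
            assert set(tree.leaf_names()) == set(d.taxa)
            for i, a in enumerate(d.taxa):
                for b in d.taxa[i + 1:]:
                    assert paths[(min(a, b), max(a, b))] == pytest.approx(
                        d.get(a, b), abs=1e-9)

    def test_taxon_order_invariance(self):
        rng = random.Random(9)
        d = random_additive_matrix(rng, 6)
        perm = list(range(6))
        rng.shuffle(perm)
        shuffled = DistanceMatrix(
            [d.taxa[i] for i in perm], d.values[np.ix_(perm, perm)])
        p1 = nj_tree(d).leaf_distances()
        p2 = nj_tree(shuffled).leaf_distances()
        for key, val in p1.items():
            assert p2[key] == pytest.approx(val, abs=1e-9)

    def test_branch_lengths_never_negative(self):
        rng = random.Random(13)
        # noisy, non-additive matrices
        for _ in range(10):
            n = rng.randint(4, 7)
            m = np.zeros((n, n))
            for i, j in itertools.combinations(range(n), 2):
                m[i, j] = m[j, i] = rng.uniform(0.0, 1.0)
            tree = nj_tree(DistanceMatrix([f"t{i}" for i in range(n)], m))
            assert all(node.length >= 0 for node in tree.root.walk())

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 0.1], [0.2, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, -0.1], [-0.1, 0]]))


class TestClassifyConservation:
    @pytest.mark.parametrize("d,expected", [
        (0.0, "zero"),
        (0.02, "conserved_le_5pct"),
        (0.05, "conserved_le_5pct"),   # boundary is inclusive
        (0.0500001, "diverged_gt_5pct"),
        (1.0, "diverged_gt_5pct"),
    ])
    def test_bins(self, d, expected):
        assert classify_conservation(d) == expected

    def test_highly_conserved_includes_zero_and_le5(self):
        assert is_highly_conserved("zero")
        assert is_highly_conserved("conserved_le_5pct")
        assert not is_highly_conserved("diverged_gt_5pct")

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_conservation(1.5)

    def test_monotone(self):
        order = {"zero": 0, "conserved_le_5pct": 1, "diverged_gt_5pct": 2}
        grid = [i / 200 for i in range(201)]
        bins = [order[classify_conservation(d)] for d in grid]
        assert bins == sorted(bins)


class TestConservationProfile:
    def _records(self, seqs_by_species, number=1):
        out = []
        for sp, seq in seqs_by_species.items():
            out.append(PrecursorRecord.from_parts(
                f"{sp}-mir-{number}", "", seq, f"mir-{number}"))
        return out

    def test_identical_family_all_zero(self):
        seq = "ACGU" * 20
        recs = self._records({sp: seq for sp in ("hsa", "bta", "ssc")})
        human = [r for r in recs if r.species_code == "hsa"]
        animal = [r for r in recs if r.species_code != "hsa"]
        calls, bins = conservation_profile(
            human, animal, {"mir-1": [r.pre_id for r in recs]})
        assert {c.bin for c in calls} == {"zero"}
        assert bins["bta"]["zero"] == 1

    def test_minimum_distance_counterpart_chosen(self):
        base = "ACGU" * 20
        diverged = "UGCA" * 20
        human = [PrecursorRecord.from_parts("hsa-mir-1", "", base)]
        animal = [PrecursorRecord.from_parts("bta-mir-1a", "", diverged),
                  PrecursorRecord.from_parts("bta-mir-1b", "", base)]
        calls, _ = conservation_profile(
            human, animal,
            {"mir-1": ["hsa-mir-1", "bta-mir-1a", "bta-mir-1b"]})
        (call,) = calls
        assert call.animal_pre_id == "bta-mir-1b"
        assert call.divergence == 0.0

    def test_human_only_family_no_calls(self):
        human = [PrecursorRecord.from_parts("hsa-mir-1", "", "ACGU" * 20),
                 PrecursorRecord.from_parts("hsa-mir-2", "", "ACGU" * 20)]
        calls, _ = conservation_profile(
            human, [], {"mir-1": ["hsa-mir-1", "hsa-mir-2"]})
        assert calls == []

    def test_singleton_family_skipped(self, caplog):
        human = [PrecursorRecord.from_parts("hsa-mir-1", "", "ACGU" * 20)]
        calls, _ = conservation_profile(human, [], {"mir-1": ["hsa-mir-1"]})
        assert calls == []

    def test_duplicate_family_assignment_rejected(self):
        human = [PrecursorRecord.from_parts("hsa-mir-1", "", "ACGU" * 20)]
        with pytest.raises(ValueError, match="multiple families"):
            conservation_profile(human, [], {"a": ["hsa-mir-1"],
                                             "b": ["hsa-mir-1"]})

    def test_call_consistency_enforced(self):
        with pytest.raises(ValueError):
            ConservationCall("hsa-mir-1", "bta-mir-1", "bta", 0.2, "zero")
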