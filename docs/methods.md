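# Methods

## Problem and model

The package asks, for each human disease-associated mature miRNA,
(i) whether any of five domestic animal species (cow `bta`, chicken
`gga`, pig `ssc`, horse `eca`, dog `cfa`) carries a mature miRNA with
the *identical* sequence, (ii) how diverged the corresponding pre-miRNA
hairpins are, and (iii) whether the miRNA's protein target has a
well-supported animal ortholog. The three questions use three distinct
criteria, all implemented here:

* **Exact mature-sequence identity.** Two mature miRNAs match iff
  their normalized RNA sequences are equal — same length, same content,
  no offsets, no mismatch tolerance. Normalization folds case and maps
  T→U, so DNA-alphabet inputs never block a match. A sequence
  containing `N` can never certify 100% identity and is excluded from
  matching entirely. Matching is on sequence only; IDs, arm labels and
  family labels are carried as annotation. Duplicate sequences with
  distinct IDs within a species are each reported, so counts are
  ID-level, not unique-sequence-level.

* **Hairpin divergence.** Within a curated miRNA family, members are
  multiply aligned and pairwise divergence is the p-distance: the
  fraction of *comparable* alignment columns (non-gap, non-`N` in both
  rows) at which the rows differ. A human hairpin's divergence toward a
  species is the **minimum** p-distance over that species' family
  members — the question being whether a conserved counterpart exists,
  not how conserved the average member is. Divergence ≤ 0.05 counts as
  highly conserved; the boundary value 0.05 is inclusive. The zero bin
  (no observed substitutions) is reported separately from (0, 0.05].
  The conservation call uses alignment p-distances, not tree branch
  lengths; the neighbor-joining tree is a summary for visualization and
  downstream tree analysis.

* **Reciprocal target identity.** Candidate human/animal protein
  couples are scored with a single full-length global alignment;
  percent identity is the number of identical aligned residue pairs
  divided by each sequence's *full* length in turn, so terminal gaps
  penalize the truncated side. A pair is kept iff it is one-to-one
  within its species (neither gene occurs in another candidate pair for
  that species) and both identities are strictly greater than 70.
  No database search or synteny is involved: candidates are given.

## Alignment machinery

Pairwise alignment is global (end-to-end) with affine gap costs: a gap
of length L costs `gap_open + (L−1)·gap_extend`. Defaults for
nucleotides are match +2, mismatch −1, gap_open −5, gap_extend −2 —
deliberately gap-averse, since pre-miRNA hairpins within a family are
nearly indel-free and spurious gaps would distort p-distances. Protein
mode uses BLOSUM62 with gap_open −10, gap_extend −1. The dynamic
program is the three-state Gotoh recurrence, filled row-wise with
vectorized numpy operations (the in-row horizontal gap state is
resolved with a running-maximum identity). Traceback tie-breaking is
deterministic: diagonal, then vertical (gap in the second sequence),
then horizontal; predecessor states are matched within an absolute
tolerance of 1e−9, far below the smallest meaningful score difference
of any supported scheme.

The multiple alignment is progressive: all-pairs global alignments give
p-distances, a UPGMA (average-linkage) guide tree orders the merges
(ties broken toward the smallest original taxon indices, so an
all-equal matrix yields a deterministic ladder), and profiles are
merged leaf-to-root with sum-of-pairs expected column scores. Existing
gap characters score `gap_extend` against residues and 0 against gaps;
once inserted, a gap is never removed. With two input sequences the
procedure reduces exactly to the pairwise aligner.

Neighbor joining follows Saitou–Nei: repeatedly join the pair
minimizing `Q(i,j) = (n−2)d(i,j) − r_i − r_j`, with branch lengths from
the standard two-point formulas. Negative branch-length estimates are
clamped to zero and the deficit moved to the sister branch, preserving
the cherry's total length. Ties resolve to the smallest index pair. The
output is an unrooted tree serialized rooted at a trifurcation, branch
lengths to six decimals. On an additive input matrix the reconstructed
leaf-to-leaf path lengths reproduce the input exactly (verified to
1e−9 in tests).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not real hairpin biology. Each family draws a uniform-random ancestral
hairpin (default 90 nt) and evolves it down the fixed topology
`((((hsa,ssc),(eca,cfa)),bta),gga)` under a no-indel point-substitution
model: each site independently substitutes with the branch's
probability, to one of the three alternative bases uniformly
(Jukes–Cantor-like). Under this model the probability that two leaves
differ at a site has the closed form
`p₁(1−p₂) + p₂(1−p₁) + (2/3)p₁p₂`, where `p₁, p₂` are the lineage
probabilities obtained by composing per-branch probabilities with the
same formula; this closed form is the oracle for parameter-recovery
tests.

Default branch substitution probabilities: 0.01 on terminal mammal
branches, 0.005 on internal mammal branches, 0.02 on the cow branch and
0.06 on the chicken branch, with 0.01 on the mammal stem. These place
expected human–mammal hairpin divergences at roughly 0.02–0.04 (below
the 0.05 threshold) and human–chicken divergence near 0.09 (above it),
reproducing the qualitative regime of real amniote miRNA families —
most mammalian pairs highly conserved, chicken diverged. The mature arm
is a fixed 22-nt window 3 nt from the hairpin's 3′ end (5′ optionally);
with probability `fraction_exact_mature` (default 0.5) an animal's arm
window is overwritten with the human arm, planting an exact-match
counterpart. Realized matches (planted plus identical-by-descent) are
recorded by direct sequence comparison and constitute the ground truth
that exact matching must recover. Disease associations draw 1–3
phenotypes per human miRNA from a fixed pool, with the first two
sharing a Pubmed ID so the pipe-separated multi-disease cell format is
exercised. Target proteins are generated at exact planted identity
levels (100, 98, 71, 70, 60 percent, by substituting the required
residue count in a 300-residue sequence), plus one deliberate
one-to-many couple that must fail the one-to-one filter.

What the generator does **not** emulate: indels (so guide-tree and gap
behavior on real, gap-containing families is exercised only by the
alignment unit tests, not end-to-end), rate heterogeneity across sites,
hairpin secondary structure and thermodynamics, arm-switching, multiple
hairpin copies per family within a species, and the empirical length
distribution of real matures (all simulated matures share one length).
Passing tests therefore certify the pipeline's bookkeeping and
statistical behavior under the stated model, not performance on real
miRBase data; the I/O layer is separately tested against miRBase-dialect
edge cases (extra header tokens, DNA alphabet, `N` bases, malformed
records).

## Integration

The resource record grain is one (animal mature miRNA, human homolog,
disease association) triple — the finest grain the 28-column table
supports; per-miRNA aggregation is a presentation concern. Records sort
deterministically by (species, miRNA ID, Pubmed ID, phenotype), and the
writer refuses any record failing validation, so re-running integration
on identical inputs yields a byte-identical TSV. Genomic coordinates
are 1-based inclusive pass-through data. Ontology fields (OMIM/OMIA,
Disease Ontology, BRENDA Tissue Ontology) are opaque strings: no live
lookups. The mature sequence serialized for an animal record is the
human homolog's sequence, which is identical by the exact-match
invariant. Disease associations whose human miRNA has no animal
counterpart are dropped with a logged count, not an error.

## Numerical and design choices

* Degenerate inputs: p-distance over zero comparable columns is an
  error (neither 0 nor 1); families with fewer than two present members
  are skipped with a warning; empty match maps yield empty matrices.
* The curated 56-row presence/absence matrix bundled under
  `mircons/data/` is a desk-scale reference input; its per-row species
  totals are recomputed and checked, never trusted.
* Problem sizes: the default generator produces 50 families of 90-nt
  hairpins across 6 species (~2 s for the full pipeline); tests use
  6–12 families, and parameter-recovery checks use 400-nt hairpins with
  planting disabled so the binomial standard error of the mean
  divergence is well below the effects under test.
* Randomness enters only through the generator's seed; alignment,
  clustering and integration are fully deterministic, with explicit
  tie-break rules throughout.

## Known limitations

Near-matches (≤k mismatches) and seed-region matching are out of scope;
matching is strictly exact. Distance correction beyond the raw
p-distance (e.g., Kimura) is not applied, though the scoring scheme and
distance hook are configurable. The progressive aligner is a profile
sum-of-pairs implementation without iterative refinement and is not a
substitute for a production MSA tool on large, indel-rich families.
Orthology confidence is pass-through metadata, never recomputed.
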