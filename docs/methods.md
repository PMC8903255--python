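# Methods

## Pocket definition and the three-point representation

A binding pocket is the set of protein residues with at least one heavy
atom within a cutoff (default **4.5 Å**) of any heavy atom of a bound
ligand.  Hydrogens are ignored on both sides because most deposited
structures lack them; waters and ions never count as pocket residues.
Only the first model of a multi-model file is used, and for alternate
locations the highest-occupancy conformer is kept (first encountered on
a tie).  Nonstandard residues are mapped to their parent amino acid via
the curated het-to-parent table shipped with Biopython, and to `X`
(worst-case in all substitution lookups) when no parent is known.

Each residue is reduced to Cα, Cβ and the unweighted centroid of its
side-chain heavy atoms (Cβ included, so short side chains keep a
sensible mass centre).  Glycine has no side chain: all three points
collapse onto Cα.  For alanine the centroid is Cβ itself.  A missing Cβ
on a non-glycine residue is rebuilt from N, CA and C at ideal
tetrahedral geometry (1.53 Å bond); a side chain missing beyond Cβ is
treated like alanine.  Residues without Cα are skipped with a logged
warning.  The representation is exactly equivariant under rigid motions,
which the tests assert to 1e-9 Å.

## Pairwise alignment

Each pocket yields an N×N×3 distance matrix (Cα–Cα, Cβ–Cβ,
centroid–centroid).  A candidate pairing of residue i in one pocket with
residue j in the other is a node of a correspondence graph; two nodes
are joined when the RMSD between their two three-channel dyad distance
triplets is below the tolerance (**1.0 Å**, applied to the RMSD of the
triplet rather than per channel) and the mapping stays injective.
Cliques of this graph are mutually consistent partial alignments.

The clique search is a best-first depth-first traversal: candidates are
ordered by increasing summed dyad RMSD to the current clique, a
candidate that breaks consistency is moved to a visited set
(backtracking), branches that cannot reach the best length found so far
are pruned, and the whole search is capped by a node-expansion budget
(default **20 000** per pocket pair).  Below the budget the search is
exhaustive — for pockets of ≤ 6 residues the reported match count
provably equals the brute-force maximum clique, which the tests verify
against an independent exact solver — and above it the search degrades
gracefully into an anytime heuristic.  Up to **10** seeds are kept,
ranked by length, then raw BLOSUM-62 sum of the mapped pairs, then
lexicographically (the package is deterministic everywhere; every tie
anywhere is broken lexicographically).

Only dyads seed the search.  Triads and tetrads would constrain the
search more strongly but multiply the candidate space (a 20-residue site
has 380 dyads, 6 840 triads, 116 280 tetrads); the combinatorics helper
exists to make that accounting explicit.

Each top seed is superposed with the Kabsch algorithm using **all three
points** of every matched residue (three points per residue stabilise
the rotation for short seeds), then extended and refined:

1. unmatched residues are paired greedily by mutual nearest neighbour
   whenever their post-superposition Cα–Cα distance is below the
   extension cutoff (default **2.0 Å**);
2. the frame is re-fitted on the extended set and step 1 is repeated
   from scratch (seed pairs stay locked) until the correspondence is
   stable — first at twice the cutoff to settle the frame, then at the
   cutoff itself.  A single pass is not enough: a frame fitted only on
   the seed subset is tilted towards it, and with every residue of a
   pocket displaced by ~1.4 Å a one-pass extension strands several true
   correspondences outside the cutoff.  The coarse-to-fine loop is the
   standard trimmed-ICP remedy.

Two guards keep the extension honest:

* **Minimum seed support (4 residues).**  Three residues are the
  mathematical minimum that fixes a rigid frame, so a three-residue seed
  is unfalsifiable; one consistent residue beyond the minimum is
  required before any extension.  On 1 000 unrelated synthetic pocket
  pairs of ≤ 6 residues the largest chance clique was 3, so chance
  seeds in the small-pocket regime never extend.
* **Majority-coverage acceptance.**  The extended correspondence
  replaces the seed only when it accounts for at least **half of the
  smaller pocket**.  Frames borrowed from chance-level seeds between
  unrelated pockets plateau near a third of the pocket, whereas genuine
  frames converge to near-complete correspondences, so the acceptance is
  effectively bimodal — mirroring the intended behaviour of reporting
  clean alignments for related sites and no alignment for unrelated
  ones.

Candidates are scored by match count, then scaled-BLOSUM sum, and the
best becomes the alignment.  Scores: `m_dist_max` = matches / larger
pocket, `m_dist_min` = matches / smaller pocket, `m_seq` = arithmetic
mean over matched pairs of the scaled BLOSUM-62 score
`max(0, B(a,b)) / min(B(a,a), B(b,b))`, clamped to [0, 1] (identity = 1,
anything involving `X` = 0).  Matches are the pairs of the final
correspondence with no further per-pair distance cap.  The computation
runs in a canonical pocket order and is mapped back, so all three scores
are exactly symmetric under argument swap.  If no compatible dyad exists
at all, the scores are 0 and the pair list empty — "no alignment" is a
result, not an error.

## Multiple alignment, clustering, motifs

All-vs-all comparison enumerates ordered pairs including self (N²
records — the convention that reproduces published pair counts such as
676 for 26 sites); each unordered pair is computed once and mirrored,
and the sorted output is invariant to the worker count of the
process-parallel map.

The similarity network keeps edges with `m_dist_max ≥ 0.4`.  Clustering
is MCODE-style: vertices are weighted by core-clustering coefficient ×
highest k-core number of their closed neighbourhood; complexes grow from
the heaviest unseen vertex over neighbours within 20% of the seed
weight; a single haircut pass removes singly connected members.  Members
of no complex survive as singleton clusters, so clustering is a
partition that refines the connected components.  Each cluster's
representative is its highest weighted-degree member (within the
cluster; ties lexicographic).

Every member is pairwise-aligned onto the representative (star multiple
alignment — no simultaneous multi-superposition is attempted).  Each
representative residue defines a profile column carrying occupancy,
residue counts, the mean Cα of the column in the representative frame
and the per-member mapped sequence position.  Motif derivation keeps
columns with occupancy ≥ **0.7**; a column admits the amino acids seen
in ≥ **10%** of its occupying members; consecutive columns separated in
sequence render a variable gap `x(kmin,kmax)` from the range of
separations observed across members, and a minimum separation beyond
**30** splits the motif into sequence-discontinuous parts.  The
occupancy, frequency and split thresholds are free parameters of this
package (exposed on the CLI); they were fixed once against the
qualitative shape of published site motifs (two short conserved blocks
bridged by a wide variable gap) and are not fitted to data.

Scanning requires all three evidence types at once: residue identity in
the element's set, sequence separations inside the gap bounds, and a
Kabsch superposition of the assigned Cα onto the column anchors with
RMSD ≤ **1.5 Å**; the minimum-RMSD assignment wins.  Motifs with fewer
than three anchored positions cannot pin a frame and fall back to
sequence-only matching.

## Synthetic test bed

The generator emulates pockets, not proteins: n residues (5–30 in the
studied range) with uniform random types, Cα rejection-sampled in a
sphere (default diameter 20 Å; all pairwise Cα distances ≥ 3.5 Å), Cβ
at 1.53 Å in a random direction and the centroid 0.5–2.5 Å beyond Cβ,
glycine/alanine identities respected.  Everything is deterministic in
the seed.

*Position perturbation* displaces every residue rigidly (all three
points together) along its own uniform random direction with one shared
magnitude, rescaled so the realized Cα RMSD equals the request to 1e-6.
The shared magnitude makes the perturbation a pure distance-noise probe:
the question is how the aligner degrades as *every* inter-residue
distance decays, not whether a few outlier residues are droppable.
*Type perturbation* mutates a chosen fraction of residues to uniformly
random different types, never touching a Cα; side-chain points are
rebuilt only where the glycine/alanine representation rules force it.
The planted-motif universe builds clusters from a common base pocket
whose core residues (defaults: 9 of 20, i.e. a core fraction above the
0.4 network threshold) keep their types and positions (0.15 Å jitter)
while all other residues are re-typed and relocated per member; decoys
are fresh random pockets.  At the default density (20 residues across a
28 Å site) unrelated pockets stay below the network threshold, so the
planted partition is the unique ground truth.

What the synthetic bed does **not** emulate: backbone connectivity and
secondary structure, realistic side-chain geometry and rotamers, residue
composition bias of real sites, cofactors, or crystallographic noise
models.  Tests passing on it therefore establish the geometric and
algorithmic claims (score identities, mutation invariance of the
distance scores, graceful degradation, exact clique recovery,
planted-motif recovery) — they do not certify performance on real
structures, for which the `extract` path consumes ordinary PDB files.

## Sizes, budgets, numerical notes

The test suite and acceptance checks run at desk scale: sensitivity
sweeps use one 20-residue pocket with 100 replicates per magnitude, the
oracle-equivalence check uses 200 pocket pairs of 4–6 residues, and the
planted universe holds 50 pockets (3 × 5 members + 35 decoys).  The
large published-count check (1 319 sites → 1 739 761 pair records) runs
with a stub comparator since it tests enumeration, not alignment.
Degenerate superposition inputs (< 3 points, collinear sets) raise a
dedicated error and the affected seed is skipped; self-comparisons are
exact (scores equal 1.0 by equality, not tolerance).  Coordinates are
Å throughout; residue numbering is the 1-based PDB convention.
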