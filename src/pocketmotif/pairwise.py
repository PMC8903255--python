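"""Pairwise, sequence-order-independent structural alignment of pockets.

Two pockets are compared through their per-pocket distance matrices
(N×N×3: Cα–Cα, Cβ–Cβ and centroid–centroid distances).  A candidate
residue correspondence (i, j) is a node of a correspondence graph; two
candidates are joined when their dyad distance triplets agree to an RMSD
below a tolerance (1.0 Å).  Cliques of this graph are mutually
consistent partial alignments ("seed alignments"); they are grown by a
best-first depth-first search with backtracking over a visited set,
superposed with the Kabsch algorithm using all three points of every
matched residue, extended by mutual-nearest-neighbour Cα matching and
scored.

Three scores are reported, each in [0, 1]:

* ``m_dist_max`` -- matches / size of the larger pocket (global similarity)
* ``m_dist_min`` -- matches / size of the smaller pocket (local similarity)
* ``m_seq``     -- mean scaled BLOSUM-62 substitution score over matched
  residue pairs (sequence similarity of the structurally matched shell)

A score of 1 on all three means the pockets are identical.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .pockets import Pocket, STANDARD_AA1

__all__ = [
    "DistanceMatrix",
    "SeedAlignment",
    "PairwiseAlignment",
    "DegenerateGeometryError",
    "build_distance_matrix",
    "count_ktuple_permutations",
    "dyad_compatible",
    "generate_seeds",
    "kabsch_superpose",
    "align_pair",
    "scaled_blosum",
    "raw_blosum",
]

CHANNELS = ("ca", "cb", "cn")

DEFAULT_TOL = 1.0          # dyad RMSD tolerance, Å
DEFAULT_EXT_CUTOFF = 2.0   # post-superposition Cα extension cutoff, Å
DEFAULT_MAX_SEEDS = 10
DEFAULT_MAX_EXPANSIONS = 20000  # clique-search node budget per pocket pair
# Minimum seed support to trust a superposition frame for extension: three
# residues are the mathematical minimum that fixes a rigid frame, so a frame
# supported by only that minimum is unfalsifiable; one consistent residue
# beyond it is required before neighbour extension is applied.
MIN_EXT_SEED = 4
# An extended correspondence is trusted only when it accounts for at least
# this fraction of the smaller pocket; otherwise the alignment is reported
# at seed level.  Chance-level frames between unrelated pockets never reach
# majority coverage, while genuinely similar sites converge to near-complete
# correspondences, so the acceptance is effectively bimodal.
EXT_ACCEPT_FRACTION = 0.5


class DegenerateGeometryError(ValueError):
    """Raised when a point set is too degenerate to superpose."""


# ---------------------------------------------------------------------------
# BLOSUM-62 lookups
# ---------------------------------------------------------------------------

def _build_blosum_tables():
    from Bio.Align import substitution_matrices

    b62 = substitution_matrices.load("BLOSUM62")
    letters = STANDARD_AA1 + "X"
    index = {aa: i for i, aa in enumerate(letters)}
    raw = np.zeros((len(letters), len(letters)))
    scaled = np.zeros_like(raw)
    for a in letters:
        for b in letters:
            raw[index[a], index[b]] = b62[a, b]
    for a in STANDARD_AA1:
        for b in STANDARD_AA1:
            val = max(0.0, b62[a, b]) / min(b62[a, a], b62[b, b])
            scaled[index[a], index[b]] = min(1.0, max(0.0, val))
    # 'X' rows/columns stay 0 in the scaled table (worst case).
    return index, raw, scaled


_B62_INDEX, _B62_RAW, _B62_SCALED = _build_blosum_tables()


def _aa_index(aa: str) -> int:
    try:
        return _B62_INDEX[aa]
    except KeyError:
        raise ValueError(f"unknown amino-acid code {aa!r}") from None


def raw_blosum(a: str, b: str) -> float:
    """Unscaled BLOSUM-62 substitution score."""
    return float(_B62_RAW[_aa_index(a), _aa_index(b)])


def scaled_blosum(a: str, b: str) -> float:
    """BLOSUM-62 substitution score scaled to [0, 1].

    ``s(a, b) = max(0, B62(a, b)) / min(B62(a, a), B62(b, b))`` clamped to
    [0, 1]; identities score 1 for the 20 standard residues and anything
    involving 'X' scores 0.
    """
    return float(_B62_SCALED[_aa_index(a), _aa_index(b)])


def _seq_indices(seq: str) -> np.ndarray:
    return np.array([_aa_index(a) for a in seq], dtype=int)


# ---------------------------------------------------------------------------
# Distance matrices and dyads
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Per-pocket N×N×3 symmetric distance matrix (channels ca, cb, cn)."""

    pocket_id: str
    n: int
    d: np.ndarray  # (n, n, 3)


def build_distance_matrix(pocket: Pocket) -> DistanceMatrix:
    n = pocket.n
    d = np.empty((n, n, len(CHANNELS)))
    for c, channel in enumerate(CHANNELS):
        pts = pocket.coords(channel)
        d[:, :, c] = cdist(pts, pts)
    return DistanceMatrix(pocket.pocket_id, n, d)


def count_ktuple_permutations(n: int, k: int) -> int:
    """Number of ordered k-tuples of distinct residues from n (n·(n−1)·…)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    return math.perm(n, k) if k <= n else 0


def dyad_compatible(t1, t2, tol: float = DEFAULT_TOL) -> bool:
    """True when two dyad distance triplets agree to an RMSD below ``tol``."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    return bool(np.sqrt(np.mean((t1 - t2) ** 2)) < tol)


# ---------------------------------------------------------------------------
# Seed generation: clique growth in the correspondence graph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeedAlignment:
    """A mutually consistent set of residue correspondences."""

    pairs: tuple[tuple[int, int], ...]
    blosum_score: float = 0.0

    @property
    def score_len(self) -> int:
        return len(self.pairs)


def correspondence_graph(D1: DistanceMatrix, D2: DistanceMatrix,
                         tol: float = DEFAULT_TOL):
    """Adjacency and dyad-RMSD matrices of the correspondence graph.

    Node ``v = i * n2 + j`` stands for matching residue i of pocket 1
    with residue j of pocket 2.  An edge joins two nodes when their dyad
    distance triplets agree to an RMSD below ``tol`` and the mapping stays
    injective (distinct i and distinct j).
    """
    n1, n2 = D1.n, D2.n
    diff = D1.d[:, None, :, None, :] - D2.d[None, :, None, :, :]
    rms = np.sqrt(np.mean(diff ** 2, axis=-1)).reshape(n1 * n2, n1 * n2)
    i_of = np.repeat(np.arange(n1), n2)
    j_of = np.tile(np.arange(n2), n1)
    adj = (rms < tol) \
        & (i_of[:, None] != i_of[None, :]) \
        & (j_of[:, None] != j_of[None, :])
    np.fill_diagonal(adj, False)
    return adj, rms, i_of, j_of


def generate_seeds(D1: DistanceMatrix, D2: DistanceMatrix,
                   tol: float = DEFAULT_TOL,
                   max_seeds: int = DEFAULT_MAX_SEEDS,
                   aa1: str | None = None, aa2: str | None = None,
                   max_expansions: int = DEFAULT_MAX_EXPANSIONS,
                   sort_order: str = "best_first") -> list[SeedAlignment]:
    """Grow seed alignments as cliques of the correspondence graph.

    The search is a best-first depth-first traversal: candidates are
    ordered by increasing summed dyad RMSD to the current clique; a
    candidate that breaks clique consistency is dropped into the visited
    set (backtracking) and growth continues until no unvisited consistent
    candidate remains.  Branches that cannot reach the best length found
    so far are pruned, and the whole search is capped by a node budget so
    large pockets stay tractable.  Seeds are ranked by decreasing length,
    ties by raw BLOSUM-62 sum of the mapped pairs, then lexicographically.

    ``sort_order`` controls the candidate ordering during growth:
    ``"best_first"`` (default) visits candidates by increasing dyad RMSD
    to the current clique — the greedy-optimal order; ``"paper"`` visits
    them in decreasing order of distance difference instead.

    Returns an empty list when no compatible dyad exists at all.
    """
    if sort_order not in ("best_first", "paper"):
        raise ValueError(f"unknown sort order {sort_order!r}")
    sign = 1.0 if sort_order == "best_first" else -1.0
    adj, rms, i_of, j_of = correspondence_graph(D1, D2, tol)
    if not adj.any():
        return []

    nv = adj.shape[0]
    found: dict[tuple, None] = {}
    best = [2]
    budget = [max_expansions]

    def record(clique: list[int]):
        if len(clique) < 2:
            return
        if len(clique) > best[0]:
            best[0] = len(clique)
        if len(clique) >= best[0]:
            found[tuple(sorted(clique))] = None

    def expand(clique: list[int], cand_mask: np.ndarray, wsum: np.ndarray):
        if budget[0] <= 0:
            record(clique)
            return
        budget[0] -= 1
        cand = np.flatnonzero(cand_mask)
        if cand.size == 0:
            record(clique)
            return
        if len(clique) + cand.size < best[0]:
            return
        order = cand[np.lexsort((cand, sign * wsum[cand]))]
        live = cand_mask.copy()
        for v in order:
            if budget[0] <= 0:
                break
            if not live[v]:
                continue
            expand(clique + [v], live & adj[v], wsum + rms[v])
            live[v] = False  # visited: never re-enter this branch
            if len(clique) + int(live.sum()) < best[0]:
                break

    expand([], np.ones(nv, dtype=bool), np.zeros(nv))

    aa_raw = None
    if aa1 is not None and aa2 is not None:
        s1, s2 = _seq_indices(aa1), _seq_indices(aa2)

        def aa_raw(v):
            return _B62_RAW[s1[i_of[v]], s2[j_of[v]]]

    seeds = []
    for clique in found:
        pairs = tuple(sorted((int(i_of[v]), int(j_of[v])) for v in clique))
        blosum = float(sum(aa_raw(v) for v in clique)) if aa_raw else 0.0
        seeds.append(SeedAlignment(pairs, blosum))
    seeds.sort(key=lambda s: (-s.score_len, -s.blosum_score, s.pairs))
    return seeds[:max_seeds]


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(points_a, points_b):
    """Least-squares rigid superposition of ``points_b`` onto ``points_a``.

    Returns ``(rotation, translation, rmsd)`` with the proper rotation
    (det = +1; the reflection branch is corrected) and translation such
    that ``rotation @ b + translation`` best matches ``a``.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if a.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 paired points")
    ca0, cb0 = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca0, b - cb0
    for pts in (a0, b0):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-6 * max(1.0, s[0]):
            raise DegenerateGeometryError(
                "degenerate (collinear or coincident) point configuration")
    with warnings.catch_warnings():
        # near-planar point sets trip scipy's ill-conditioning warning even
        # though the rank check above already rejects true degeneracy
        warnings.simplefilter("ignore", UserWarning)
        rot, rssd = Rotation.align_vectors(a0, b0)
    rotation = rot.as_matrix()
    translation = ca0 - rotation @ cb0
    rmsd = float(rssd) / math.sqrt(a.shape[0])
    return rotation, translation, rmsd


# ---------------------------------------------------------------------------
# Full pairwise alignment
# ---------------------------------------------------------------------------

@dataclass
class PairwiseAlignment:
    """Final residue correspondence between two pockets plus scores.

    ``pairs`` maps residue indices of ``pocket_a`` onto ``pocket_b``;
    ``rotation``/``translation`` place ``pocket_b`` coordinates into the
    frame of ``pocket_a``.  ``rmsd`` is over matched Cα after the final
    superposition (NaN when no alignment exists).
    """

    pocket_a: str
    pocket_b: str
    n_a: int
    n_b: int
    pairs: tuple[tuple[int, int], ...]
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    m_dist_min: float
    m_dist_max: float
    m_seq: float

    @property
    def matches(self) -> int:
        return len(self.pairs)


def _three_point_stack(pocket: Pocket, indices) -> np.ndarray:
    out = []
    for idx in indices:
        r = pocket.residues[idx]
        out.extend([r.ca, r.cb, r.cn])
    return np.asarray(out)


def _empty_alignment(p1: Pocket, p2: Pocket) -> PairwiseAlignment:
    return PairwiseAlignment(p1.pocket_id, p2.pocket_id, p1.n, p2.n, (),
                             np.eye(3), np.zeros(3), float("nan"),
                             0.0, 0.0, 0.0)


def align_pair(P1: Pocket, P2: Pocket,
               tol: float = DEFAULT_TOL,
               ext_cutoff: float = DEFAULT_EXT_CUTOFF,
               max_seeds: int = DEFAULT_MAX_SEEDS,
               max_expansions: int = DEFAULT_MAX_EXPANSIONS,
               sort_order: str = "best_first") -> PairwiseAlignment:
    """Optimal pairwise alignment of two pockets.

    The top-ranked seeds are each superposed (Kabsch, all three points of
    every seed pair), extended by greedy mutual-nearest-neighbour matching
    of unmatched residues whose post-superposition Cα–Cα distance is below
    ``ext_cutoff``, re-superposed on the extended set and re-extended until
    the correspondence stops growing, and scored by (match count, then
    scaled-BLOSUM sum).  The best candidate wins.  Seeds of fewer than
    three residues determine the rotation too poorly to support extension,
    so they are scored as-is.

    The computation is carried out in a canonical pocket order so that the
    three scores are exactly symmetric in the argument order.
    """
    swap = (P2.pocket_id, P2.n) < (P1.pocket_id, P1.n)
    A, B = (P2, P1) if swap else (P1, P2)

    DA, DB = build_distance_matrix(A), build_distance_matrix(B)
    seeds = generate_seeds(DA, DB, tol=tol, max_seeds=max_seeds,
                           aa1=A.sequence, aa2=B.sequence,
                           max_expansions=max_expansions,
                           sort_order=sort_order)
    a_ca, b_ca = A.coords("ca"), B.coords("ca")
    sa, sb = _seq_indices(A.sequence), _seq_indices(B.sequence)

    best = None  # (matches, seq_sum, -seed_rank, pairs, rot, trans, rmsd)
    for rank, seed in enumerate(seeds):
        idx_a = [i for i, _ in seed.pairs]
        idx_b = [j for _, j in seed.pairs]
        try:
            rot, trans, _ = kabsch_superpose(_three_point_stack(A, idx_a),
                                             _three_point_stack(B, idx_b))
        except DegenerateGeometryError:
            continue
        seed_pairs = sorted(seed.pairs)
        seed_frame = (rot, trans)
        pairs = list(seed_pairs)
        if len(seed_pairs) >= MIN_EXT_SEED:
            # Alternate extension and re-superposition until the
            # correspondence is stable (ICP-style refinement).  The seed
            # pairs stay locked; every other residue is re-matched from
            # scratch each round, so an early mis-pairing can be dropped
            # once the frame improves.
            seed_a = {i for i, _ in seed_pairs}
            seed_b = {j for _, j in seed_pairs}
            free_a = sorted(set(range(A.n)) - seed_a)
            free_b = sorted(set(range(B.n)) - seed_b)
            # Coarse-to-fine: settle the frame at a looser radius first so
            # the final matching is not biased by the initial seed subset.
            for cutoff in (2.0 * ext_cutoff, ext_cutoff):
                seen = set()
                for _ in range(50):
                    moved = b_ca @ rot.T + trans
                    added = []
                    if free_a and free_b:
                        dmat = cdist(a_ca[free_a], moved[free_b])
                        while dmat.size:
                            flat = int(np.argmin(dmat))
                            r, c = divmod(flat, dmat.shape[1])
                            if dmat[r, c] >= cutoff:
                                break
                            added.append((free_a[r], free_b[c]))
                            dmat[r, :] = np.inf
                            dmat[:, c] = np.inf
                    pairs = sorted(seed_pairs + added)
                    key = tuple(pairs)
                    if key in seen:
                        break
                    seen.add(key)
                    try:
                        rot, trans, _ = kabsch_superpose(
                            _three_point_stack(A, [i for i, _ in pairs]),
                            _three_point_stack(B, [j for _, j in pairs]))
                    except DegenerateGeometryError:
                        break
            if len(pairs) < math.ceil(EXT_ACCEPT_FRACTION * min(A.n, B.n)):
                pairs = list(seed_pairs)  # majority coverage not reached
                rot, trans = seed_frame

        idx_a = [i for i, _ in pairs]
        idx_b = [j for _, j in pairs]
        moved = b_ca[idx_b] @ rot.T + trans
        rmsd = float(np.sqrt(np.mean(np.sum((a_ca[idx_a] - moved) ** 2, axis=1))))
        seq_sum = float(_B62_SCALED[sa[idx_a], sb[idx_b]].sum())

        key = (len(pairs), seq_sum, -rank)
        if best is None or key > best[0]:
            best = (key, tuple(pairs), rot, trans, rmsd, seq_sum)

    if best is None:
        return _empty_alignment(P1, P2)

    _, pairs, rot, trans, rmsd, seq_sum = best
    matches = len(pairs)
    m_dist_max = matches / max(A.n, B.n)
    m_dist_min = matches / min(A.n, B.n)
    m_seq = seq_sum / matches if matches else 0.0

    if swap:
        pairs = tuple(sorted((j, i) for i, j in pairs))
        rot, trans = rot.T, -(rot.T @ trans)
    return PairwiseAlignment(P1.pocket_id, P2.pocket_id, P1.n, P2.n,
                             tuple(pairs), rot, trans, rmsd,
                             m_dist_min, m_dist_max, m_seq)
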