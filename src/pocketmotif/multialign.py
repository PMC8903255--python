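"""All-vs-all comparison, similarity network, clustering and the star
multiple site alignment.

The workflow mirrors the published procedure for multiple binding
sites: every pocket pair is scored, pockets become nodes of a network
whose edges carry ``m_dist_max`` (kept when ≥ 0.4), densely connected
complexes are found by an MCODE-style procedure, the highest
weighted-degree member of each cluster becomes its representative, and
all members are pairwise-aligned onto the representative to give a
multiple alignment summarised as a consensus profile.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import pairwise
from .parallel import parallel_map
from .pockets import Pocket, STANDARD_AA1

log = logging.getLogger("pocketmotif")

__all__ = [
    "SimilarityNetwork",
    "Cluster",
    "ProfileColumn",
    "ConsensusProfile",
    "all_vs_all",
    "build_network",
    "cluster_network",
    "select_representative",
    "build_profile",
]

DEFAULT_THRESHOLD = 0.4       # m_dist_max cut for a network edge
DEFAULT_NODE_SCORE_CUTOFF = 0.2  # MCODE expansion cutoff

SCORE_COLUMNS = ["pocket_a", "pocket_b", "n_a", "n_b", "matches", "rmsd",
                 "m_dist_min", "m_dist_max", "m_seq", "error"]


# ---------------------------------------------------------------------------
# All-vs-all scoring
# ---------------------------------------------------------------------------

_WORK: dict = {}


def _init_worker(pockets, params, compare):
    _WORK["pockets"] = pockets
    _WORK["params"] = params
    _WORK["compare"] = compare


def _run_pair(task):
    ia, ib = task
    pockets = _WORK["pockets"]
    compare = _WORK["compare"]
    pa, pb = pockets[ia], pockets[ib]
    if compare is not None:
        return compare(pa, pb)
    aln = pairwise.align_pair(pa, pb, **_WORK["params"])
    return {"matches": aln.matches, "rmsd": aln.rmsd,
            "m_dist_min": aln.m_dist_min, "m_dist_max": aln.m_dist_max,
            "m_seq": aln.m_seq}


def all_vs_all(pockets: list[Pocket], compare=None, workers: int = 1,
               **align_params) -> pd.DataFrame:
    """Score table over all ordered pocket pairs, self pairs included.

    For N pockets the table has exactly N² records (the enumeration
    convention of the published pair counts); each unordered pair is
    computed once and mirrored.  A failing pair is recorded with an error
    flag instead of aborting the run.  The output is sorted and therefore
    independent of the worker count.
    """
    if len(pockets) < 1:
        raise ValueError("need at least one pocket")
    ids = [p.pocket_id for p in pockets]
    if len(set(ids)) != len(ids):
        raise ValueError("pocket ids must be unique")

    tasks = [(ia, ib) for ia in range(len(pockets))
             for ib in range(ia, len(pockets))]
    results = parallel_map(_run_pair, tasks, workers=workers,
                           initializer=_init_worker,
                           initargs=(pockets, align_params, compare))

    rows = []
    for (ia, ib), res in zip(tasks, results):
        pa, pb = pockets[ia], pockets[ib]
        if res.ok:
            rec = res.value
            base = (rec["matches"], rec["rmsd"], rec["m_dist_min"],
                    rec["m_dist_max"], rec["m_seq"], "")
        else:
            base = (0, float("nan"), float("nan"), float("nan"),
                    float("nan"), res.error)
        rows.append((pa.pocket_id, pb.pocket_id, pa.n, pb.n) + base)
        if ia != ib:
            rows.append((pb.pocket_id, pa.pocket_id, pb.n, pa.n) + base)
    table = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    return (table.sort_values(["pocket_a", "pocket_b"])
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# Similarity network
# ---------------------------------------------------------------------------

@dataclass
class SimilarityNetwork:
    """Undirected pocket-similarity network (edge weight = m_dist_max)."""

    graph: nx.Graph
    threshold: float

    @property
    def nodes(self):
        return sorted(self.graph.nodes)

    def edges(self):
        return sorted((min(a, b), max(a, b), d["weight"])
                      for a, b, d in self.graph.edges(data=True))


def build_network(scores: pd.DataFrame,
                  threshold: float = DEFAULT_THRESHOLD) -> SimilarityNetwork:
    """Similarity network from a full score table.

    An edge joins two distinct pockets when their ``m_dist_max`` reaches
    the threshold.  The score table must be symmetric to 1e-6.
    """
    valid = scores[scores["error"].astype(str) == ""]
    lookup = {(a, b): m for a, b, m in
              zip(valid["pocket_a"], valid["pocket_b"], valid["m_dist_max"])}
    for (a, b), m in lookup.items():
        rev = lookup.get((b, a))
        if rev is not None and abs(m - rev) > 1e-6:
            raise ValueError(
                f"asymmetric score table: m_dist_max({a},{b})={m} vs "
                f"m_dist_max({b},{a})={rev}")

    g = nx.Graph()
    g.add_nodes_from(pd.unique(scores[["pocket_a", "pocket_b"]].values.ravel()))
    for (a, b), m in lookup.items():
        if a < b and np.isfinite(m) and m >= threshold:
            g.add_edge(a, b, weight=float(m))
    return SimilarityNetwork(g, threshold)


# ---------------------------------------------------------------------------
# MCODE-style clustering
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    members: tuple[str, ...]
    representative: str

    @property
    def size(self) -> int:
        return len(self.members)


def _vertex_weights(g: nx.Graph) -> dict:
    """MCODE vertex weighting: core-clustering coefficient × highest
    k-core number of the closed neighbourhood."""
    weights = {}
    for v in g.nodes:
        nbhd = list(g[v]) + [v]
        sub = g.subgraph(nbhd)
        if sub.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        k = max(nx.core_number(sub).values())
        kcore = nx.k_core(sub, k)
        weights[v] = float(nx.density(kcore) * k)
    return weights


def cluster_network(net: SimilarityNetwork,
                    node_score_cutoff: float = DEFAULT_NODE_SCORE_CUTOFF,
                    haircut: bool = True) -> list[Cluster]:
    """Find densely connected complexes, MCODE-style.

    Complexes are seeded from the highest-weighted unseen vertex and
    expanded to neighbours whose weight is within ``node_score_cutoff`` of
    the seed weight; the haircut removes singly connected members.  Every
    pocket not retained in a complex becomes its own trivial cluster, so
    the output is a partition refining the connected components.
    """
    g = net.graph
    weights = _vertex_weights(g)
    seen: set = set()
    complexes: list[list[str]] = []
    for seed in sorted(g.nodes, key=lambda v: (-weights[v], v)):
        if seed in seen:
            continue
        floor = (1.0 - node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        seen.add(seed)
        while frontier:
            v = frontier.pop(0)
            for u in sorted(g[v]):
                if u not in seen and weights[u] >= floor:
                    seen.add(u)
                    members.add(u)
                    frontier.append(u)
        complexes.append(sorted(members))

    clusters: list[Cluster] = []
    leftovers: list[str] = []
    for members in complexes:
        if haircut and len(members) > 1:
            sub = g.subgraph(members)
            kept = [v for v in members if sub.degree(v) >= 2]
            leftovers.extend(v for v in members if v not in kept)
            members = kept
        if len(members) >= 2:
            clusters.append(Cluster(tuple(sorted(members)),
                                    select_representative(members, net)))
        else:
            leftovers.extend(members)
    for v in sorted(leftovers):
        clusters.append(Cluster((v,), v))
    clusters.sort(key=lambda c: (-c.size, c.members))
    return clusters


def select_representative(members, net: SimilarityNetwork) -> str:
    """Member with the highest weighted degree inside the cluster
    (ties: lexicographically smallest id)."""
    members = sorted(members)
    g = net.graph
    mset = set(members)

    def wdeg(v):
        return sum(d["weight"] for _, u, d in g.edges(v, data=True)
                   if u in mset)

    return min(members, key=lambda v: (-wdeg(v), v))


# ---------------------------------------------------------------------------
# Star multiple alignment → consensus profile
# ---------------------------------------------------------------------------

@dataclass
class ProfileColumn:
    """One column of the consensus profile (one representative residue)."""

    index: int
    chain: str
    resseq: int
    icode: str
    rep_aa: str
    occupancy: float
    counts: dict            # amino acid -> integer count over members
    mean_ca: list           # mean Cα of the column in the representative frame
    member_map: dict        # member id -> (chain, resseq, icode, aa) or None


@dataclass
class ConsensusProfile:
    """Star multiple alignment of a cluster, column per representative residue."""

    cluster_id: str
    representative: str
    members: tuple[str, ...]
    columns: list[ProfileColumn]

    @property
    def n_members(self) -> int:
        return len(self.members)

    def to_json(self) -> str:
        payload = {
            "cluster_id": self.cluster_id,
            "representative": self.representative,
            "members": list(self.members),
            "columns": [{
                "index": c.index, "chain": c.chain, "resseq": c.resseq,
                "icode": c.icode, "rep_aa": c.rep_aa,
                "occupancy": c.occupancy, "counts": c.counts,
                "mean_ca": [float(x) for x in c.mean_ca],
                "member_map": {m: (list(v) if v is not None else None)
                               for m, v in c.member_map.items()},
            } for c in self.columns],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ConsensusProfile":
        data = json.loads(text)
        columns = [ProfileColumn(
            c["index"], c["chain"], c["resseq"], c["icode"], c["rep_aa"],
            c["occupancy"], c["counts"], c["mean_ca"],
            {m: (tuple(v) if v is not None else None)
             for m, v in c["member_map"].items()},
        ) for c in data["columns"]]
        return cls(data["cluster_id"], data["representative"],
                   tuple(data["members"]), columns)

    def frequency_table(self) -> pd.DataFrame:
        """Columns × 20 amino-acid count matrix (logo input)."""
        rows = []
        for c in self.columns:
            rows.append([c.counts.get(aa, 0) for aa in STANDARD_AA1])
        idx = [f"{c.chain}{c.resseq}{c.icode}" for c in self.columns]
        return pd.DataFrame(rows, index=idx, columns=list(STANDARD_AA1))


def build_profile(cluster: Cluster, pockets: dict[str, Pocket],
                  cluster_id: str | None = None,
                  **align_params) -> ConsensusProfile:
    """Align every member onto the representative and tabulate columns.

    Requires at least three members (smaller clusters carry too little
    signal for consensus).  A member that fails to align contributes gaps
    everywhere and is logged.
    """
    if cluster.size < 3:
        raise ValueError("profiles require clusters of at least 3 members")
    rep = pockets[cluster.representative]
    members = tuple(sorted(cluster.members))
    columns = []
    maps: dict[str, dict[int, tuple]] = {}
    cas: dict[str, dict[int, np.ndarray]] = {}

    for mid in members:
        pocket = pockets[mid]
        if mid == cluster.representative:
            maps[mid] = {i: r for i, r in enumerate(pocket.residues)}
            cas[mid] = {i: r.ca for i, r in enumerate(pocket.residues)}
            continue
        aln = pairwise.align_pair(rep, pocket, **align_params)
        if not aln.pairs:
            log.warning("cluster %s: member %s does not align to "
                        "representative %s; all gaps",
                        cluster_id or "?", mid, cluster.representative)
            maps[mid] = {}
            cas[mid] = {}
            continue
        maps[mid] = {i: pocket.residues[j] for i, j in aln.pairs}
        moved = pocket.coords("ca") @ aln.rotation.T + aln.translation
        cas[mid] = {i: moved[j] for i, j in aln.pairs}

    for i, res in enumerate(rep.residues):
        counts: Counter = Counter()
        member_map = {}
        ca_points = []
        for mid in members:
            hit = maps[mid].get(i)
            if hit is None:
                member_map[mid] = None
            else:
                member_map[mid] = (hit.id.chain, hit.id.resseq,
                                   hit.id.icode, hit.id.aa)
                counts[hit.id.aa] += 1
                ca_points.append(cas[mid][i])
        occupied = sum(counts.values())
        mean_ca = (np.mean(ca_points, axis=0) if ca_points
                   else np.asarray(res.ca))
        columns.append(ProfileColumn(
            i, res.id.chain, res.id.resseq, res.id.icode, res.id.aa,
            occupied / len(members), dict(sorted(counts.items())),
            [float(x) for x in mean_ca], member_map))
    return ConsensusProfile(cluster_id or cluster.representative,
                            cluster.representative, members, columns)
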