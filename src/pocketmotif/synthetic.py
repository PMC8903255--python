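"""Synthetic pockets and sensitivity analyses.

Real binding sites are 5–30 residues sampled from a roughly globular
shell around the ligand, with all pairwise Cα distances above ~3.5 Å
(steric exclusion) and a pocket diameter of a few tens of Å.  The
generator emulates exactly that: Cα positions are rejection-sampled
inside a sphere with a minimum-separation constraint, Cβ is placed at
the ideal 1.53 Å bond length in a random direction and the side-chain
centroid 0.5–2.5 Å beyond Cβ, with the glycine/alanine identities of
the three-point representation respected.

Two perturbation modes mirror the sensitivity analyses of the aligner:

* position mode: every residue is displaced rigidly (all three points
  together) along a random direction, with displacements rescaled so the
  realized Cα RMSD to the original pocket equals the requested magnitude
  exactly;
* type mode: a chosen fraction of residues is mutated to a uniformly
  random *different* amino acid, leaving every Cα untouched.

``generate_motif_universe`` builds a small universe of pocket clusters
sharing planted conserved cores, used to exercise the full multiple-
alignment → motif pipeline with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pockets import Pocket, PocketError, Residue3P, ResidueId, STANDARD_AA1
from . import pairwise

__all__ = [
    "PerturbationSpec",
    "generate_synthetic_pocket",
    "perturb_positions",
    "perturb_types",
    "run_sensitivity",
    "generate_motif_universe",
    "MIN_CA_SEPARATION",
]

MIN_CA_SEPARATION = 3.5  # Å, steric lower bound on Cα–Cα distances
_CB_BOND = 1.53


@dataclass
class PerturbationSpec:
    """One sensitivity run: which knob to turn, how far, how often."""

    mode: str  # "position" or "type"
    magnitudes: tuple[float, ...]
    seed: int = 0
    replicates: int = 100

    def __post_init__(self):
        if self.mode not in ("position", "type"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        self.magnitudes = tuple(float(m) for m in self.magnitudes)
        for m in self.magnitudes:
            if self.mode == "position" and not (0.0 <= m <= 14.0):
                raise ValueError("position magnitudes must be in [0, 14] Å")
            if self.mode == "type" and not (0.0 <= m <= 1.0):
                raise ValueError("mutation fractions must be in [0, 1]")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _side_points(ca: np.ndarray, aa: str, rng: np.random.Generator):
    """Cβ and centroid for a synthetic residue of type ``aa``."""
    if aa == "G":
        return ca.copy(), ca.copy()
    cb = ca + _CB_BOND * _random_unit(rng)
    if aa == "A":
        return cb, cb.copy()
    direction = _random_unit(rng)
    if np.dot(direction, cb - ca) < 0:  # centroid points away from the backbone
        direction = -direction
    cn = cb + rng.uniform(0.5, 2.5) * direction
    return cb, cn


def _sample_ca_positions(n: int, rng: np.random.Generator, diameter: float,
                         existing: np.ndarray | None = None,
                         max_attempts_per_point: int = 2000) -> np.ndarray:
    radius = diameter / 2.0
    points = [] if existing is None else [p for p in existing]
    placed = []
    for _ in range(n):
        for attempt in range(max_attempts_per_point):
            p = rng.uniform(-radius, radius, size=3)
            if np.linalg.norm(p) > radius:
                continue
            if points and min(np.linalg.norm(p - q) for q in points) < MIN_CA_SEPARATION:
                continue
            points.append(p)
            placed.append(p)
            break
        else:
            raise PocketError(
                f"could not place {n} residues at >= {MIN_CA_SEPARATION} Å "
                f"separation inside a {diameter} Å sphere; try a larger diameter")
    return np.asarray(placed)


def generate_synthetic_pocket(n: int, seed, diameter: float = 20.0,
                              pocket_id: str | None = None,
                              resseqs=None, types=None) -> Pocket:
    """Deterministically generate a synthetic pocket of ``n`` residues.

    Residue types are uniform over the 20 standard amino acids unless
    ``types`` is given; residues are numbered 1..n on chain A unless
    ``resseqs`` is given.
    """
    if not (3 <= n <= 50):
        raise PocketError("synthetic pockets support 3 to 50 residues")
    rng = np.random.default_rng(seed)
    cas = _sample_ca_positions(n, rng, diameter)
    if types is None:
        types = [STANDARD_AA1[k] for k in rng.integers(0, 20, size=n)]
    if resseqs is None:
        resseqs = list(range(1, n + 1))
    if pocket_id is None:
        pocket_id = f"synth-{seed}-n{n}"
    residues = []
    for k in range(n):
        aa = types[k]
        cb, cn = _side_points(cas[k], aa, rng)
        rid = ResidueId(pocket_id, "A", int(resseqs[k]), "", aa)
        residues.append(Residue3P(rid, cas[k], cb, cn))
    return Pocket(pocket_id, residues, source=f"synthetic seed={seed}")


def perturb_positions(pocket: Pocket, target_rmsd: float, seed,
                      n_move: int | None = None) -> Pocket:
    """Displace residues rigidly so the Cα RMSD to the original is exact.

    Each selected residue (all of them by default) is moved along its own
    uniformly random direction; all displacements share one magnitude and
    are rescaled so the realized Cα RMSD equals ``target_rmsd`` to within
    numerical precision.  Residue types are unchanged.
    """
    if target_rmsd < 0:
        raise ValueError("target RMSD must be >= 0")
    new_id = f"{pocket.pocket_id}|pos{target_rmsd:g}"
    if target_rmsd == 0:
        return pocket.with_id(new_id)
    rng = np.random.default_rng(seed)
    n = pocket.n
    k = n if n_move is None else max(1, min(n, int(n_move)))
    chosen = rng.choice(n, size=k, replace=False)
    deltas = np.zeros((n, 3))
    for idx in chosen:
        deltas[idx] = _random_unit(rng)
    realized = np.sqrt(np.mean(np.sum(deltas ** 2, axis=1)))
    deltas *= target_rmsd / realized
    residues = [r.moved(d) for r, d in zip(pocket.residues, deltas)]
    return Pocket(new_id, residues, pocket.ligand_id, pocket.source)


def perturb_types(pocket: Pocket, fraction: float, seed) -> Pocket:
    """Mutate a fraction of residues to random different types.

    Cα coordinates are never touched; Cβ and the centroid are rebuilt only
    when the mutation crosses the glycine/alanine special cases of the
    three-point representation (e.g. a new glycine collapses onto Cα).
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("mutation fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = pocket.n
    k = int(round(fraction * n))
    new_id = f"{pocket.pocket_id}|mut{fraction:g}"
    if k == 0:
        return pocket.with_id(new_id)
    chosen = set(int(i) for i in rng.choice(n, size=k, replace=False))
    residues = []
    for idx, res in enumerate(pocket.residues):
        if idx not in chosen:
            residues.append(res)
            continue
        old = res.id.aa
        options = [a for a in STANDARD_AA1 if a != old]
        new = options[int(rng.integers(0, len(options)))]
        rid = ResidueId(res.id.structure_id, res.id.chain, res.id.resseq,
                        res.id.icode, new)
        ca, cb, cn = res.ca, res.cb, res.cn
        if new == "G":
            cb = cn = ca
        elif old == "G":
            cb, cn = _side_points(ca, new, rng)
        elif new == "A":
            cn = cb
        elif old == "A":
            direction = _random_unit(rng)
            if np.dot(direction, cb - ca) < 0:
                direction = -direction
            cn = cb + rng.uniform(0.5, 2.5) * direction
        residues.append(Residue3P(rid, ca, cb, cn))
    return Pocket(new_id, residues, pocket.ligand_id, pocket.source)


def run_sensitivity(base: Pocket, spec: PerturbationSpec,
                    **align_params) -> pd.DataFrame:
    """Perturb → align → score, for every magnitude × replicate.

    Returns a table with one row per replicate: magnitude, replicate,
    the three alignment scores and the realized Cα RMSD of the
    perturbation (before alignment, residue-for-residue).
    """
    rows = []
    for mi, mag in enumerate(spec.magnitudes):
        for rep in range(spec.replicates):
            sub_seed = [spec.seed, mi, rep]
            if spec.mode == "position":
                pert = perturb_positions(base, mag, sub_seed)
            else:
                pert = perturb_types(base, mag, sub_seed)
            realized = float(np.sqrt(np.mean(
                np.sum((base.coords("ca") - pert.coords("ca")) ** 2, axis=1))))
            aln = pairwise.align_pair(base, pert, **align_params)
            rows.append({"mode": spec.mode, "magnitude": mag, "replicate": rep,
                         "m_dist_min": aln.m_dist_min,
                         "m_dist_max": aln.m_dist_max,
                         "m_seq": aln.m_seq,
                         "realized_rmsd": realized})
    return (pd.DataFrame(rows)
            .sort_values(["magnitude", "replicate"])
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# Planted-motif universe
# ---------------------------------------------------------------------------

@dataclass
class MotifUniverse:
    """Synthetic pocket clusters with planted conserved cores."""

    pockets: list[Pocket]
    clusters: dict[str, list[str]]           # cluster name -> member ids
    cores: dict[str, dict]                   # cluster name -> planted core info
    decoys: list[str] = field(default_factory=list)


def generate_motif_universe(seed, n_clusters: int = 3, members: int = 5,
                            pocket_size: int = 20,
                            core_positions: tuple[int, ...] = (2, 3, 4, 9, 10,
                                                               11, 15, 16, 17),
                            n_decoys: int = 0,
                            core_jitter: float = 0.15,
                            diameter: float = 28.0) -> MotifUniverse:
    """Build clusters of pockets that share a conserved spatial core.

    Each cluster derives from its own base pocket.  Members keep the core
    residues (types fixed, positions jittered by ``core_jitter`` Å) while
    every non-core residue is re-typed at random and relocated to a fresh
    position, so only the core aligns across members.  Decoy pockets share
    the size statistics but no planted structure.  The defaults put the
    planted core fraction (9/20) above the 0.4 network threshold while the
    density is kept low enough (20 residues across a 28 Å site) that
    unrelated pockets stay below it, so the planted partition is the
    unique well-posed ground truth.
    """
    rng = np.random.default_rng(seed)
    pockets: list[Pocket] = []
    clusters: dict[str, list[str]] = {}
    cores: dict[str, dict] = {}

    for c in range(n_clusters):
        name = f"cluster{c}"
        base = generate_synthetic_pocket(
            pocket_size, seed=[seed, c], diameter=diameter,
            pocket_id=f"{name}_base")
        core_idx = sorted(core_positions)
        core_res = [base.residues[i] for i in core_idx]
        cores[name] = {
            "resseqs": [r.id.resseq for r in core_res],
            "types": [r.id.aa for r in core_res],
            "anchors": np.array([r.ca for r in core_res]),
        }
        member_ids = []
        for m in range(members):
            mid = f"{name}_m{m}"
            residues = []
            placed = []
            for i in core_idx:
                res = base.residues[i]
                jitter = rng.normal(scale=core_jitter, size=3)
                residues.append(Residue3P(
                    ResidueId(mid, "A", res.id.resseq, "", res.id.aa),
                    res.ca + jitter, res.cb + jitter, res.cn + jitter))
                placed.append(res.ca + jitter)
            for i in range(pocket_size):
                if i in core_idx:
                    continue
                res = base.residues[i]
                pos = _sample_ca_positions(1, rng, diameter,
                                           existing=np.asarray(placed))[0]
                placed.append(pos)
                aa = STANDARD_AA1[int(rng.integers(0, 20))]
                cb, cn = _side_points(pos, aa, rng)
                residues.append(Residue3P(
                    ResidueId(mid, "A", res.id.resseq, "", aa), pos, cb, cn))
            pockets.append(Pocket(mid, residues, source=f"planted {name}"))
            member_ids.append(mid)
        clusters[name] = member_ids

    decoys = []
    for d in range(n_decoys):
        did = f"decoy{d}"
        pockets.append(generate_synthetic_pocket(
            pocket_size, seed=[seed, 10_000 + d], diameter=diameter,
            pocket_id=did))
        decoys.append(did)
    return MotifUniverse(pockets, clusters, cores, decoys)
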