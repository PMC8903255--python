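"""PROSITE-style structural motifs with 3D anchors.

A motif is an ordered pattern of allowed-residue sets separated by fixed
or variable sequence gaps, e.g. ``[CS]-P-[FNWY]`` or
``[KQRTN]-[IV]-P-x(9,25)-[QED]-S``.  Unlike a sequence pattern, every
residue-set element also carries a 3D anchor (the mean Cα of its profile
column in the representative frame), so a motif can be scanned against a
pocket jointly on residue identity, sequence separation and geometry.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pockets import Pocket, STANDARD_AA1
from .pairwise import kabsch_superpose, DegenerateGeometryError
from .multialign import ConsensusProfile

log = logging.getLogger("pocketmotif")

__all__ = [
    "ResidueSet",
    "Gap",
    "Motif",
    "MotifParseError",
    "ScanMatch",
    "derive_motif",
    "motif_to_string",
    "parse_motif",
    "scan_motif",
    "export_logo_matrix",
]

DEFAULT_OCC_THRESHOLD = 0.7
DEFAULT_AA_FREQ_THRESHOLD = 0.1
DEFAULT_MAX_GAP = 30
DEFAULT_GEOM_TOL = 1.5  # Å, Cα RMSD of a scan hit onto the anchors


class MotifParseError(ValueError):
    """Malformed motif string."""


@dataclass(frozen=True)
class ResidueSet:
    """One conserved position: allowed amino acids plus its 3D anchor."""

    aas: tuple[str, ...]
    anchor: tuple[float, float, float] | None = None
    occupancy: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "aas", tuple(sorted(set(self.aas))))
        if not self.aas or any(a not in STANDARD_AA1 + "X" for a in self.aas):
            raise ValueError(f"invalid residue set {self.aas!r}")


@dataclass(frozen=True)
class Gap:
    """Variable sequence gap: between ``min`` and ``max`` skipped residues."""

    min: int
    max: int

    def __post_init__(self):
        if not (0 <= self.min <= self.max):
            raise ValueError(f"invalid gap bounds ({self.min}, {self.max})")


@dataclass(frozen=True)
class Motif:
    elements: tuple
    source_cluster: str = ""

    def __post_init__(self):
        elems = tuple(self.elements)
        object.__setattr__(self, "elements", elems)
        if not elems:
            raise ValueError("motif has no elements")
        if isinstance(elems[0], Gap) or isinstance(elems[-1], Gap):
            raise ValueError("motif must start and end with a residue set")
        for a, b in zip(elems, elems[1:]):
            if isinstance(a, Gap) and isinstance(b, Gap):
                raise ValueError("motif has consecutive gaps")

    @property
    def residue_sets(self) -> list[ResidueSet]:
        return [e for e in self.elements if isinstance(e, ResidueSet)]

    @property
    def has_geometry(self) -> bool:
        return all(e.anchor is not None for e in self.residue_sets)

    def anchors(self) -> np.ndarray:
        return np.array([e.anchor for e in self.residue_sets], dtype=float)

    def __str__(self):
        return motif_to_string(self)


# ---------------------------------------------------------------------------
# Derivation from a consensus profile
# ---------------------------------------------------------------------------

def derive_motif(profile: ConsensusProfile,
                 occ_threshold: float = DEFAULT_OCC_THRESHOLD,
                 aa_freq_threshold: float = DEFAULT_AA_FREQ_THRESHOLD,
                 max_gap: int = DEFAULT_MAX_GAP) -> list[Motif]:
    """Derive structural motifs from a consensus profile.

    Profile columns occupied by at least ``occ_threshold`` of the members
    become motif positions; each position allows the amino acids seen in
    at least ``aa_freq_threshold`` of its occupying members.  Consecutive
    positions separated in sequence yield variable gaps ``x(kmin,kmax)``
    from the range of separations observed across members; a separation
    beyond ``max_gap`` in every member splits the motif into
    sequence-discontinuous parts.  Returns an empty list when no column
    is conserved enough.
    """
    if profile.n_members < 3:
        raise ValueError("motif derivation requires a profile of >= 3 members")
    cols = [c for c in profile.columns if c.occupancy >= occ_threshold]
    if not cols:
        return []

    def residue_set(col):
        occupied = sum(col.counts.values())
        aas = [aa for aa, cnt in col.counts.items()
               if cnt / occupied >= aa_freq_threshold]
        if not aas:  # extremely fragmented column: keep the modal residue
            aas = [max(col.counts, key=lambda a: (col.counts[a], a))]
        return ResidueSet(tuple(aas), tuple(col.mean_ca), col.occupancy)

    def separations(col_a, col_b):
        out = []
        for mid in profile.members:
            pa, pb = col_a.member_map.get(mid), col_b.member_map.get(mid)
            if pa is None or pb is None or pa[0] != pb[0]:
                continue
            out.append(max(0, abs(pb[1] - pa[1]) - 1))
        return out

    motifs: list[Motif] = []
    elements: list = [residue_set(cols[0])]
    for prev, col in zip(cols, cols[1:]):
        seps = separations(prev, col) or [max(0, col.resseq - prev.resseq - 1)]
        kmin, kmax = min(seps), max(seps)
        if kmin > max_gap or prev.chain != col.chain:
            motifs.append(Motif(tuple(elements), profile.cluster_id))
            elements = [residue_set(col)]
            continue
        if kmax > 0:
            elements.append(Gap(kmin, kmax))
        elements.append(residue_set(col))
    motifs.append(Motif(tuple(elements), profile.cluster_id))
    return motifs


# ---------------------------------------------------------------------------
# String grammar
# ---------------------------------------------------------------------------

_SET_RE = re.compile(r"^[A-Z]$|^\[([A-Z]+)\]$")
_GAP_RE = re.compile(r"^[xX]\((\d+)(?:,(\d+))?\)$")


def motif_to_string(motif: Motif) -> str:
    """Render a motif in the bracketed grammar, e.g. ``[CS]-P-x(9,25)-F``."""
    parts = []
    for e in motif.elements:
        if isinstance(e, Gap):
            parts.append(f"x({e.min})" if e.min == e.max
                         else f"x({e.min},{e.max})")
        else:
            parts.append(e.aas[0] if len(e.aas) == 1
                         else "[" + "".join(e.aas) + "]")
    return "-".join(parts)


def parse_motif(text: str, source_cluster: str = "") -> Motif:
    """Parse a motif string into a geometry-free :class:`Motif`.

    The grammar: elements joined by '-', single letters or bracketed sets
    for positions, ``x(m)`` / ``x(m,n)`` for gaps (case-insensitive x).
    Raises :class:`MotifParseError` naming the offending position.
    """
    elements: list = []
    pos = 0
    tokens = text.strip().split("-")
    for k, token in enumerate(tokens):
        token = token.strip()
        gap = _GAP_RE.match(token)
        if gap:
            lo = int(gap.group(1))
            hi = int(gap.group(2)) if gap.group(2) is not None else lo
            try:
                elements.append(Gap(lo, hi))
            except ValueError as exc:
                raise MotifParseError(
                    f"element {k + 1} at position {pos}: {exc}") from exc
        elif _SET_RE.match(token):
            aas = token.strip("[]")
            try:
                elements.append(ResidueSet(tuple(aas)))
            except ValueError as exc:
                raise MotifParseError(
                    f"element {k + 1} at position {pos}: {exc}") from exc
        else:
            raise MotifParseError(
                f"element {k + 1} at position {pos}: cannot parse {token!r}")
        pos += len(token) + 1
    try:
        return Motif(tuple(elements), source_cluster)
    except ValueError as exc:
        raise MotifParseError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

@dataclass
class ScanMatch:
    """A motif occurrence in a pocket."""

    pocket_id: str
    residue_indices: tuple[int, ...]
    residue_labels: tuple[str, ...]
    rmsd: float | None  # None in sequence-only mode


def _gap_bounds(motif: Motif) -> list[tuple[int, int]]:
    """Allowed residue-separation range before each residue set (first: None)."""
    bounds = []
    pending: Gap | None = None
    for e in motif.elements:
        if isinstance(e, Gap):
            pending = e
            continue
        bounds.append(None if not bounds and pending is None
                      else ((pending.min, pending.max) if pending else (0, 0)))
        pending = None
    bounds[0] = None
    return bounds


def scan_motif(motif: Motif, pocket: Pocket,
               geom_tol: float = DEFAULT_GEOM_TOL,
               max_nodes: int = 200_000) -> ScanMatch | None:
    """Search a pocket for an occurrence of the motif.

    Structural mode (motif has anchors and ≥ 3 positions): an injective,
    sequence-ordered assignment of pocket residues to the motif positions
    must match on residue type, satisfy every gap's separation range, and
    superpose its Cα set onto the anchors with RMSD ≤ ``geom_tol``; the
    minimum-RMSD assignment is returned.  With fewer than three anchored
    positions the geometry is under-determined and matching falls back to
    sequence-only mode, which returns the first valid assignment.
    """
    sets = motif.residue_sets
    bounds = _gap_bounds(motif)
    structural = motif.has_geometry and len(sets) >= 3
    anchors = motif.anchors() if structural else None
    residues = pocket.residues

    best: tuple[float, tuple[int, ...]] | None = None
    first: tuple[int, ...] | None = None
    budget = [max_nodes]

    def feasible(prev_idx: int, idx: int, bound) -> bool:
        a, b = residues[prev_idx].id, residues[idx].id
        if a.chain != b.chain or b.resseq <= a.resseq:
            return False
        sep = b.resseq - a.resseq - 1
        return bound[0] <= sep <= bound[1]

    def search(level: int, chosen: list[int]):
        nonlocal best, first
        if budget[0] <= 0 or (first is not None and not structural):
            return
        if level == len(sets):
            if not structural:
                first = tuple(chosen)
                return
            try:
                _, _, rmsd = kabsch_superpose(
                    anchors, np.array([residues[i].ca for i in chosen]))
            except DegenerateGeometryError:
                return
            if rmsd <= geom_tol and (best is None or rmsd < best[0]):
                best = (rmsd, tuple(chosen))
            return
        for idx in range(len(residues)):
            if budget[0] <= 0:
                return
            budget[0] -= 1
            if idx in chosen:
                continue
            if residues[idx].id.aa not in sets[level].aas:
                continue
            if level > 0 and not feasible(chosen[-1], idx, bounds[level]):
                continue
            search(level + 1, chosen + [idx])

    search(0, [])

    hit = None
    if structural and best is not None:
        hit = (best[1], best[0])
    elif not structural and first is not None:
        hit = (first, None)
    if hit is None:
        return None
    indices, rmsd = hit
    labels = tuple(residues[i].id.label() for i in indices)
    return ScanMatch(pocket.pocket_id, indices, labels, rmsd)


# ---------------------------------------------------------------------------
# Logo export
# ---------------------------------------------------------------------------

def export_logo_matrix(profile: ConsensusProfile, path) -> pd.DataFrame:
    """Write the columns × 20 position-frequency matrix as TSV.

    Both integer counts and member-normalised frequencies are written, in
    a layout any logo renderer can consume; the count rows sum to
    occupancy × member count per column.
    """
    counts = profile.frequency_table()
    freqs = counts / profile.n_members
    counts = counts.add_suffix("_count")
    freqs = freqs.add_suffix("_freq")
    table = pd.concat([counts, freqs], axis=1)
    table.insert(0, "occupancy", [c.occupancy for c in profile.columns])
    table.index.name = "position"
    table.to_csv(path, sep="\t")
    return table


def motifs_to_json(motifs: list[Motif], params: dict | None = None) -> str:
    """Serialise motifs (with anchors and provenance) to the JSON schema."""
    payload = {"motifs": [], "params": params or {}}
    for m in motifs:
        elements = []
        for e in m.elements:
            if isinstance(e, Gap):
                elements.append({"type": "gap", "min": e.min, "max": e.max})
            else:
                elements.append({"type": "set", "aas": "".join(e.aas),
                                 "anchor": (list(e.anchor)
                                            if e.anchor is not None else None),
                                 "occupancy": e.occupancy})
        payload["motifs"].append({"pattern": motif_to_string(m),
                                  "source_cluster": m.source_cluster,
                                  "elements": elements})
    return json.dumps(payload, indent=1)


def motifs_from_json(text: str) -> list[Motif]:
    data = json.loads(text)
    out = []
    for rec in data["motifs"]:
        elements = []
        for e in rec["elements"]:
            if e["type"] == "gap":
                elements.append(Gap(e["min"], e["max"]))
            else:
                anchor = tuple(e["anchor"]) if e.get("anchor") else None
                elements.append(ResidueSet(tuple(e["aas"]), anchor,
                                           e.get("occupancy", 1.0)))
        out.append(Motif(tuple(elements), rec.get("source_cluster", "")))
    return out
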