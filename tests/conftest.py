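"""Shared fixtures: hand-written PDB text and synthetic pockets.

All structure fixtures are generated programmatically at test time; no
binary or downloaded data is used anywhere in the suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from pocketmotif.synthetic import generate_synthetic_pocket


def pdb_atom(record, serial, name, resname, chain, resseq, xyz,
             occ=1.0, b=0.0, elem=None, altloc=" ", icode=" ") -> str:
    elem = elem or name.strip()[0]
    return (f"{record:<6s}{serial:5d} {name.center(4)}{altloc}{resname:>3s} "
            f"{chain}{resseq:4d}{icode}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{b:6.2f}"
            f"          {elem:>2s}")


def make_ala(serial, chain, resseq, ca, direction=(1.0, 0.0, 0.0)) -> list[str]:
    """ATOM records for one alanine whose CA sits at ``ca``.

    When ``direction`` points away from a reference point, every other
    atom of the residue lies at least as far from it as the CA, so the CA
    distance controls inclusion in a distance-cutoff scan.
    """
    ca = np.asarray(ca, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    perp = np.array([-d[1], d[0], 0.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.array([0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    n = ca + 1.46 * perp
    c = ca - 1.52 * perp
    o = c + 1.23 * d
    cb = ca + 1.53 * d
    lines = []
    for k, (name, xyz) in enumerate(
            [("N", n), ("CA", ca), ("C", c), ("O", o), ("CB", cb)]):
        lines.append(pdb_atom("ATOM", serial + k, name, "ALA", chain,
                              resseq, xyz))
    return lines


@pytest.fixture
def six_residue_site(tmp_path):
    """Structure with one ligand atom at the origin and six alanines whose
    nearest atoms sit at known distances: exactly four are within 4.5 Å."""
    # nearest atom of each residue is its CA (other atoms point away)
    distances = [2.0, 3.0, 4.0, 4.4, 4.6, 8.0]
    lines = []
    serial = 1
    for i, dist in enumerate(distances):
        direction = np.zeros(3)
        direction[i % 3] = 1.0 if i % 2 == 0 else -1.0
        ca = direction * dist
        lines += make_ala(serial, "A", i + 1, ca, direction)
        serial += 5
    lines.append(pdb_atom("HETATM", serial, "C1", "LIG", "A", 100,
                          (0.0, 0.0, 0.0)))
    lines.append("END")
    path = tmp_path / "site.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path, distances


@pytest.fixture
def pocket20():
    return generate_synthetic_pocket(20, seed=11)


@pytest.fixture
def small_pocket():
    return generate_synthetic_pocket(6, seed=2)
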