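"""Pocket model: parsing policies, site extraction, three-point residues."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from pocketmotif.pockets import (Pocket, PocketError, Residue3P, ResidueId,
                                 extract_binding_site, load_structure,
                                 read_pocket_file, three_point_representation,
                                 write_pocket_file)
from pocketmotif.synthetic import generate_synthetic_pocket

from conftest import make_ala, pdb_atom


# ---------------------------------------------------------------------------
# load_structure
# ---------------------------------------------------------------------------

def test_minimal_structure_parses_with_correct_coordinates(tmp_path):
    lines = []
    for i, x in enumerate([0.0, 5.0, 10.0]):
        lines += make_ala(1 + 5 * i, "A", i + 1, (x, 0.0, 0.0))
    path = tmp_path / "three.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    handle = load_structure(path)
    residues = list(handle.model.get_residues())
    assert len(residues) == 3
    np.testing.assert_allclose(residues[1]["CA"].get_coord(), [5.0, 0.0, 0.0],
                               atol=1e-3)


def test_only_first_model_is_used(tmp_path):
    body1 = "\n".join(make_ala(1, "A", 1, (0, 0, 0))
                      + make_ala(6, "A", 2, (5, 0, 0))
                      + make_ala(11, "A", 3, (10, 0, 0)))
    body2 = "\n".join(make_ala(1, "A", 1, (99, 0, 0))
                      + make_ala(6, "A", 2, (99, 5, 0))
                      + make_ala(11, "A", 3, (99, 10, 0)))
    path = tmp_path / "models.pdb"
    path.write_text(f"MODEL        1\n{body1}\nENDMDL\n"
                    f"MODEL        2\n{body2}\nENDMDL\nEND\n")
    handle = load_structure(path)
    coords = np.array([a.get_coord() for a in handle.model.get_atoms()])
    assert coords[:, 0].max() < 20  # model 2 atoms (x=99) are absent


def test_altloc_keeps_highest_occupancy_conformer(tmp_path):
    lines = make_ala(1, "A", 1, (0, 0, 0)) + make_ala(6, "A", 2, (5, 0, 0))
    # third residue with a disordered CA: A at occ 0.6, B at occ 0.4
    lines += [
        pdb_atom("ATOM", 11, "N", "ALA", "A", 3, (9.0, 0, 0)),
        pdb_atom("ATOM", 12, "CA", "ALA", "A", 3, (10.0, 0, 0),
                 occ=0.6, altloc="A"),
        pdb_atom("ATOM", 13, "CA", "ALA", "A", 3, (20.0, 0, 0),
                 occ=0.4, altloc="B"),
        pdb_atom("ATOM", 14, "C", "ALA", "A", 3, (11.5, 0, 0)),
        pdb_atom("ATOM", 15, "O", "ALA", "A", 3, (11.5, 1.2, 0)),
        pdb_atom("ATOM", 16, "CB", "ALA", "A", 3, (10.0, 1.5, 0)),
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    handle = load_structure(path)
    res3 = list(handle.model.get_residues())[2]
    assert res3["CA"].get_coord()[0] == pytest.approx(10.0, abs=1e-3)


@pytest.mark.parametrize("content", ["", "this is not a structure\n"])
def test_unparseable_or_empty_file_raises_naming_the_file(tmp_path, content):
    path = tmp_path / "bad.pdb"
    path.write_text(content)
    with pytest.raises(PocketError, match="bad.pdb"):
        load_structure(path)


# ---------------------------------------------------------------------------
# extract_binding_site
# ---------------------------------------------------------------------------

def test_extraction_respects_the_distance_cutoff(six_residue_site):
    path, distances = six_residue_site
    handle = load_structure(path)
    pocket = extract_binding_site(handle, ("LIG", "A", 100), cutoff=4.5)
    assert pocket.n == 4  # 2.0, 3.0, 4.0 and 4.4 Å in; 4.6 and 8.0 out
    assert [r.id.resseq for r in pocket.residues] == [1, 2, 3, 4]


def test_extraction_is_monotone_in_cutoff(six_residue_site):
    path, _ = six_residue_site
    handle = load_structure(path)
    tight = extract_binding_site(handle, ("LIG", "A", 100), cutoff=4.5)
    loose = extract_binding_site(handle, ("LIG", "A", 100), cutoff=5.0)
    tight_ids = {r.id.sort_key for r in tight.residues}
    loose_ids = {r.id.sort_key for r in loose.residues}
    assert tight_ids <= loose_ids


def test_every_extracted_residue_verifiably_touches_the_ligand(six_residue_site):
    path, distances = six_residue_site
    handle = load_structure(path)
    pocket = extract_binding_site(handle, ("LIG", "A", 100), cutoff=4.5)
    # independent re-scan: nearest CA distance to the ligand at the origin
    for res in pocket.residues:
        assert distances[res.id.resseq - 1] <= 4.5


def test_missing_ligand_error_lists_available_groups(six_residue_site):
    path, _ = six_residue_site
    handle = load_structure(path)
    with pytest.raises(PocketError, match="LIG:A:100"):
        extract_binding_site(handle, ("ATP", "A", 1))


def test_no_residue_in_range_is_an_empty_site_error(tmp_path):
    lines = []
    for i in range(3):
        lines += make_ala(1 + 5 * i, "A", i + 1, (50.0 + 5 * i, 0, 0))
    lines.append(pdb_atom("HETATM", 99, "C1", "LIG", "A", 9, (0, 0, 0)))
    path = tmp_path / "far.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    with pytest.raises(PocketError, match="empty site"):
        extract_binding_site(load_structure(path), ("LIG", "A", 9))


# ---------------------------------------------------------------------------
# three_point_representation
# ---------------------------------------------------------------------------

def _build_residue(resname, atoms, chain="A", resseq=1):
    """Assemble a Bio.PDB residue in memory (no file round trip)."""
    from Bio.PDB.StructureBuilder import StructureBuilder

    sb = StructureBuilder()
    sb.init_structure("mem")
    sb.init_model(0)
    sb.init_chain(chain)
    sb.init_seg("    ")
    sb.init_residue(resname, " ", resseq, " ")
    for k, (name, coord) in enumerate(atoms.items()):
        sb.init_atom(name, np.asarray(coord, dtype=float), 0.0, 1.0, " ",
                     name.center(4), k + 1, element=name.strip()[0])
    return list(sb.get_structure().get_residues())[0]


def test_glycine_collapses_all_points_onto_ca():
    res = _build_residue("GLY", {"N": (0, 1.4, 0), "CA": (1, 2, 3),
                                 "C": (2.2, 2, 3), "O": (2.2, 3.2, 3)})
    r3p = three_point_representation(res, "s")
    np.testing.assert_array_equal(r3p.cb, r3p.ca)
    np.testing.assert_array_equal(r3p.cn, r3p.ca)
    assert r3p.id.aa == "G"


def test_alanine_centroid_is_its_cbeta():
    res = _build_residue("ALA", {"N": (-1.4, 0, 0), "CA": (0, 0, 0),
                                 "C": (1.5, 0, 0), "O": (1.5, 1.2, 0),
                                 "CB": (0, 0, 1)})
    r3p = three_point_representation(res, "s")
    np.testing.assert_array_equal(r3p.cn, r3p.cb)
    np.testing.assert_allclose(r3p.cb, [0, 0, 1])


def test_side_chain_centroid_is_unweighted_mean_including_cbeta():
    res = _build_residue("SER", {"N": (-1.4, 0, 0), "CA": (0.4, 0.9, 0),
                                 "C": (1.5, 0, 0), "O": (1.5, 1.2, 0),
                                 "CB": (0, 0, 0), "OG": (0, 0, 2)})
    r3p = three_point_representation(res, "s")
    np.testing.assert_allclose(r3p.cn, [0, 0, 1])


def test_missing_cbeta_is_reconstructed_at_ideal_geometry():
    res = _build_residue("LYS", {"N": (-1.458, 0, 0), "CA": (0, 0, 0),
                                 "C": (0.55, 1.42, 0), "O": (0.55, 2.6, 0)})
    r3p = three_point_representation(res, "s")
    bond = np.linalg.norm(r3p.cb - r3p.ca)
    assert 1.4 < bond <= 2.0
    assert np.linalg.norm(r3p.cn - r3p.cb) < 1e-9  # no side chain -> cn = cb


def test_residue_without_ca_is_skipped_with_warning(caplog):
    res = _build_residue("ALA", {"N": (0, 0, 0), "C": (1.5, 0, 0)})
    with caplog.at_level("WARNING", logger="pocketmotif"):
        assert three_point_representation(res, "s") is None
    assert "no Cα" in caplog.text or "no C" in caplog.text


def test_representation_is_rigid_motion_equivariant():
    atoms = {"N": (-1.4, 0.2, 0), "CA": (0, 0, 0), "C": (1.5, 0.1, 0),
             "O": (1.6, 1.3, 0), "CB": (-0.3, -0.9, 1.1),
             "OG": (0.2, -0.5, 2.4)}
    rot = Rotation.from_euler("xyz", [0.4, -1.1, 2.2]).as_matrix()
    shift = np.array([3.0, -7.0, 11.0])
    moved = {k: rot @ np.asarray(v, float) + shift for k, v in atoms.items()}
    a = three_point_representation(_build_residue("SER", atoms), "s")
    b = three_point_representation(_build_residue("SER", moved), "s")
    for channel in ("ca", "cb", "cn"):
        np.testing.assert_allclose(
            rot @ getattr(a, channel) + shift, getattr(b, channel),
            atol=1e-9)


# ---------------------------------------------------------------------------
# Residue3P / Pocket invariants
# ---------------------------------------------------------------------------

def test_pocket_rejects_fewer_than_three_residues():
    r = generate_synthetic_pocket(5, seed=0).residues
    with pytest.raises(PocketError, match="at least 3"):
        Pocket("tiny", r[:2])


def test_pocket_orders_residues_and_rejects_duplicates():
    res = generate_synthetic_pocket(5, seed=0).residues
    shuffled = [res[3], res[0], res[4], res[1], res[2]]
    p = Pocket("p", shuffled)
    assert [r.id.resseq for r in p.residues] == [1, 2, 3, 4, 5]
    with pytest.raises(PocketError, match="duplicate"):
        Pocket("dup", [res[0], res[0], res[1]])


def test_implausible_ca_cb_bond_is_rejected():
    rid = ResidueId("s", "A", 1, "", "L")
    with pytest.raises(PocketError, match="Cα–Cβ"):
        Residue3P(rid, np.zeros(3), np.array([3.0, 0, 0]),
                  np.array([3.0, 0, 0]))


# ---------------------------------------------------------------------------
# Pocket files
# ---------------------------------------------------------------------------

def test_pocket_file_round_trip_preserves_ids_and_coordinates(tmp_path):
    pocket = generate_synthetic_pocket(5, seed=9, pocket_id="demo")
    path = tmp_path / "demo.pdb"
    write_pocket_file(pocket, path)
    back = read_pocket_file(path)
    assert back.pocket_id == "demo"
    assert [r.id.sort_key for r in back.residues] == \
        [r.id.sort_key for r in pocket.residues]
    assert back.sequence == pocket.sequence
    for a, b in zip(pocket.residues, back.residues):
        for ch in ("ca", "cb", "cn"):
            np.testing.assert_allclose(getattr(a, ch), getattr(b, ch),
                                       atol=5e-4)


def test_pocket_file_with_two_residues_is_rejected(tmp_path):
    lines = ["REMARK 900 POCKET_ID twomer"]
    lines += make_ala(1, "A", 1, (0, 0, 0))
    lines += make_ala(6, "A", 2, (5, 0, 0))
    path = tmp_path / "two.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    with pytest.raises(PocketError, match="at least 3"):
        read_pocket_file(path)


def test_insertion_codes_keep_their_sorted_order(tmp_path):
    base = generate_synthetic_pocket(4, seed=3).residues
    res = [Residue3P(ResidueId("s", "A", 10, icode, r.id.aa),
                     r.ca, r.cb, r.cn)
           for icode, r in zip(["", "A", "B"], base[:3])]
    res.append(Residue3P(ResidueId("s", "A", 11, "", base[3].id.aa),
                         base[3].ca, base[3].cb, base[3].cn))
    pocket = Pocket("icodes", res)
    path = tmp_path / "icodes.pdb"
    write_pocket_file(pocket, path)
    back = read_pocket_file(path)
    assert [r.id.sort_key for r in back.residues] == \
        [("A", 10, ""), ("A", 10, "A"), ("A", 10, "B"), ("A", 11, "")]
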