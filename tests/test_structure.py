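"""Structure analytics: parsing, disulfides, Ca site, heme, cavities,
charge patches, Matthews coefficient, and rigid-motion invariance."""

import numpy as np
import pandas as pd
import pytest

from peroxikit.structure import (
    CrystalForm,
    NoIonError,
    StructureModel,
    StructureParseError,
    _COLUMNS,
    apply_rigid_transform,
    calcium_coordination,
    cavity_volume,
    charge_patches,
    detect_covalent_links,
    find_disulfides,
    heme_geometry,
    matthews_solvent,
    parse_structure,
    random_rotation,
    write_pdb,
)
from peroxikit.synthetic import SyntheticSpec, make_toy_structure


def _model_from_rows(rows):
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return StructureModel(df)


def _atom(record, name, resname, chain, resnum, x, y, z, element, occ=1.0,
          altloc=""):
    return (record, 0, name, altloc, resname, chain, resnum, "", x, y, z, occ,
            20.0, element)


@pytest.fixture
def toy_full():
    spec = SyntheticSpec(seed=7, n_disulfides=3, ca_site=True,
                         porphyrin={"dome": 0.1, "saddle": 0.2, "fe_oop": 0.25},
                         ester_link=True, n_exposed_lys=3)
    model, truth = make_toy_structure(spec)
    return model, truth


# ---------------------------------------------------------------------------
# parsing


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.697   7.152  -4.953  1.00  0.00           C
END
"""


def test_parse_minimal_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINIMAL_PDB)
    model = parse_structure(path)
    assert len(model) == 3
    assert model.atoms.loc[1, "name"] == "CA"
    assert model.atoms.loc[0, "x"] == pytest.approx(11.104)


def test_parse_malformed_record_names_line(tmp_path):
    path = tmp_path / "bad.pdb"
    path.write_text(MINIMAL_PDB.replace("11.639", "xx.xxx"))
    with pytest.raises(StructureParseError, match="line 2"):
        parse_structure(path)


def test_pdb_round_trip_preserves_coordinates(tmp_path, toy_full):
    model, _ = toy_full
    path = tmp_path / "toy.pdb"
    write_pdb(model, path)
    back = parse_structure(path)
    assert len(back) == len(model)
    np.testing.assert_allclose(back.coords, model.coords, atol=1e-3)


def test_parse_resolves_altloc_to_highest_occupancy(tmp_path):
    lines = [
        "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.40  0.00           N",
        "ATOM      2  N  BALA A   1       1.000   0.000   0.000  0.60  0.00           N",
        "END",
    ]
    path = tmp_path / "alt.pdb"
    path.write_text("\n".join(lines) + "\n")
    model = parse_structure(path)
    assert len(model) == 1
    assert model.atoms.iloc[0]["x"] == pytest.approx(1.0)


def test_toy_structure_atom_count_matches_truth(toy_full):
    model, truth = toy_full
    assert len(model) == truth["n_atoms"]


# ---------------------------------------------------------------------------
# disulfides


def test_planted_disulfides_detected(toy_full):
    model, truth = toy_full
    bonds, free = find_disulfides(model)
    assert len(bonds) == truth["n_disulfides"] == 3
    assert free == []
    for b in bonds:
        assert b.sg_distance == pytest.approx(truth["sg_distance"], abs=1e-6)


def test_no_cysteines_no_bonds():
    model = _model_from_rows([_atom("ATOM", "CA", "ALA", "A", 1, 0, 0, 0, "C")])
    bonds, free = find_disulfides(model)
    assert bonds == [] and free == []


def test_greedy_matching_no_double_use():
    # three SG in a row at 2.0 A spacing: only one bond, middle pairs with
    # nearest; each cysteine used at most once, leftover reported free
    rows = [_atom("ATOM", "SG", "CYS", "A", i + 1, 2.0 * i + (0.1 if i == 2 else 0),
                  0, 0, "S") for i in range(3)]
    bonds, free = find_disulfides(_model_from_rows(rows))
    assert len(bonds) == 1
    assert len(free) == 1
    used = {bonds[0].cys_a[1], bonds[0].cys_b[1]}
    assert free[0][1] not in used


# ---------------------------------------------------------------------------
# calcium


def test_ideal_pentagonal_bipyramid(toy_full):
    model, _ = toy_full
    site = calcium_coordination(model)
    assert site.coordination_number == 7
    assert site.geometry_label == "pentagonal-bipyramidal"
    assert all(d == pytest.approx(2.4, abs=1e-6)
               for *_, d in site.ligand_atoms)


def test_isolated_calcium_empty_shell():
    rows = [_atom("HETATM", "CA", "CA", "A", 1, 0, 0, 0, "CA"),
            _atom("ATOM", "O", "HOH", "B", 2, 10, 0, 0, "O")]
    site = calcium_coordination(_model_from_rows(rows))
    assert site.ligand_atoms == []


def test_no_calcium_raises():
    model = _model_from_rows([_atom("ATOM", "CA", "ALA", "A", 1, 0, 0, 0, "C")])
    with pytest.raises(NoIonError):
        calcium_coordination(model)


def test_octahedral_not_labelled_pbp():
    rows = [_atom("HETATM", "CA", "CA", "A", 1, 0, 0, 0, "CA")]
    n = 900
    for v in ([2.4, 0, 0], [-2.4, 0, 0], [0, 2.4, 0], [0, -2.4, 0],
              [0, 0, 2.4], [0, 0, -2.4], [1.7, 1.7, 0]):
        n += 1
        rows.append(_atom("HETATM", "O", "HOH", "B", n, *v, "O"))
    site = calcium_coordination(_model_from_rows(rows))
    assert site.coordination_number == 7
    assert site.geometry_label != "pentagonal-bipyramidal"


# ---------------------------------------------------------------------------
# heme geometry


def _porphyrin_model(dome=0.0, saddle=0.0, fe_oop=0.0):
    spec = SyntheticSpec(seed=0, porphyrin={"dome": dome, "saddle": saddle,
                                            "fe_oop": fe_oop})
    model, _ = make_toy_structure(spec)
    return model


def test_planar_porphyrin_zeros():
    geom = heme_geometry(_porphyrin_model(), proximal_his=474)
    assert geom.fe_oop == pytest.approx(0.0, abs=1e-9)
    assert geom.dome == pytest.approx(0.0, abs=1e-9)
    assert geom.saddle == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("dome,saddle,fe_oop", [
    (0.0, 0.0, 0.25),
    (0.1, 0.0, 0.0),
    (0.0, 0.2, 0.0),
    (0.12, 0.3, -0.15),
])
def test_planted_distortions_recovered(dome, saddle, fe_oop):
    geom = heme_geometry(_porphyrin_model(dome, saddle, fe_oop),
                         proximal_his=474)
    assert geom.fe_oop == pytest.approx(fe_oop, abs=1e-6)
    assert geom.dome == pytest.approx(dome, abs=1e-6)
    assert geom.saddle == pytest.approx(abs(saddle), abs=1e-6)


def test_missing_macrocycle_atoms_named():
    model = _porphyrin_model()
    pruned = StructureModel(model.atoms[model.atoms["name"] != "NB"]
                            .reset_index(drop=True))
    with pytest.raises(ValueError, match="NB"):
        heme_geometry(pruned, proximal_his=474)


def test_mean_plane_matches_eigen_oracle(rng):
    """The fitted plane minimizes squared deviations: compare against an
    independent eigen-decomposition of the covariance of perturbed ring
    atoms after a random rigid motion."""
    model = _porphyrin_model(0.05, 0.1, 0.2)
    jitter = model.atoms.copy()
    ring = jitter["resname"] == "HEM"
    jitter.loc[ring, ["x", "y", "z"]] += rng.normal(0, 0.02, (ring.sum(), 3))
    model = StructureModel(jitter)
    rot, trans = random_rotation(rng), rng.uniform(-30, 30, 3)
    moved = apply_rigid_transform(model, rot, trans)
    geom = heme_geometry(moved, proximal_his=474)

    from peroxikit.structure import MACROCYCLE_ATOMS
    heme = moved.select(resname="HEM")
    xyz = np.array([heme[heme["name"] == a][["x", "y", "z"]].to_numpy()[0]
                    for a in MACROCYCLE_ATOMS])
    centered = xyz - xyz.mean(axis=0)
    evals, evecs = np.linalg.eigh(centered.T @ centered)
    normal = evecs[:, 0]  # smallest eigenvalue -> plane normal
    assert abs(abs(normal @ geom.normal) - 1.0) < 1e-9


def test_heme_geometry_rigid_motion_invariant(rng):
    model = _porphyrin_model(0.1, 0.2, 0.25)
    geom0 = heme_geometry(model, proximal_his=474)
    for _ in range(3):
        moved = apply_rigid_transform(model, random_rotation(rng),
                                      rng.uniform(-50, 50, 3))
        geom = heme_geometry(moved, proximal_his=474)
        assert geom.fe_oop == pytest.approx(geom0.fe_oop, abs=1e-9)
        assert geom.dome == pytest.approx(geom0.dome, abs=1e-9)
        assert geom.saddle == pytest.approx(geom0.saddle, abs=1e-9)


def test_fe_oop_sign_flips_with_proximal_side():
    """Placing the reference histidine on the other side flips the sign."""
    model = _porphyrin_model(0.0, 0.0, 0.25)
    flipped = apply_rigid_transform(model, np.diag([1.0, -1.0, -1.0]), [0, 0, 0])
    geom = heme_geometry(model, proximal_his=474)
    geom_f = heme_geometry(flipped, proximal_his=474)
    assert geom_f.fe_oop == pytest.approx(geom.fe_oop, abs=1e-9)  # still toward His
    # without a proximal reference the convention makes fe_oop non-negative
    geom_n = heme_geometry(model)
    assert geom_n.fe_oop >= 0


# ---------------------------------------------------------------------------
# covalent links


def test_planted_ester_detected(toy_full):
    model, truth = toy_full
    links = detect_covalent_links(model)
    esters = [l for l in links if l.rule == "ester"]
    sulfonium = [l for l in links if l.rule == "sulfonium"]
    assert len(esters) == truth["heme"]["ester_links"] == 1
    assert esters[0].distance == pytest.approx(truth["heme"]["ester_distance"],
                                               abs=1e-6)
    assert sulfonium == []


def test_distant_carboxylate_not_linked():
    spec = SyntheticSpec(seed=0, porphyrin={"dome": 0, "saddle": 0, "fe_oop": 0},
                         ester_link=True, ester_distance=3.0)
    model, _ = make_toy_structure(spec)
    assert detect_covalent_links(model) == []


# ---------------------------------------------------------------------------
# cavity volume


def _spherical_shell(radius=6.4, spacing=1.0):
    n = int(4 * np.pi * radius ** 2 / spacing ** 2)
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    pts = radius * np.stack([np.sin(phi) * np.cos(theta),
                             np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)
    rows = [_atom("ATOM", "CA", "ALA", "A", i + 1, *p, "C")
            for i, p in enumerate(pts)]
    return _model_from_rows(rows)


def test_cavity_volume_of_analytic_sphere():
    """Closed shell enclosing an empty 5 A ball: volume within 10% of
    4/3 pi 5^3 = 523.6 A^3 at 0.5 A grid spacing."""
    model = _spherical_shell()
    result = cavity_volume(model, (0, 0, 0), grid_spacing=0.5, probe_radius=1.4)
    assert not result.open_pocket
    assert result.volume == pytest.approx(4 / 3 * np.pi * 125.0, rel=0.10)


def test_cavity_volume_grid_convergence():
    model = _spherical_shell()
    v1 = cavity_volume(model, (0, 0, 0), grid_spacing=0.5).volume
    v2 = cavity_volume(model, (0, 0, 0), grid_spacing=0.25).volume
    assert abs(v2 - v1) / v1 < 0.05


def test_open_pocket_flagged():
    rows = [_atom("ATOM", "CA", "ALA", "A", i + 1, x, y, z, "C")
            for i, (x, y, z) in enumerate(
                (x, y, z) for x in range(4) for y in range(4) for z in range(4))]
    model = _model_from_rows(rows)
    result = cavity_volume(model, (10.0, 10.0, 10.0), grid_spacing=0.5)
    assert result.open_pocket
    assert result.truncation_radius is not None


def test_cavity_seed_clash_raises():
    model = _spherical_shell()
    atom0 = model.coords[0]
    with pytest.raises(ValueError, match="clash"):
        cavity_volume(model, atom0 + 0.1)


def test_cavity_monotone_when_wall_removed():
    model = _spherical_shell()
    v_closed = cavity_volume(model, (0, 0, 0), grid_spacing=0.5).volume
    # removing wall atoms can only grow the reachable free region
    thinned = StructureModel(model.atoms.iloc[:-60].reset_index(drop=True))
    v_open = cavity_volume(thinned, (0, 0, 0), grid_spacing=0.5).volume
    assert v_open >= v_closed


# ---------------------------------------------------------------------------
# charge patches


def test_exposed_lysine_cluster_single_patch():
    spec = SyntheticSpec(seed=0, n_exposed_lys=3)
    model, _ = make_toy_structure(spec)
    patches = charge_patches(model, cluster_radius=8.0)
    positive = [p for p in patches if p.net_charge > 0]
    assert len(positive) == 1
    assert positive[0].net_charge == pytest.approx(3.0)
    assert len(positive[0].residues) == 3


def test_buried_charges_no_patch(rng):
    """A lysine fully enclosed in a carbon shell is not solvent-exposed."""
    rows = [_atom("ATOM", "NZ", "LYS", "A", 1, 0, 0, 0, "N"),
            _atom("ATOM", "CE", "LYS", "A", 1, 1.4, 0, 0, "C")]
    n = 1
    shell = _spherical_shell(radius=4.0, spacing=1.0)
    for _, r in shell.atoms.iterrows():
        n += 1
        rows.append(_atom("ATOM", "CA", "GLY", "B", n, r["x"], r["y"], r["z"], "C"))
    patches = charge_patches(_model_from_rows(rows))
    assert patches == []


def test_patch_inventory_rotation_invariant(rng):
    spec = SyntheticSpec(seed=0, n_exposed_lys=3)
    model, _ = make_toy_structure(spec)
    ref = [(p.net_charge, tuple(r[:2] for r in p.residues))
           for p in charge_patches(model)]
    moved = apply_rigid_transform(model, random_rotation(rng), [5.0, -3.0, 8.0])
    got = [(p.net_charge, tuple(r[:2] for r in p.residues))
           for p in charge_patches(moved)]
    assert got == ref


# ---------------------------------------------------------------------------
# Matthews coefficient


def test_matthews_direct_arithmetic():
    form = CrystalForm(100.0, 100.0, 100.0, space_group="P 1", z_per_cell=4)
    v_m, solvent = matthews_solvent(form, 10000.0)
    assert v_m == pytest.approx(25.0)
    assert solvent == pytest.approx(1 - 1.23 / 25.0, abs=1e-9)  # 95.08%


def test_matthews_vm_123_zero_solvent():
    form = CrystalForm(10.0, 10.0, 10.0, z_per_cell=1)
    with pytest.warns(UserWarning):
        v_m, solvent = matthews_solvent(form, 1000.0 / 1.23)
    assert v_m == pytest.approx(1.23)
    assert solvent == pytest.approx(0.0, abs=1e-9)


def test_matthews_monotonicity():
    base = CrystalForm(50.0, 60.0, 70.0, z_per_cell=4)
    bigger = CrystalForm(55.0, 60.0, 70.0, z_per_cell=4)
    v1, _ = matthews_solvent(base, 20000.0)
    v2, _ = matthews_solvent(bigger, 20000.0)
    v3, _ = matthews_solvent(base, 25000.0)
    assert v2 > v1 > v3


def test_space_group_multiplicity_inferred():
    form = CrystalForm(53.12, 85.56, 139.39, space_group="P 21 21 21",
                       mol_per_asu=1)
    assert form.z_per_cell == 4


# ---------------------------------------------------------------------------
# rigid-motion invariance of detection outputs


def test_detection_rigid_motion_invariant(rng, toy_full):
    model, _ = toy_full
    bonds0, free0 = find_disulfides(model)
    site0 = calcium_coordination(model)
    links0 = detect_covalent_links(model)
    for _ in range(2):
        moved = apply_rigid_transform(model, random_rotation(rng),
                                      rng.uniform(-100, 100, 3))
        bonds, free = find_disulfides(moved)
        assert {b.residue_pair for b in bonds} == {b.residue_pair for b in bonds0}
        assert free == free0
        site = calcium_coordination(moved)
        assert site.coordination_number == site0.coordination_number
        assert site.geometry_label == site0.geometry_label
        links = detect_covalent_links(moved)
        assert [(l.rule, l.residue) for l in links] == \
            [(l.rule, l.residue) for l in links0]
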