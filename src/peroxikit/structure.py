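"""Geometry analytics on atomic models of heme peroxidases.

Implements the structural half of the characterization pipeline: disulfide
detection, Ca2+ coordination geometry, heme mean-plane/distortion metrics
(iron out-of-plane displacement, doming, saddling), covalent heme-protein
link detection (ester and sulfonium rules), grid flood-fill cavity volumes,
surface charge-patch clustering, and Matthews-coefficient bookkeeping.

Coordinates are in angstroms, right-handed; residues use author numbering
(1-based, closed intervals). Parsing of PDB/mmCIF goes through Bio.PDB; the
in-memory model is a flat pandas table so every analysis below is plain
numpy geometry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .constants import (
    DEFAULT_VDW,
    MAX_ASA,
    NEGATIVE_RESIDUES,
    POSITIVE_RESIDUES,
    SPACE_GROUP_MULTIPLICITY,
    VDW_RADII,
)

__all__ = [
    "StructureModel",
    "DisulfideBond",
    "CoordinationSite",
    "HemeGeometry",
    "CovalentLink",
    "CavityResult",
    "ChargePatch",
    "CrystalForm",
    "parse_structure",
    "write_pdb",
    "find_disulfides",
    "calcium_coordination",
    "heme_geometry",
    "detect_covalent_links",
    "cavity_volume",
    "charge_patches",
    "matthews_solvent",
    "apply_rigid_transform",
    "random_rotation",
]

_COLUMNS = ["record", "serial", "name", "altloc", "resname", "chain", "resnum",
            "icode", "x", "y", "z", "occupancy", "bfactor", "element"]

#: the 24 atoms of the porphyrin macrocycle, in ring order A->B->C->D
MACROCYCLE_ATOMS = [
    "NA", "C1A", "C2A", "C3A", "C4A", "CHB",
    "NB", "C1B", "C2B", "C3B", "C4B", "CHC",
    "NC", "C1C", "C2C", "C3C", "C4C", "CHD",
    "ND", "C1D", "C2D", "C3D", "C4D", "CHA",
]
PYRROLE_N = ["NA", "NB", "NC", "ND"]
#: beta carbons around the ring with the saddle sign pattern (+,+,-,-,+,+,-,-)
BETA_CARBONS = ["C2A", "C3A", "C2B", "C3B", "C2C", "C3C", "C2D", "C3D"]
SADDLE_SIGNS = np.array([+1, +1, -1, -1, +1, +1, -1, -1], dtype=float)


class StructureParseError(ValueError):
    pass


@dataclass
class StructureModel:
    """A flat atomic model: one row per atom in ``atoms`` (pandas DataFrame).

    Columns: record, serial, name, altloc, resname, chain, resnum, icode,
    x, y, z, occupancy, bfactor, element. Altlocs are already resolved
    (highest occupancy wins) unless the model was built with them kept.
    """

    atoms: pd.DataFrame
    id: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"missing atom columns {missing}")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite coordinates")
        keys = self.atoms[["chain", "resnum", "icode", "name", "altloc"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise ValueError(f"duplicate atom key {tuple(dup)}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(float)

    def select(self, **criteria) -> pd.DataFrame:
        """Select atom rows by equality on any column, e.g. resname='CYS'."""
        mask = np.ones(len(self.atoms), dtype=bool)
        for col, value in criteria.items():
            series = self.atoms[col]
            if isinstance(value, (list, tuple, set, frozenset)):
                mask &= series.isin(list(value)).to_numpy()
            else:
                mask &= (series == value).to_numpy()
        return self.atoms[mask]

    def protein_atoms(self) -> pd.DataFrame:
        return self.atoms[self.atoms["record"] == "ATOM"]

    def with_coords(self, xyz: np.ndarray) -> "StructureModel":
        atoms = self.atoms.copy()
        atoms[["x", "y", "z"]] = np.asarray(xyz, float)
        return StructureModel(atoms, id=self.id)


def _resolve_altlocs(df: pd.DataFrame) -> pd.DataFrame:
    """Keep, per (chain, resnum, icode, name), the highest-occupancy altloc."""
    order = df.sort_values("occupancy", ascending=False, kind="stable")
    kept = order.drop_duplicates(subset=["chain", "resnum", "icode", "name"])
    kept = kept.sort_index().copy()
    kept["altloc"] = ""
    return kept.reset_index(drop=True)


def _prevalidate_pdb(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except (ValueError, IndexError) as exc:
                    raise StructureParseError(
                        f"{path}: malformed coordinate record at line {lineno}: "
                        f"{line.rstrip()!r}") from exc


def parse_structure(path, format: str | None = None, keep_altlocs: bool = False,
                    model_index: int = 0) -> StructureModel:
    """Load ATOM/HETATM records from a PDB or mmCIF file.

    The format is inferred from the extension unless given. Alternate
    locations are resolved to the highest-occupancy conformer by default.
    Malformed coordinate records raise ``StructureParseError`` naming the
    offending line.
    """
    from Bio.PDB import MMCIFParser, PDBParser

    path = str(path)
    if format is None:
        format = "mmcif" if path.endswith((".cif", ".mmcif")) else "pdb"
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"format must be 'pdb' or 'mmcif', got {format!r}")

    if format == "pdb":
        _prevalidate_pdb(path)
        parser = PDBParser(QUIET=True)
    else:
        parser = MMCIFParser(QUIET=True)
    try:
        structure = parser.get_structure("model", path)
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    rows = []
    model = list(structure)[model_index]
    for chain in model:
        for residue in chain:
            hetflag, resnum, icode = residue.id
            record = "ATOM" if hetflag == " " else "HETATM"
            for atom in residue.get_unpacked_list():
                element = (atom.element or "").strip().upper()
                rows.append((record, atom.serial_number, atom.get_name(),
                             (atom.get_altloc() or "").strip(), residue.get_resname(),
                             chain.id, resnum, icode.strip(),
                             float(atom.coord[0]), float(atom.coord[1]),
                             float(atom.coord[2]),
                             float(atom.get_occupancy() or 1.0),
                             float(atom.get_bfactor() or 0.0), element))
    if not rows:
        raise StructureParseError(f"no atoms found in {path}")
    df = pd.DataFrame(rows, columns=_COLUMNS)
    if not keep_altlocs:
        df = _resolve_altlocs(df)
    return StructureModel(df.reset_index(drop=True), id=path)


def write_pdb(model: StructureModel, path) -> None:
    """Write the model as legal fixed-column PDB ATOM/HETATM records."""
    with open(path, "w") as fh:
        for i, row in enumerate(model.atoms.itertuples(index=False), start=1):
            name = row.name if len(row.name) == 4 else f" {row.name:<3}"
            fh.write(
                f"{row.record:<6}{i:>5} {name}{(row.altloc or ' '):1}"
                f"{row.resname:>3} {row.chain:1}{int(row.resnum):>4}"
                f"{(row.icode or ' '):1}   "
                f"{row.x:8.3f}{row.y:8.3f}{row.z:8.3f}"
                f"{row.occupancy:6.2f}{row.bfactor:6.2f}          "
                f"{row.element:>2}\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Disulfides


@dataclass(frozen=True)
class DisulfideBond:
    cys_a: tuple[str, int]
    cys_b: tuple[str, int]
    sg_distance: float

    @property
    def residue_pair(self) -> frozenset:
        return frozenset((self.cys_a[1], self.cys_b[1]))


def find_disulfides(model: StructureModel, sg_cutoff: float = 2.5
                    ) -> tuple[list[DisulfideBond], list[tuple[str, int]]]:
    """Detect Cys-Cys bridges by greedy nearest-pair matching of Sgamma atoms.

    Sgamma pairs are matched closest-first under the cutoff, each cysteine
    used at most once; cysteines left over are returned as free.
    """
    if sg_cutoff <= 0:
        raise ValueError("sg_cutoff must be > 0")
    sg = model.select(resname="CYS", name="SG")
    ids = [(row.chain, int(row.resnum)) for row in sg.itertuples(index=False)]
    xyz = sg[["x", "y", "z"]].to_numpy(float)
    pairs = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            if d <= sg_cutoff:
                pairs.append((d, i, j))
    pairs.sort()
    used: set[int] = set()
    bonds = []
    for d, i, j in pairs:
        if i in used or j in used:
            continue
        used.update((i, j))
        bonds.append(DisulfideBond(ids[i], ids[j], d))
    free = [ids[k] for k in range(len(ids)) if k not in used]
    return bonds, free


# ---------------------------------------------------------------------------
# Calcium coordination


@dataclass(frozen=True)
class CoordinationSite:
    ion: tuple[str, int, str]
    ligand_atoms: list  # (chain, resnum, resname, atom name, distance)
    geometry_label: str

    @property
    def coordination_number(self) -> int:
        return len(self.ligand_atoms)

    @property
    def ligand_residues(self) -> set[tuple[str, int]]:
        return {(chain, resnum) for chain, resnum, *_ in self.ligand_atoms}


class NoIonError(ValueError):
    pass


def _pbp_label(ca_xyz: np.ndarray, ligand_xyz: np.ndarray, angle_tol: float = 15.0) -> str:
    """Classify a 7-coordinate site; pentagonal bipyramid needs a ~180 deg
    axial pair with the other five ligands ~90 deg off the axis."""
    n = len(ligand_xyz)
    if n != 7:
        return f"coordination-{n}"
    vecs = ligand_xyz - ca_xyz
    unit = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            ang = math.degrees(math.acos(np.clip(unit[i] @ unit[j], -1, 1)))
            if best is None or ang > best[0]:
                best = (ang, i, j)
    ang, i, j = best
    if ang < 180.0 - angle_tol:
        return "coordination-7"
    axis = unit[i] - unit[j]
    axis /= np.linalg.norm(axis)
    for k in range(n):
        if k in (i, j):
            continue
        off = abs(90.0 - math.degrees(math.acos(np.clip(unit[k] @ axis, -1, 1))))
        if off > angle_tol:
            return "coordination-7"
    return "pentagonal-bipyramidal"


def calcium_coordination(model: StructureModel, o_cutoff: float = 2.9,
                         angle_tol: float = 15.0) -> CoordinationSite:
    """Oxygen coordination shell of the (first) Ca2+ ion.

    All oxygen atoms (side chain, backbone, water) within the cutoff are
    listed as ligands. A 7-coordinate shell passing the axial/equatorial
    angle test (+-angle_tol degrees) is labelled pentagonal-bipyramidal.
    """
    ca = model.atoms[(model.atoms["element"] == "CA")
                     | (model.atoms["resname"] == "CA")]
    ca = ca[ca["record"] == "HETATM"]
    if len(ca) == 0:
        raise NoIonError("no Ca2+ ion in model")
    ion_row = ca.iloc[0]
    ion_xyz = ion_row[["x", "y", "z"]].to_numpy(float)

    oxy = model.atoms[(model.atoms["element"] == "O")
                      & ~((model.atoms["chain"] == ion_row["chain"])
                          & (model.atoms["resnum"] == ion_row["resnum"])
                          & (model.atoms["resname"] == ion_row["resname"]))]
    xyz = oxy[["x", "y", "z"]].to_numpy(float)
    dist = np.linalg.norm(xyz - ion_xyz, axis=1)
    within = dist <= o_cutoff
    ligands = []
    for (idx, row), d in zip(oxy[within].iterrows(), dist[within]):
        ligands.append((row["chain"], int(row["resnum"]), row["resname"],
                        row["name"], float(d)))
    ligands.sort(key=lambda t: t[4])
    label = _pbp_label(ion_xyz, xyz[within], angle_tol) if within.any() else "apo"
    return CoordinationSite(
        (ion_row["chain"], int(ion_row["resnum"]), ion_row["resname"]),
        ligands, label)


# ---------------------------------------------------------------------------
# Heme geometry


@dataclass(frozen=True)
class HemeGeometry:
    """Mean-plane geometry of the porphyrin macrocycle.

    ``fe_oop`` is the signed iron displacement from the 24-atom least-squares
    plane, positive toward the proximal histidine. ``dome`` is the mean
    signed deviation of the four pyrrole nitrogens (same sign convention);
    ``saddle`` is the mean absolute alternating-sign deviation of the eight
    beta carbons, (1/8)|sum s_i d_i| with signs (+,+,-,-,+,+,-,-).
    """

    centroid: np.ndarray
    normal: np.ndarray
    fe_oop: float
    dome: float
    saddle: float
    per_atom_dev: dict


def _fit_plane(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(xyz - centroid)
    return centroid, vt[2]


def heme_geometry(model: StructureModel, proximal_his: int | tuple[str, int] | None = None,
                  heme_resname: str = "HEM",
                  heme_id: tuple[str, int] | None = None) -> HemeGeometry:
    """Porphyrin mean plane, Fe displacement, and dome/saddle amplitudes.

    The plane is the least-squares fit through the 24 macrocycle atoms. If
    ``proximal_his`` is given the plane normal is oriented toward that
    histidine's NE2 so that positive deviations point to the proximal side;
    otherwise the normal is oriented so that fe_oop >= 0. For models with
    several heme groups (e.g. a dimer) pass ``heme_id`` = (chain, resnum);
    by default the first heme in the model is analysed.
    """
    heme = model.select(resname=heme_resname)
    if len(heme) == 0:
        raise ValueError(f"no residue {heme_resname!r} in model")
    if heme_id is not None:
        heme = heme[(heme["chain"] == heme_id[0]) & (heme["resnum"] == heme_id[1])]
        if len(heme) == 0:
            raise ValueError(f"no {heme_resname} residue {heme_id}")
    else:
        first = heme.iloc[0]
        heme = heme[(heme["chain"] == first["chain"])
                    & (heme["resnum"] == first["resnum"])]
    by_name = {row["name"]: np.array([row["x"], row["y"], row["z"]])
               for _, row in heme.iterrows()}
    missing = [a for a in MACROCYCLE_ATOMS if a not in by_name]
    if missing:
        raise ValueError(f"heme macrocycle atoms missing: {missing}")
    if "FE" not in by_name:
        raise ValueError("heme iron (FE) missing")

    ring = np.array([by_name[a] for a in MACROCYCLE_ATOMS])
    centroid, normal = _fit_plane(ring)

    if proximal_his is not None:
        if isinstance(proximal_his, tuple):
            his = model.select(chain=proximal_his[0], resnum=proximal_his[1], name="NE2")
        else:
            his = model.select(resnum=proximal_his, name="NE2")
        if len(his) == 0:
            raise ValueError(f"proximal histidine {proximal_his} has no NE2 atom")
        ne2 = his.iloc[0][["x", "y", "z"]].to_numpy(float)
        if (ne2 - centroid) @ normal < 0:
            normal = -normal
    elif (by_name["FE"] - centroid) @ normal < 0:
        normal = -normal

    dev = {name: float((by_name[name] - centroid) @ normal) for name in MACROCYCLE_ATOMS}
    fe_oop = float((by_name["FE"] - centroid) @ normal)
    dome = float(np.mean([dev[a] for a in PYRROLE_N]))
    saddle = float(abs(SADDLE_SIGNS @ np.array([dev[a] for a in BETA_CARBONS])) / 8.0)
    return HemeGeometry(centroid, normal, fe_oop, dome, saddle, dev)


def list_hemes(model: StructureModel, heme_resname: str = "HEM") -> list[tuple[str, int]]:
    """(chain, resnum) of every heme group in the model, in file order."""
    heme = model.select(resname=heme_resname)
    seen: list[tuple[str, int]] = []
    for row in heme.itertuples(index=False):
        key = (row.chain, int(row.resnum))
        if key not in seen:
            seen.append(key)
    return seen


# ---------------------------------------------------------------------------
# Covalent heme-protein links


@dataclass(frozen=True)
class CovalentLink:
    rule: str
    residue: tuple[str, int, str]
    residue_atom: str
    heme_atom: str
    distance: float


#: default link rules: (rule name, residue names, residue atoms, heme atoms).
#: Ester links form between Asp/Glu carboxylate oxygens and the modified
#: (hydroxy)methyl carbons of the porphyrin; the MPO-type sulfonium links a
#: methionine S-delta to a vinyl carbon.
DEFAULT_LINK_RULES = (
    ("ester", ("ASP", "GLU"), ("OD1", "OD2", "OE1", "OE2"),
     ("CMA", "CMB", "CMC", "CMD")),
    ("sulfonium", ("MET",), ("SD",), ("CAB", "CBB", "CAC", "CBC")),
)


def detect_covalent_links(model: StructureModel, rules=DEFAULT_LINK_RULES,
                          bond_cutoff: float = 1.8,
                          heme_resname: str = "HEM") -> list[CovalentLink]:
    """Find covalent heme-protein links by short-contact rules.

    Each rule names candidate protein residue/atom types and heme atom names;
    any pair closer than ``bond_cutoff`` (default 1.8 A, a generous covalent
    O-C / S-C contact) is reported, closest contact per residue-rule.
    """
    heme = model.select(resname=heme_resname)
    links = []
    for rule, resnames, resatoms, hematoms in rules:
        hx = heme[heme["name"].isin(hematoms)]
        if len(hx) == 0:
            continue
        hxyz = hx[["x", "y", "z"]].to_numpy(float)
        prot = model.atoms[model.atoms["resname"].isin(resnames)
                           & model.atoms["name"].isin(resatoms)]
        best: dict[tuple, CovalentLink] = {}
        for _, row in prot.iterrows():
            d = np.linalg.norm(hxyz - row[["x", "y", "z"]].to_numpy(float), axis=1)
            k = int(np.argmin(d))
            if d[k] <= bond_cutoff:
                key = (row["chain"], int(row["resnum"]))
                link = CovalentLink(rule, (row["chain"], int(row["resnum"]),
                                           row["resname"]),
                                    row["name"], hx.iloc[k]["name"], float(d[k]))
                if key not in best or link.distance < best[key].distance:
                    best[key] = link
        links.extend(sorted(best.values(), key=lambda l: l.distance))
    return links


# ---------------------------------------------------------------------------
# Cavity volume


@dataclass(frozen=True)
class CavityResult:
    volume: float
    n_points: int
    grid_spacing: float
    open_pocket: bool
    truncation_radius: float | None = None


def cavity_volume(model: StructureModel, seed_point, grid_spacing: float = 0.5,
                  probe_radius: float = 1.4, margin: float = 2.0) -> CavityResult:
    """Flood-fill cavity volume from a seed point.

    Grid points at least ``probe_radius`` from every atom center are free;
    the 6-connected free component containing the seed is the cavity and its
    volume is point count x spacing^3. If the component reaches the bounding
    box (atom bbox + margin) the pocket is open: the flag is set and the
    maximum seed distance reached is reported as the truncation radius.
    """
    seed = np.asarray(seed_point, float)
    xyz = model.coords
    tree = cKDTree(xyz)
    if tree.query(seed)[0] < probe_radius:
        raise ValueError("seed point clashes with an atom (inside probe radius)")

    lo = np.minimum(xyz.min(axis=0), seed) - margin
    hi = np.maximum(xyz.max(axis=0), seed) + margin
    axes = [np.arange(lo[k], hi[k] + grid_spacing, grid_spacing) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    shape = grid.shape[:3]
    flat = grid.reshape(-1, 3)
    dist, _ = tree.query(flat, workers=-1)
    free = (dist >= probe_radius).reshape(shape)

    labels, _ = ndimage.label(free)
    seed_idx = tuple(int(round((seed[k] - lo[k]) / grid_spacing)) for k in range(3))
    seed_label = labels[seed_idx]
    if seed_label == 0:
        raise ValueError("seed grid point is not free; move the seed or refine the grid")
    mask = labels == seed_label
    n = int(mask.sum())
    volume = n * grid_spacing ** 3

    boundary = (mask[0].any() or mask[-1].any() or mask[:, 0].any()
                or mask[:, -1].any() or mask[:, :, 0].any() or mask[:, :, -1].any())
    trunc = None
    if boundary:
        pts = flat.reshape(*shape, 3)[mask]
        trunc = float(np.max(np.linalg.norm(pts - seed, axis=1)))
    return CavityResult(volume, n, grid_spacing, bool(boundary), trunc)


# ---------------------------------------------------------------------------
# Charge patches


@dataclass(frozen=True)
class ChargePatch:
    residues: list  # (chain, resnum, resname, formal charge)
    net_charge: float
    centroid: np.ndarray


def _sphere_points(n: int) -> np.ndarray:
    """Golden-spiral quasi-uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def shrake_rupley_sasa(model: StructureModel, probe: float = 1.4,
                       n_points: int = 120) -> np.ndarray:
    """Per-atom solvent-accessible surface area by rolling-probe point
    sampling (Shrake-Rupley). Returns SASA in A^2 per atom row."""
    atoms = model.atoms
    xyz = model.coords
    radii = np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in atoms["element"]]) + probe
    sphere = _sphere_points(n_points)
    tree = cKDTree(xyz)
    max_r = radii.max()
    sasa = np.zeros(len(atoms))
    for i in range(len(atoms)):
        pts = xyz[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(xyz[i], radii[i] + max_r)
                     if j != i]
        if neighbors:
            nxyz = xyz[neighbors]
            nrad = radii[neighbors]
            d2 = ((pts[:, None, :] - nxyz[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nrad ** 2)[None, :]).any(axis=1)
            n_acc = int((~buried).sum())
        else:
            n_acc = n_points
        sasa[i] = 4 * np.pi * radii[i] ** 2 * n_acc / n_points
    return sasa


_CHARGE_ATOM = {
    "ARG": ("CZ", "NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "ASP": ("CG", "OD1", "OD2"),
    "GLU": ("CD", "OE1", "OE2"),
    "HIS": ("ND1", "NE2", "CE1"),
}


def charge_patches(model: StructureModel, exposure_probe: float = 1.4,
                   cluster_radius: float = 8.0, exposure_threshold: float = 0.2,
                   include_his: bool = False, n_points: int = 120) -> list[ChargePatch]:
    """Cluster solvent-exposed charged residues into surface patches.

    Relative accessibility is residue SASA (Shrake-Rupley point sampling with
    the given probe) over the residue's theoretical maximum; residues above
    ``exposure_threshold`` carrying a formal charge (Arg/Lys +1, Asp/Glu -1,
    His +0.5 if enabled) are single-linkage clustered by their charged-group
    centroids within ``cluster_radius``. Patches are ranked by |net charge|.
    """
    charge_of = {r: +1.0 for r in POSITIVE_RESIDUES}
    charge_of.update({r: -1.0 for r in NEGATIVE_RESIDUES})
    if include_his:
        charge_of["HIS"] = 0.5

    prot = model.protein_atoms()
    if len(prot) == 0:
        return []
    sasa = shrake_rupley_sasa(model, probe=exposure_probe, n_points=n_points)

    exposed = []  # (chain, resnum, resname, charge, centroid)
    for (chain, resnum, icode), group in prot.groupby(["chain", "resnum", "icode"],
                                                      sort=False):
        resname = group["resname"].iloc[0]
        if resname not in charge_of:
            continue
        res_sasa = sasa[group.index.to_numpy()].sum()
        rel = res_sasa / MAX_ASA.get(resname, 200.0)
        if rel < exposure_threshold:
            continue
        anchor_names = _CHARGE_ATOM.get(resname, ())
        anchor = group[group["name"].isin(anchor_names)]
        pts = (anchor if len(anchor) else group)[["x", "y", "z"]].to_numpy(float)
        exposed.append((chain, int(resnum), resname, charge_of[resname],
                        pts.mean(axis=0)))
    if not exposed:
        return []

    centers = np.array([e[4] for e in exposed])
    parent = list(range(len(exposed)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(exposed)):
        for j in range(i + 1, len(exposed)):
            if np.linalg.norm(centers[i] - centers[j]) <= cluster_radius:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(len(exposed)):
        groups.setdefault(find(i), []).append(i)

    patches = []
    for members in groups.values():
        residues = [(exposed[i][0], exposed[i][1], exposed[i][2], exposed[i][3])
                    for i in members]
        net = sum(r[3] for r in residues)
        centroid = centers[members].mean(axis=0)
        patches.append(ChargePatch(sorted(residues, key=lambda r: (r[0], r[1])),
                                   net, centroid))
    patches.sort(key=lambda p: (-abs(p.net_charge), p.residues[0]))
    return patches


# ---------------------------------------------------------------------------
# Matthews coefficient


@dataclass(frozen=True)
class CrystalForm:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    space_group: str = "P 1"
    mol_per_asu: int = 1
    z_per_cell: int | None = None

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        if self.z_per_cell is None:
            key = self.space_group.strip()
            mult = SPACE_GROUP_MULTIPLICITY.get(key) or SPACE_GROUP_MULTIPLICITY.get(
                key.replace(" ", ""))
            if mult is None:
                raise ValueError(
                    f"unknown space group {self.space_group!r}; pass z_per_cell")
            object.__setattr__(self, "z_per_cell", mult * self.mol_per_asu)

    @property
    def volume(self) -> float:
        """Unit-cell volume by the general triclinic formula."""
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        return (self.a * self.b * self.c
                * math.sqrt(1 - ca**2 - cb**2 - cg**2 + 2 * ca * cb * cg))


def matthews_solvent(form: CrystalForm, molecular_mass: float) -> tuple[float, float]:
    """Matthews coefficient V_M (A^3/Da) and solvent fraction.

    V_M = V_cell / (Z x M); solvent fraction = 1 - 1.23 / V_M (the Matthews
    relation with partial specific volume 0.74 cm^3/g). Values implying a
    physically over-dense or over-dilute crystal are clamped to [0, 1] with a
    warning.
    """
    if molecular_mass <= 0:
        raise ValueError("molecular mass must be positive")
    v_m = form.volume / (form.z_per_cell * molecular_mass)
    solvent = 1.0 - 1.23 / v_m
    if v_m <= 1.23:
        warnings.warn(f"V_M = {v_m:.2f} <= 1.23 A^3/Da: physically over-dense cell")
    if not (0.0 <= solvent <= 1.0):
        solvent = min(max(solvent, 0.0), 1.0)
    return v_m, solvent


# ---------------------------------------------------------------------------
# Rigid transforms (used by invariance tests and the report)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def apply_rigid_transform(model: StructureModel, rotation: np.ndarray,
                          translation) -> StructureModel:
    xyz = model.coords @ np.asarray(rotation, float).T + np.asarray(translation, float)
    return model.with_coords(xyz)
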