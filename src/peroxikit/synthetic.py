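"""Synthetic fixtures with planted ground truth for every pipeline stage.

Each generator draws from its own seeded sub-stream (derived from the spec
seed and a fixed per-component index), so adding or reordering components
never perturbs another component's output, and an identical spec yields
bit-identical files. Every generator returns a machine-readable truth record
alongside the data, for recovery tests.

The default generator parameters are the conditions of the characterization
study this package models: site glycoform distributions dominated by
HexNAc2Hex(3..6) high-mannose-type compositions, a ragged light-chain C
terminus with a ~77% arginine share, a two-transition DSC endotherm at
82/85 deg C, and a single optical melt transition at 70 deg C. Where the
study reports only the major species, the unreported remainder is assigned
to plausible neighboring compositions so that fractions total 1 (see
docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .glyco import DeconvolutedPeak, GlycanComposition, glycopeptide_mass, write_peaklist_csv
from .sequence import Peptide
from .structure import StructureModel, write_pdb, _COLUMNS
from .thermal import MeltCurve, Thermogram, TransitionFit, dsc_model_cp, melt_model

__all__ = [
    "SyntheticSpec",
    "ASN363_FRACTIONS",
    "ASN327_FRACTIONS",
    "TERMINUS_FRACTIONS",
    "SYNTHETIC_ASN363_PEPTIDE",
    "SYNTHETIC_ASN327_PEPTIDE",
    "SYNTHETIC_TERMINAL_VARIANTS",
    "make_glyco_peaklist",
    "make_terminus_peaklist",
    "make_melt_curve",
    "make_thermogram",
    "make_toy_structure",
]

_STREAMS = {"glyco": 1, "termini": 2, "melt": 3, "dsc": 4, "structure": 5}

#: Reported major glycoforms at Asn363 (48% HexNAc2Hex3, 30% HexNAc2Hex6);
#: the unreported 22% remainder is split over the intermediate high-mannose
#: compositions so the stated fractions are fractions of the site total.
ASN363_FRACTIONS = {
    GlycanComposition(hexnac=2, hex=3): 0.48,
    GlycanComposition(hexnac=2, hex=6): 0.30,
    GlycanComposition(hexnac=2, hex=4): 0.12,
    GlycanComposition(hexnac=2, hex=5): 0.10,
}

#: Reported glycoforms at Asn327 (36/18.5/19/14% for HexNAc2Hex4/3/5/6);
#: the 12.5% remainder goes to the next larger high-mannose composition.
ASN327_FRACTIONS = {
    GlycanComposition(hexnac=2, hex=4): 0.36,
    GlycanComposition(hexnac=2, hex=3): 0.185,
    GlycanComposition(hexnac=2, hex=5): 0.19,
    GlycanComposition(hexnac=2, hex=6): 0.14,
    GlycanComposition(hexnac=2, hex=7): 0.125,
}

#: Ragged light-chain C terminus: arginine vs valine share (renormalized).
TERMINUS_FRACTIONS = {"R": 0.772, "V": 0.228}

#: Synthetic stand-in tryptic glycopeptides (the study peptide sequences are
#: not reproduced here; recovery statistics depend only on masses).
SYNTHETIC_ASN363_PEPTIDE = Peptide("LLNTTGK", 361, 367)
SYNTHETIC_ASN327_PEPTIDE = Peptide("VVNGSDLAK", 325, 333)

#: Synthetic stand-in light-chain terminal peptides: a fully tryptic
#: ...R-ending peptide and its one-residue ragged ...RV extension.
SYNTHETIC_TERMINAL_VARIANTS = (
    Peptide("LQDSLFGGAR", 235, 244),
    Peptide("LQDSLFGGARV", 235, 245, semi=True),
)


@dataclass
class SyntheticSpec:
    """Generator parameters for all synthetic fixtures.

    Fractions must lie in [0, 1] and sum to at most 1 per component. The
    same spec (including seed) always produces bit-identical outputs.
    """

    seed: int = 0
    # glycopeptide peak list
    glyco_fractions: Mapping[GlycanComposition, float] = field(
        default_factory=lambda: dict(ASN363_FRACTIONS))
    ppm_sigma: float = 5.0
    intensity_cv: float = 0.05
    base_intensity: float = 1000.0
    # ragged-terminus mixture
    terminus_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(TERMINUS_FRACTIONS))
    # DSC thermogram: (tm deg C, dH_vH, dH_cal) per transition
    transitions: Sequence[tuple[float, float, float]] = (
        (82.0, 120.0, 120.0), (85.0, 150.0, 150.0))
    dsc_noise: float = 0.02
    dsc_baseline: tuple[float, float] = (0.2, 0.0)
    dsc_t_range: tuple[float, float, float] = (20.0, 100.0, 0.2)
    # optical melt
    melt_tms: Sequence[float] = (70.0,)
    melt_widths: Sequence[float] = (2.0,)
    melt_amplitudes: Sequence[float] = (1.0,)
    melt_baseline: tuple[float, float] = (-1.0, 0.0)
    melt_noise: float = 0.01
    melt_t_range: tuple[float, float, float] = (20.0, 95.0, 0.5)
    # toy structure plants
    n_disulfides: int = 0
    sg_distance: float = 2.03
    ca_site: bool = False
    ca_o_distance: float = 2.4
    porphyrin: Mapping[str, float] | None = None  # dome, saddle, fe_oop
    ester_link: bool = False
    ester_distance: float = 1.4
    n_exposed_lys: int = 0

    def __post_init__(self) -> None:
        for name, fracs in (("glyco", self.glyco_fractions),
                            ("terminus", self.terminus_fractions)):
            vals = list(fracs.values())
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValueError(f"{name} fractions must lie in [0, 1]")
            if sum(vals) > 1.0 + 1e-9:
                raise ValueError(f"{name} fractions sum to {sum(vals)} > 1")

    def rng(self, component: str) -> np.random.Generator:
        """Seeded sub-stream for one component."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[component]]))


def _noisy_intensity(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Multiplicative Gaussian intensity noise; non-positive draws are
    resampled so intensities stay physical."""
    if mean <= 0:
        raise ValueError("mean intensity must be positive")
    while True:
        value = mean * (1.0 + rng.normal(0.0, cv)) if cv > 0 else mean
        if value > 0:
            return value


def _mass_error(rng: np.random.Generator, ppm_sigma: float) -> float:
    """Relative mass error: Normal(0, sigma_ppm) truncated at 2 sigma
    (resampled). Truncation keeps every generated peak identifiable at the
    standard matching tolerance of twice the mass accuracy, so the generated
    composition fractions are recoverable rather than censored; the effective
    sigma is 0.88x the nominal value."""
    if ppm_sigma <= 0:
        return 0.0
    while True:
        eps = rng.normal(0.0, ppm_sigma)
        if abs(eps) <= 2.0 * ppm_sigma:
            return eps * 1e-6


def make_glyco_peaklist(spec: SyntheticSpec, peptide: Peptide | None = None,
                        site: int | None = None, csv_path=None, truth_path=None
                        ) -> tuple[list[DeconvolutedPeak], dict]:
    """One deconvoluted peak per glycoform of a glycopeptide.

    Peak masses are the theoretical glycopeptide masses perturbed by
    Normal(0, ppm_sigma) relative error; intensities are proportional to the
    spec fractions with Normal(0, cv) multiplicative noise (resampled if
    non-positive). Returns (peaks, truth); optionally writes CSV + JSON.
    """
    peptide = peptide or SYNTHETIC_ASN363_PEPTIDE
    site = site if site is not None else peptide.start + peptide.sequence.index("N")
    rng = spec.rng("glyco")
    peaks = []
    truth_rows = []
    for comp, fraction in spec.glyco_fractions.items():
        theo = glycopeptide_mass(peptide.mass, comp)
        mass = theo * (1.0 + _mass_error(rng, spec.ppm_sigma))
        intensity = _noisy_intensity(rng, spec.base_intensity * fraction,
                                     spec.intensity_cv)
        peaks.append(DeconvolutedPeak(mass, intensity))
        truth_rows.append({"composition": str(comp), "fraction": fraction,
                           "theoretical_mass": theo})
    truth = {"seed": spec.seed, "peptide": peptide.sequence, "site": site,
             "ppm_sigma": spec.ppm_sigma, "intensity_cv": spec.intensity_cv,
             "glycoforms": truth_rows}
    if csv_path is not None:
        write_peaklist_csv(peaks, csv_path)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2)
    return peaks, truth


def make_terminus_peaklist(spec: SyntheticSpec,
                           variants: Sequence[Peptide] = SYNTHETIC_TERMINAL_VARIANTS,
                           csv_path=None, truth_path=None
                           ) -> tuple[list[DeconvolutedPeak], dict]:
    """Peak list of ragged chain-terminal peptide variants.

    Each variant whose terminal residue appears in ``terminus_fractions``
    gets one peak at its (ppm-perturbed) mass with intensity proportional to
    the fraction, same noise model as the glyco generator.
    """
    rng = spec.rng("termini")
    peaks = []
    truth_rows = []
    for pep in variants:
        res = pep.sequence[-1]
        if res not in spec.terminus_fractions:
            continue
        fraction = spec.terminus_fractions[res]
        mass = pep.mass * (1.0 + _mass_error(rng, spec.ppm_sigma))
        intensity = _noisy_intensity(rng, spec.base_intensity * fraction,
                                     spec.intensity_cv)
        peaks.append(DeconvolutedPeak(mass, intensity))
        truth_rows.append({"peptide": pep.sequence, "terminal": res,
                           "fraction": fraction, "theoretical_mass": pep.mass})
    truth = {"seed": spec.seed, "fractions": dict(spec.terminus_fractions),
             "variants": truth_rows}
    if csv_path is not None:
        write_peaklist_csv(peaks, csv_path)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2)
    return peaks, truth


def make_melt_curve(spec: SyntheticSpec, csv_path=None) -> tuple[MeltCurve, dict]:
    """Sigmoidal melting trace with additive Gaussian noise."""
    rng = spec.rng("melt")
    lo, hi, step = spec.melt_t_range
    t = np.arange(lo, hi + step / 2, step)
    clean = melt_model(t, spec.melt_baseline, spec.melt_tms, spec.melt_widths,
                       spec.melt_amplitudes)
    scale = max(abs(a) for a in spec.melt_amplitudes)
    y = clean + rng.normal(0.0, spec.melt_noise * scale, size=t.shape) \
        if spec.melt_noise > 0 else clean
    curve = MeltCurve(t, y)
    truth = {"seed": spec.seed, "tms": list(spec.melt_tms),
             "widths": list(spec.melt_widths),
             "amplitudes": list(spec.melt_amplitudes),
             "baseline": list(spec.melt_baseline), "noise": spec.melt_noise}
    if csv_path is not None:
        pd.DataFrame({"temperature": t, "signal": y}).to_csv(csv_path, index=False)
    return curve, truth


def make_thermogram(spec: SyntheticSpec, csv_path=None) -> tuple[Thermogram, dict]:
    """Non-two-state forward model + linear baseline + Gaussian noise.

    The noise standard deviation is ``dsc_noise`` times the peak excess heat
    capacity (2% of amplitude by default).
    """
    if not spec.transitions:
        raise ValueError("need at least one transition")
    rng = spec.rng("dsc")
    lo, hi, step = spec.dsc_t_range
    t = np.arange(lo, hi + step / 2, step)
    trs = [TransitionFit(tm=tm, dh_vh=dhv, dh_cal=dhc)
           for tm, dhv, dhc in spec.transitions]
    clean = dsc_model_cp(trs, t) + spec.dsc_baseline[0] + spec.dsc_baseline[1] * t
    scale = float(np.max(dsc_model_cp(trs, t)))
    y = clean + rng.normal(0.0, spec.dsc_noise * scale, size=t.shape) \
        if spec.dsc_noise > 0 else clean
    thermo = Thermogram(t, y)
    truth = {"seed": spec.seed,
             "transitions": [{"tm": tm, "dh_vh": dhv, "dh_cal": dhc}
                             for tm, dhv, dhc in spec.transitions],
             "baseline": list(spec.dsc_baseline), "noise": spec.dsc_noise}
    if csv_path is not None:
        pd.DataFrame({"temperature": t, "cp": y}).to_csv(csv_path, index=False)
    return thermo, truth


# ---------------------------------------------------------------------------
# Toy structures


class ClashError(ValueError):
    pass


def _rows_for(component, record, name, resname, chain, resnum, xyz, element):
    return {"component": component, "record": record, "serial": 0, "name": name,
            "altloc": "", "resname": resname, "chain": chain, "resnum": resnum,
            "icode": "", "x": xyz[0], "y": xyz[1], "z": xyz[2],
            "occupancy": 1.0, "bfactor": 20.0, "element": element}


def _ideal_porphyrin(dome: float, saddle: float, fe_oop: float) -> list[dict]:
    """Idealized 24-atom macrocycle + Fe + ring methyls, deformable.

    Doming displaces the four pyrrole nitrogens along +z by 1.2*dome so the
    mean signed N deviation from the refit 24-atom plane equals ``dome``
    exactly; saddling displaces the eight beta carbons by +-saddle with the
    (+,+,-,-,+,+,-,-) pattern, which leaves the plane unchanged; the iron
    sits at fe_oop above the (shifted) plane.
    """
    rows = []
    ring_letters = "ABCD"
    theta0 = {"A": 0.0, "B": 90.0, "C": 180.0, "D": 270.0}
    saddle_sign = {"A": +1.0, "B": -1.0, "C": +1.0, "D": -1.0}

    def polar(r, deg, z=0.0):
        a = np.radians(deg)
        return np.array([r * np.cos(a), r * np.sin(a), z])

    dz_n = 1.2 * dome
    plane_z = 4 * dz_n / 24.0
    for letter in ring_letters:
        th = theta0[letter]
        s = saddle_sign[letter]
        rows.append(_rows_for("heme", "HETATM", f"N{letter}", "HEM", "X", 701,
                              polar(2.05, th, dz_n), "N"))
        rows.append(_rows_for("heme", "HETATM", f"C1{letter}", "HEM", "X", 701,
                              polar(3.05, th - 24.0), "C"))
        rows.append(_rows_for("heme", "HETATM", f"C2{letter}", "HEM", "X", 701,
                              polar(4.30, th - 17.0, s * saddle), "C"))
        rows.append(_rows_for("heme", "HETATM", f"C3{letter}", "HEM", "X", 701,
                              polar(4.30, th + 17.0, s * saddle), "C"))
        rows.append(_rows_for("heme", "HETATM", f"C4{letter}", "HEM", "X", 701,
                              polar(3.05, th + 24.0), "C"))
        rows.append(_rows_for("heme", "HETATM", f"CH{letter}", "HEM", "X", 701,
                              polar(3.40, th - 45.0), "C"))
        rows.append(_rows_for("heme", "HETATM", f"CM{letter}", "HEM", "X", 701,
                              polar(5.40, th + 31.0), "C"))
    rows.append(_rows_for("heme", "HETATM", "FE", "HEM", "X", 701,
                          np.array([0.0, 0.0, fe_oop + plane_z]), "FE"))
    return rows


def make_toy_structure(spec: SyntheticSpec, pdb_path=None
                       ) -> tuple[StructureModel, dict]:
    """Small coordinate model with planted, exactly-known geometry.

    Components (all optional, controlled by the spec): a polyalanine
    scaffold; ``n_disulfides`` Cys pairs at ``sg_distance`` Sgamma
    separation; a Ca2+ ion with seven water oxygens in an ideal pentagonal
    bipyramid at ``ca_o_distance``; an idealized porphyrin with controllable
    dome/saddle amplitudes and Fe out-of-plane displacement plus a proximal
    histidine on the +z side; an Asp carboxylate oxygen ``ester_distance``
    from a heme methyl carbon; and ``n_exposed_lys`` isolated surface
    lysines. Atom naming is legal PDB. Components that overlap (< 1 A
    between atoms of different components) raise ``ClashError``.
    """
    rows: list[dict] = []

    # polyalanine scaffold, well away from the plants
    for i in range(12):
        base = np.array([i * 3.8, 25.0, 0.0])
        resnum = i + 1
        for name, offset, elem in (("N", (0.0, 0.0, 0.0), "N"),
                                   ("CA", (1.2, 0.8, 0.0), "C"),
                                   ("C", (2.4, 0.0, 0.2), "C"),
                                   ("O", (2.6, -1.2, 0.2), "O"),
                                   ("CB", (1.2, 1.8, 1.1), "C")):
            rows.append(_rows_for("scaffold", "ATOM", name, "ALA", "A", resnum,
                                  base + np.array(offset), elem))

    for k in range(spec.n_disulfides):
        base = np.array([k * 14.0, -15.0, 0.0])
        d = spec.sg_distance
        # partner cysteines extend in opposite directions from the S-S bond
        for resnum, sg, sign in ((101 + 2 * k, base, -1.0),
                                 (102 + 2 * k, base + np.array([d, 0.0, 0.0]), +1.0)):
            cb = sg + np.array([sign * 1.4, 1.0, 0.0])
            ca = cb + np.array([sign * 1.0, 1.2, 0.0])
            n = ca + np.array([0.0, 1.4, 0.3])
            for name, xyz, elem in (("N", n, "N"), ("CA", ca, "C"),
                                    ("CB", cb, "C"), ("SG", sg, "S")):
                rows.append(_rows_for(f"ss{k}", "ATOM", name, "CYS", "B", resnum,
                                      xyz, elem))

    if spec.ca_site:
        center = np.array([-20.0, -20.0, 0.0])
        rows.append(_rows_for("ca", "HETATM", "CA", "CA", "C", 801, center, "CA"))
        r = spec.ca_o_distance
        rows.append(_rows_for("ca", "HETATM", "O", "HOH", "C", 901,
                              center + [0, 0, r], "O"))
        rows.append(_rows_for("ca", "HETATM", "O", "HOH", "C", 902,
                              center + [0, 0, -r], "O"))
        for m in range(5):
            a = np.radians(72.0 * m)
            rows.append(_rows_for("ca", "HETATM", "O", "HOH", "C", 903 + m,
                                  center + [r * np.cos(a), r * np.sin(a), 0.0], "O"))

    heme_truth = None
    if spec.porphyrin is not None:
        dome = float(spec.porphyrin.get("dome", 0.0))
        saddle = float(spec.porphyrin.get("saddle", 0.0))
        fe_oop = float(spec.porphyrin.get("fe_oop", 0.0))
        rows.extend(_ideal_porphyrin(dome, saddle, fe_oop))
        # proximal histidine NE2 on the +z (proximal) side of the macrocycle
        for name, xyz, elem in (("NE2", (0.0, 0.0, 3.2), "N"),
                                ("CE1", (1.1, 0.0, 4.0), "C"),
                                ("ND1", (1.0, 0.0, 5.3), "N"),
                                ("CG", (-0.3, 0.3, 5.6), "C"),
                                ("CD2", (-0.9, 0.2, 4.3), "C"),
                                ("CB", (-1.0, 0.5, 6.9), "C"),
                                ("CA", (-0.2, 0.4, 8.2), "C"),
                                ("N", (-0.9, 1.0, 9.3), "N")):
            rows.append(_rows_for("heme", "ATOM", name, "HIS", "X", 474,
                                  np.array(xyz), elem))
        if spec.ester_link:
            # Asp carboxylate O planted ester_distance from methyl carbon CMA
            cma = next(r for r in rows if r["name"] == "CMA")
            anchor = np.array([cma["x"], cma["y"], cma["z"]])
            direction = anchor / np.linalg.norm(anchor)
            od1 = anchor + spec.ester_distance * direction
            cg = od1 + 1.3 * direction
            od2 = cg + np.array([0.0, 1.2, 0.4])
            cb = cg + 1.5 * direction
            ca = cb + 1.5 * direction
            for name, xyz, elem in (("OD1", od1, "O"), ("CG", cg, "C"),
                                    ("OD2", od2, "O"), ("CB", cb, "C"),
                                    ("CA", ca, "C")):
                rows.append(_rows_for("heme", "ATOM", name, "ASP", "X", 232,
                                      xyz, "O" if name.startswith("O") else "C"))
        heme_truth = {"dome": dome, "saddle": saddle, "fe_oop": fe_oop,
                      "proximal_his": 474,
                      "ester_links": 1 if spec.ester_link else 0,
                      "ester_distance": spec.ester_distance if spec.ester_link else None}

    for m in range(spec.n_exposed_lys):
        base = np.array([30.0 + 4.0 * m, 30.0, 0.0])
        for name, offset, elem in (("N", (0.0, 0.0, 0.0), "N"),
                                   ("CA", (0.5, 1.2, 0.0), "C"),
                                   ("CB", (0.5, 2.0, 1.2), "C"),
                                   ("CG", (1.0, 3.4, 1.2), "C"),
                                   ("CD", (1.0, 4.2, 2.4), "C"),
                                   ("CE", (1.5, 5.6, 2.4), "C"),
                                   ("NZ", (1.5, 6.4, 3.6), "N")):
            rows.append(_rows_for("lys", "ATOM", name, "LYS", "D", 851 + m,
                                  base + np.array(offset), "N" if name in ("N", "NZ") else "C"))

    df = pd.DataFrame(rows)
    xyz = df[["x", "y", "z"]].to_numpy(float)
    comp = df["component"].to_numpy()
    from scipy.spatial import cKDTree

    tree = cKDTree(xyz)
    for i, j in tree.query_pairs(1.0):
        if comp[i] != comp[j]:
            raise ClashError(
                f"planted components {comp[i]!r} and {comp[j]!r} clash "
                f"(atoms {df.iloc[i]['name']}/{df.iloc[j]['name']})")

    df = df.drop(columns="component")
    df["serial"] = np.arange(1, len(df) + 1)
    model = StructureModel(df[_COLUMNS].copy(), id=f"synthetic-{spec.seed}")
    truth = {
        "seed": spec.seed,
        "n_atoms": len(df),
        "n_disulfides": spec.n_disulfides,
        "sg_distance": spec.sg_distance if spec.n_disulfides else None,
        "ca_site": ({"coordination": 7, "distance": spec.ca_o_distance,
                     "geometry": "pentagonal-bipyramidal"} if spec.ca_site else None),
        "heme": heme_truth,
        "n_exposed_lys": spec.n_exposed_lys,
    }
    if pdb_path is not None:
        write_pdb(model, pdb_path)
        truth_path = str(pdb_path) + ".truth.json"
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2)
    return model, truth
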