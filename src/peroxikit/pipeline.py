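"""Pipeline orchestration: run configuration and the consolidated report.

``RunConfig`` captures every stage toggle and parameter; it round-trips
losslessly through YAML. ``run_characterization`` executes the enabled
stages in dependency order (sequence before glyco; structure and thermal
independent) and writes per-stage JSON plus a consolidated ``summary.json``
mirroring the characterization table: sequons, masses and pI, site glycoform
profiles, chain-terminus profile, disulfides, Ca site, heme geometry,
covalent links, Matthews/solvent bookkeeping, and the fitted Tm list.
Identical config + seed produces a byte-identical summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import glyco as glyco_mod
from . import sequence as seq_mod
from . import structure as struct_mod
from . import thermal as thermal_mod

logger = logging.getLogger("peroxikit")

STAGES = ("sequence", "glyco", "structure", "thermal")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All pipeline inputs and stage parameters, YAML round-trippable."""

    stages: list = field(default_factory=lambda: list(STAGES))
    output_dir: str = "peroxikit_out"
    seed: int = 0
    # sequence stage
    fasta: str | None = None
    exclude_proline_x: bool = False
    annotate_epo_chains: bool = False
    # glyco stage
    glyco_peaklist: str | None = None
    glyco_peptide: str | None = None
    glyco_peptide_start: int = 1
    glyco_site: int | None = None
    tol_ppm: float = 10.0
    terminus_peaklist: str | None = None
    terminus_peptides: list = field(default_factory=list)  # [[seq, start], ...]
    # structure stage
    structure_path: str | None = None
    sg_cutoff: float = 2.5
    ca_cutoff: float = 2.9
    link_cutoff: float = 1.8
    proximal_his: int | None = None
    cavity_seed_xyz: list | None = None
    grid_spacing: float = 0.5
    probe_radius: float = 1.4
    charge_cluster_radius: float = 8.0
    cell: list | None = None  # [a, b, c, alpha, beta, gamma, space_group]
    molecular_mass: float | None = None
    # thermal stage
    melt_csv: str | None = None
    melt_transitions: int = 1
    thermogram_csv: str | None = None
    dsc_transitions: int = 2

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s) {sorted(unknown)}")
        if not self.stages:
            raise ConfigError("at least one stage must be enabled")

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError("config must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded, so
        identical analyses hash identically wherever they are written)."""
        data = dataclasses.asdict(self)
        data.pop("output_dir")
        text = yaml.safe_dump(data, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def validate_inputs(self) -> None:
        """Fail before any computation if an enabled stage lacks its input."""
        required = {
            "sequence": [("fasta", self.fasta)],
            "glyco": [("glyco_peaklist or terminus_peaklist",
                       self.glyco_peaklist or self.terminus_peaklist)],
            "structure": [("structure_path", self.structure_path)],
            "thermal": [("melt_csv or thermogram_csv",
                         self.melt_csv or self.thermogram_csv)],
        }
        for stage in self.stages:
            for name, value in required[stage]:
                if not value:
                    raise ConfigError(f"stage {stage!r} enabled but {name} not set")
        for path in (self.fasta, self.glyco_peaklist, self.terminus_peaklist,
                     self.structure_path, self.melt_csv, self.thermogram_csv):
            if path and not Path(path).exists():
                raise ConfigError(f"input file not found: {path}")


# ---------------------------------------------------------------------------
# stages


def _stage_sequence(config: RunConfig) -> dict:
    records = seq_mod.read_fasta(config.fasta)
    out = []
    for rec in records:
        annotation = None
        if config.annotate_epo_chains and len(rec) >= seq_mod.EPO_CHAIN_ANNOTATION.heavy_chain[1]:
            annotation = seq_mod.EPO_CHAIN_ANNOTATION
        out.append(seq_mod.annotation_report(rec, annotation,
                                             exclude_proline_x=config.exclude_proline_x))
    return {"records": out}


def _stage_glyco(config: RunConfig) -> dict:
    result: dict = {}
    if config.glyco_peaklist:
        if not config.glyco_peptide:
            raise ConfigError("glyco stage needs glyco_peptide (sequence of the "
                              "sequon-bearing tryptic peptide)")
        start = config.glyco_peptide_start
        pep = seq_mod.Peptide(config.glyco_peptide, start,
                              start + len(config.glyco_peptide) - 1)
        site = config.glyco_site or (start + config.glyco_peptide.index("N"))
        comps = glyco_mod.enumerate_compositions()
        cands = [glyco_mod.GlycopeptideCandidate(pep, site, c) for c in comps]
        peaks = glyco_mod.read_peaklist_csv(config.glyco_peaklist)
        matches, unmatched = glyco_mod.match_peaks(peaks, cands, config.tol_ppm)
        profile = glyco_mod.quantify_glycoforms(matches, site)
        result["glycoforms"] = {"site": site, "fractions": profile.as_dict(),
                                "n_matched": len(matches),
                                "n_unmatched": len(unmatched)}
    if config.terminus_peaklist:
        if not config.terminus_peptides:
            raise ConfigError("glyco stage needs terminus_peptides for the "
                              "terminus peak list")
        variants = [seq_mod.Peptide(s, int(st), int(st) + len(s) - 1)
                    for s, st in config.terminus_peptides]
        peaks = glyco_mod.read_peaklist_csv(config.terminus_peaklist)
        profile = glyco_mod.quantify_chain_termini(peaks, variants, config.tol_ppm)
        result["termini"] = {"fractions": dict(sorted(profile.fractions.items()))}
    return result


def _stage_structure(config: RunConfig) -> dict:
    model = struct_mod.parse_structure(config.structure_path)
    result: dict = {"n_atoms": len(model)}
    bonds, free = struct_mod.find_disulfides(model, config.sg_cutoff)
    result["disulfides"] = {
        "bonds": [{"a": list(b.cys_a), "b": list(b.cys_b),
                   "distance": round(b.sg_distance, 3)} for b in bonds],
        "free_cysteines": [list(f) for f in free]}
    try:
        site = struct_mod.calcium_coordination(model, config.ca_cutoff)
        result["calcium"] = {
            "ion": list(site.ion), "coordination": site.coordination_number,
            "geometry": site.geometry_label,
            "ligands": [[c, r, rn, a, round(d, 3)] for c, r, rn, a, d in site.ligand_atoms]}
    except struct_mod.NoIonError:
        result["calcium"] = None
    try:
        geom = struct_mod.heme_geometry(model, proximal_his=config.proximal_his)
        result["heme"] = {"fe_oop": round(geom.fe_oop, 4),
                          "dome": round(geom.dome, 4),
                          "saddle": round(geom.saddle, 4)}
        links = struct_mod.detect_covalent_links(model, bond_cutoff=config.link_cutoff)
        result["covalent_links"] = [
            {"rule": l.rule, "residue": list(l.residue), "residue_atom": l.residue_atom,
             "heme_atom": l.heme_atom, "distance": round(l.distance, 3)} for l in links]
    except ValueError:
        result["heme"] = None
        result["covalent_links"] = []
    if config.cavity_seed_xyz:
        cav = struct_mod.cavity_volume(model, config.cavity_seed_xyz,
                                       config.grid_spacing, config.probe_radius)
        result["cavity"] = {"volume": round(cav.volume, 1),
                            "open_pocket": cav.open_pocket}
    patches = struct_mod.charge_patches(model,
                                        cluster_radius=config.charge_cluster_radius)
    result["charge_patches"] = [
        {"net_charge": p.net_charge, "n_residues": len(p.residues),
         "residues": [[c, r, rn] for c, r, rn, _ in p.residues]} for p in patches]
    if config.cell and config.molecular_mass:
        a, b, c, al, be, ga, sg = config.cell
        form = struct_mod.CrystalForm(a, b, c, al, be, ga, space_group=sg)
        v_m, solvent = struct_mod.matthews_solvent(form, config.molecular_mass)
        result["matthews"] = {"v_m": round(v_m, 3),
                              "solvent_percent": round(100 * solvent, 1)}
    return result


def _stage_thermal(config: RunConfig) -> dict:
    result: dict = {}
    if config.melt_csv:
        df = pd.read_csv(config.melt_csv)
        curve = thermal_mod.MeltCurve(df.iloc[:, 0].to_numpy(),
                                      df.iloc[:, 1].to_numpy())
        fits = thermal_mod.fit_melt_sigmoid(curve, config.melt_transitions)
        result["melt"] = {"tm": [round(f.tm, 2) for f in fits],
                          "rms_residual": round(fits[0].rms_residual, 5)}
    if config.thermogram_csv:
        df = pd.read_csv(config.thermogram_csv)
        thermo = thermal_mod.Thermogram(df.iloc[:, 0].to_numpy(),
                                        df.iloc[:, 1].to_numpy())
        fits = thermal_mod.fit_dsc_transitions(thermo, config.dsc_transitions)
        result["dsc"] = {"transitions": [{"tm": round(f.tm, 2),
                                          "dh_vh": round(f.dh_vh, 1),
                                          "dh_cal": round(f.dh_cal, 1)}
                                         for f in fits],
                         "rms_residual": round(fits[0].rms_residual, 5)}
    return result


_STAGE_FUNCS = {"sequence": _stage_sequence, "glyco": _stage_glyco,
                "structure": _stage_structure, "thermal": _stage_thermal}


def run_characterization(config: RunConfig) -> dict:
    """Run all enabled stages and write per-stage + summary JSON reports."""
    config.validate_inputs()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("peroxikit %s | config hash %s | seed %d",
                    __version__, config.config_hash(), config.seed)
        summary = {"version": __version__, "config_hash": config.config_hash(),
                   "seed": config.seed, "stages": {}}
        for stage in STAGES:  # fixed dependency order
            if stage not in config.stages:
                continue
            logger.info("running stage %s", stage)
            result = _STAGE_FUNCS[stage](config)
            summary["stages"][stage] = result
            with open(outdir / f"{stage}.json", "w") as fh:
                json.dump(result, fh, indent=2, sort_keys=True)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
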