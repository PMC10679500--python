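"""Glycopeptide mass enumeration, peak matching, and glycoform quantification.

Works on *deconvoluted* peak lists, i.e. neutral monoisotopic masses with
charge states already collapsed, as produced by standard MS deconvolution.
Glycans are handled at the composition level only (counts of HexNAc, Hex,
dHex, NeuAc, Pent); topology assignment is out of scope.

Quantification follows the standard label-free convention for glycoform
profiling: peak intensities of all matched glycoforms at one site are summed
per composition (across peptide variants and missed cleavages) and reported
as fractions of the site total.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import pandas as pd

from .constants import MONOSACCHARIDE_MASS, PROTON_MASS
from .sequence import Peptide, ProteinRecord, peptide_mass, scan_sequons

__all__ = [
    "GlycanComposition",
    "GlycopeptideCandidate",
    "DeconvolutedPeak",
    "PeakMatch",
    "GlycoformProfile",
    "TerminusProfile",
    "enumerate_compositions",
    "glycopeptide_mass",
    "build_candidates",
    "match_peaks",
    "quantify_glycoforms",
    "quantify_chain_termini",
    "mz_to_neutral_mass",
    "read_peaklist_csv",
    "write_peaklist_csv",
]

_SUGARS = ("hexnac", "hex", "dhex", "neuac", "pent")
_SUGAR_LABEL = {"hexnac": "HexNAc", "hex": "Hex", "dhex": "dHex",
                "neuac": "NeuAc", "pent": "Pent"}


class EmptyProfileError(ValueError):
    """Raised when quantification is requested for a site with no matches."""


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide count vector of an N-glycan.

    The canonical text form concatenates ``HexNAc{n}Hex{m}dHex{p}NeuAc{q}
    Pent{r}`` in that order, omitting zero-count sugars; the empty composition
    renders as an empty string.
    """

    hexnac: int = 0
    hex: int = 0
    dhex: int = 0
    neuac: int = 0
    pent: int = 0

    def __post_init__(self) -> None:
        for sugar in _SUGARS:
            if getattr(self, sugar) < 0:
                raise ValueError(f"negative {sugar} count")

    @property
    def mass(self) -> float:
        """Added monoisotopic mass of the glycan (sum of residue masses)."""
        return sum(getattr(self, s) * MONOSACCHARIDE_MASS[s] for s in _SUGARS)

    @property
    def total(self) -> int:
        return sum(getattr(self, s) for s in _SUGARS)

    def __str__(self) -> str:
        return "".join(f"{_SUGAR_LABEL[s]}{getattr(self, s)}"
                       for s in _SUGARS if getattr(self, s))

    @classmethod
    def parse(cls, text: str) -> "GlycanComposition":
        """Parse the canonical text form, e.g. ``'HexNAc2Hex3'``."""
        import re

        counts = dict.fromkeys(_SUGARS, 0)
        pos = 0
        for m in re.finditer(r"(HexNAc|Hex|dHex|NeuAc|Pent)(\d+)", text):
            if m.start() != pos:
                raise ValueError(f"cannot parse composition {text!r}")
            key = next(k for k, v in _SUGAR_LABEL.items() if v == m.group(1))
            counts[key] = int(m.group(2))
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse composition {text!r}")
        return cls(**counts)


def enumerate_compositions(bounds: Mapping[str, int] | None = None,
                           constraints: Callable[[GlycanComposition], bool] | None = None,
                           core_rule: bool = False) -> list[GlycanComposition]:
    """Enumerate all compositions within per-sugar maximum counts.

    Returns the full Cartesian product in deterministic lexicographic order
    over (hexnac, hex, dhex, neuac, pent). ``core_rule`` enforces the
    N-glycan core requirement hexnac >= 2 whenever any other sugar is present;
    ``constraints`` is an arbitrary additional predicate.

    Default bounds (HexNAc<=6, Hex<=10, dHex<=2, NeuAc<=4, Pent<=1) cover
    high-mannose, hybrid, and small complex N-glycans.
    """
    defaults = {"hexnac": 6, "hex": 10, "dhex": 2, "neuac": 4, "pent": 1}
    if bounds is not None:
        unknown = set(bounds) - set(_SUGARS)
        if unknown:
            raise ValueError(f"unknown sugar(s) {sorted(unknown)}")
        defaults.update(bounds)
    if any(v < 0 for v in defaults.values()):
        raise ValueError("bounds must be >= 0")
    out = []
    for counts in itertools.product(*(range(defaults[s] + 1) for s in _SUGARS)):
        comp = GlycanComposition(*counts)
        if core_rule and comp.hexnac < 2 and comp.total > comp.hexnac:
            continue
        if constraints is not None and not constraints(comp):
            continue
        out.append(comp)
    return out


def glycopeptide_mass(pep_mass: float, composition: GlycanComposition) -> float:
    """Neutral monoisotopic mass of peptide + attached glycan."""
    if pep_mass <= 0:
        raise ValueError("peptide mass must be positive")
    return pep_mass + composition.mass


@dataclass(frozen=True)
class GlycopeptideCandidate:
    """A (peptide, site, composition) triple with its theoretical mass."""

    peptide: Peptide
    site: int
    composition: GlycanComposition
    theoretical_mass: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not (self.peptide.start <= self.site <= self.peptide.end):
            raise ValueError(f"site {self.site} outside peptide "
                             f"[{self.peptide.start}, {self.peptide.end}]")
        if self.theoretical_mass == 0.0:
            object.__setattr__(
                self, "theoretical_mass",
                glycopeptide_mass(self.peptide.mass, self.composition))


def build_candidates(record: ProteinRecord, compositions: Sequence[GlycanComposition],
                     missed_cleavages: int = 2, specificity: str = "full",
                     exclude_proline_x: bool = False) -> list[GlycopeptideCandidate]:
    """Cross sequon-containing tryptic peptides with a composition library."""
    from .sequence import digest

    sequons = scan_sequons(record, exclude_proline_x=exclude_proline_x)
    peptides = digest(record, missed_cleavages=missed_cleavages, specificity=specificity)
    out = []
    for hit in sequons:
        for pep in peptides:
            if pep.start <= hit.position <= pep.end:
                for comp in compositions:
                    out.append(GlycopeptideCandidate(pep, hit.position, comp))
    return out


@dataclass(frozen=True)
class DeconvolutedPeak:
    """One neutral-mass peak of a deconvoluted spectrum."""

    neutral_mass: float
    intensity: float

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError("neutral mass must be > 0")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


def mz_to_neutral_mass(mz: float, charge: int) -> float:
    """Collapse an (m/z, z) observation to a neutral mass (proton adducts)."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return mz * charge - charge * PROTON_MASS


@dataclass(frozen=True)
class PeakMatch:
    peak: DeconvolutedPeak
    candidate: GlycopeptideCandidate
    ppm_error: float


def _tie_key(peak_mass: float):
    def key(cand: GlycopeptideCandidate):
        ppm = abs(cand.theoretical_mass - peak_mass) / peak_mass * 1e6
        comp = cand.composition
        return (ppm, comp.total, (comp.hexnac, comp.hex, comp.dhex, comp.neuac, comp.pent),
                cand.peptide.start, cand.peptide.end)
    return key


def match_peaks(peaks: Sequence[DeconvolutedPeak],
                candidates: Sequence[GlycopeptideCandidate],
                tol_ppm: float = 10.0) -> tuple[list[PeakMatch], list[DeconvolutedPeak]]:
    """Assign each peak to its best candidate within a ppm tolerance.

    Each peak goes to the candidate with the smallest absolute ppm error;
    ties break toward fewer total monosaccharides, then lexicographic
    composition. Returns (matches, unmatched peaks); the result is
    independent of the input ordering of peaks and candidates.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    matches: list[PeakMatch] = []
    unmatched: list[DeconvolutedPeak] = []
    for peak in peaks:
        within = [c for c in candidates
                  if abs(c.theoretical_mass - peak.neutral_mass) / peak.neutral_mass * 1e6
                  <= tol_ppm]
        if not within:
            unmatched.append(peak)
            continue
        best = min(within, key=_tie_key(peak.neutral_mass))
        ppm = (peak.neutral_mass - best.theoretical_mass) / best.theoretical_mass * 1e6
        matches.append(PeakMatch(peak, best, ppm))
    return matches, unmatched


@dataclass(frozen=True)
class GlycoformProfile:
    """Per-site intensity fractions over glycan compositions (sum to 1)."""

    site: int
    fractions: Mapping[GlycanComposition, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")

    def fraction(self, composition: GlycanComposition | str) -> float:
        if isinstance(composition, str):
            composition = GlycanComposition.parse(composition)
        return self.fractions.get(composition, 0.0)

    def as_dict(self) -> dict[str, float]:
        return {str(c): f for c, f in
                sorted(self.fractions.items(), key=lambda kv: -kv[1])}


def quantify_glycoforms(matches: Sequence[PeakMatch], site: int) -> GlycoformProfile:
    """Intensity-fraction profile of glycoforms at one Asn site.

    Intensities of all peaks matched to the same composition are summed over
    peptide variants (missed cleavages, ragged termini) before normalizing to
    the site total.
    """
    totals: dict[GlycanComposition, float] = {}
    for m in matches:
        if m.candidate.site == site:
            totals[m.candidate.composition] = (
                totals.get(m.candidate.composition, 0.0) + m.peak.intensity)
    grand = sum(totals.values())
    if grand <= 0:
        raise EmptyProfileError(f"no matched intensity at site {site}")
    return GlycoformProfile(site, {c: v / grand for c, v in totals.items()})


@dataclass(frozen=True)
class TerminusProfile:
    """Intensity fractions of alternative chain-terminal residues (sum to 1)."""

    chain_end: str
    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")

    def fraction(self, residue: str) -> float:
        return self.fractions.get(residue, 0.0)


def quantify_chain_termini(peaks: Sequence[DeconvolutedPeak],
                           terminal_variants: Sequence[Peptide],
                           tol_ppm: float = 10.0,
                           chain_end: str = "C") -> TerminusProfile:
    """Quantify ragged chain-end heterogeneity from terminal peptide variants.

    ``terminal_variants`` are peptides sharing a common N-terminal prefix and
    differing only by C-terminal extension (the ragged-processing model, e.g.
    an ...R-ending and an ...RV-ending light-chain peptide). Each peak is
    matched to the closest variant mass within tolerance; intensities are
    summed per terminal residue and renormalized to 1.
    """
    if len(terminal_variants) < 1:
        raise ValueError("need at least one terminal variant")
    prefix = min((v.sequence for v in terminal_variants), key=len)
    for v in terminal_variants:
        if not v.sequence.startswith(prefix[: min(len(prefix), len(v.sequence))]):
            raise ValueError("terminal variants must share a common prefix")
    totals: dict[str, float] = {}
    for peak in peaks:
        best, best_ppm = None, None
        for v in terminal_variants:
            ppm = abs(v.mass - peak.neutral_mass) / peak.neutral_mass * 1e6
            if ppm <= tol_ppm and (best_ppm is None or ppm < best_ppm):
                best, best_ppm = v, ppm
        if best is not None:
            res = best.sequence[-1]
            totals[res] = totals.get(res, 0.0) + peak.intensity
    grand = sum(totals.values())
    if grand <= 0:
        raise EmptyProfileError("no terminal variant matched any peak")
    return TerminusProfile(chain_end, {r: v / grand for r, v in totals.items()})


# ---------------------------------------------------------------------------
# I/O


def read_peaklist_csv(path) -> list[DeconvolutedPeak]:
    """Read a peak-list CSV with columns neutral_mass,intensity (or mz,charge,
    intensity, collapsed via proton-adduct arithmetic)."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "neutral_mass" in cols:
        masses = df[cols["neutral_mass"]]
    elif "mz" in cols and "charge" in cols:
        masses = [mz_to_neutral_mass(m, int(z))
                  for m, z in zip(df[cols["mz"]], df[cols["charge"]])]
    else:
        raise ValueError("peak list needs a neutral_mass column or mz+charge columns")
    intens = df[cols["intensity"]] if "intensity" in cols else [1.0] * len(df)
    return [DeconvolutedPeak(float(m), float(i)) for m, i in zip(masses, intens)]


def write_peaklist_csv(peaks: Sequence[DeconvolutedPeak], path) -> None:
    pd.DataFrame({"neutral_mass": [p.neutral_mass for p in peaks],
                  "intensity": [p.intensity for p in peaks]}).to_csv(path, index=False)


def matches_to_table(matches: Sequence[PeakMatch]) -> pd.DataFrame:
    return pd.DataFrame({
        "neutral_mass": [m.peak.neutral_mass for m in matches],
        "intensity": [m.peak.intensity for m in matches],
        "peptide": [m.candidate.peptide.sequence for m in matches],
        "site": [m.candidate.site for m in matches],
        "composition": [str(m.candidate.composition) for m in matches],
        "theoretical_mass": [m.candidate.theoretical_mass for m in matches],
        "ppm_error": [m.ppm_error for m in matches],
    })


def profile_to_json(profile: GlycoformProfile) -> str:
    return json.dumps({"site": profile.site, "fractions": profile.as_dict()}, indent=2)
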