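"""Sequence-level annotation of heme peroxidases.

Covers the primary-structure side of the characterization pipeline: N-glycan
sequon scanning, Needleman-Wunsch global identity, peptide masses, isoelectric
point, chain-boundary bookkeeping for the proteolytically processed light and
heavy chains, and in-silico tryptic digestion (full and semi-specific) that
feeds the glycoproteomics stage.

Conventions
-----------
Positions are 1-based and intervals are closed, matching crystallographic
author numbering. Sequences must use the 20 canonical one-letter codes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import (
    AVG_RESIDUE_MASS,
    CANONICAL_AA,
    MONO_RESIDUE_MASS,
    PKA_SETS,
    WATER_AVG,
    WATER_MONO,
)

__all__ = [
    "ProteinRecord",
    "ChainAnnotation",
    "SequonHit",
    "Peptide",
    "scan_sequons",
    "global_identity",
    "peptide_mass",
    "isoelectric_point",
    "net_charge",
    "digest",
    "read_fasta",
    "write_fasta",
    "EPO_CHAIN_ANNOTATION",
    "annotation_report",
]


class SequenceError(ValueError):
    """Raised for non-canonical residues or empty sequences."""


def _validate_sequence(sequence: str) -> str:
    seq = sequence.strip().upper()
    if not seq:
        raise SequenceError("sequence is empty")
    bad = sorted(set(seq) - set(CANONICAL_AA))
    if bad:
        raise SequenceError(
            f"non-canonical residue(s) {''.join(bad)!r}; only the 20 canonical "
            "one-letter codes are accepted"
        )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with accession and free-text description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, end: int) -> str:
        """Extract residues ``start..end`` (1-based, closed interval)."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(f"interval [{start}, {end}] outside [1, {len(self.sequence)}]")
        return self.sequence[start - 1 : end]


Interval = tuple[int, int]


@dataclass(frozen=True)
class ChainAnnotation:
    """Processing-derived chain boundaries of a pre-pro peroxidase.

    The mature enzyme consists of a light (L) and a heavy (H) chain produced
    by excision of a short internal peptide; the N-terminal signal peptide and
    propeptide are removed earlier during biosynthesis. All intervals are
    1-based, closed, and must be disjoint and ordered.
    """

    signal: Interval
    propeptide: Interval
    light_chain: Interval
    excised_peptide: Interval
    heavy_chain: Interval

    def __post_init__(self) -> None:
        intervals = [self.signal, self.propeptide, self.light_chain,
                     self.excised_peptide, self.heavy_chain]
        for lo, hi in intervals:
            if not (1 <= lo <= hi):
                raise ValueError(f"invalid interval [{lo}, {hi}]")
        for (_, hi), (lo2, _) in zip(intervals, intervals[1:]):
            if lo2 <= hi:
                raise ValueError("chain intervals must be disjoint and ordered")

    def validate_against(self, record: ProteinRecord) -> None:
        if self.heavy_chain[1] > len(record):
            raise ValueError("annotation extends beyond sequence length")

    @property
    def mature_intervals(self) -> list[Interval]:
        return [self.light_chain, self.heavy_chain]

    def mature_sequence(self, record: ProteinRecord) -> str:
        return "".join(record.subsequence(lo, hi) for lo, hi in self.mature_intervals)


#: Default chain boundaries for the eosinophil peroxidase precursor (715 aa):
#: 17-residue signal peptide, 121-residue propeptide (19-139; residue 18 is
#: left unassigned by this convention), L chain R140-R244, excised linker
#: V245-G250, H chain V251-T715.  The ragged processing at both linker ends
#: means alternative conventions exist; boundaries are configurable.
EPO_CHAIN_ANNOTATION = ChainAnnotation(
    signal=(1, 17),
    propeptide=(19, 139),
    light_chain=(140, 244),
    excised_peptide=(245, 250),
    heavy_chain=(251, 715),
)


@dataclass(frozen=True)
class SequonHit:
    """One N-X-S/T glycosylation sequon: Asn position and 3-residue window."""

    position: int
    window: str
    occupied: bool = False

    def __post_init__(self) -> None:
        if len(self.window) != 3 or self.window[0] != "N" or self.window[2] not in "ST":
            raise ValueError(f"not a sequon window: {self.window!r}")


def scan_sequons(record: ProteinRecord, exclude_proline_x: bool = False,
                 occupied_sites: Iterable[int] = ()) -> list[SequonHit]:
    """Find all N-X-S/T sequons, in ascending Asn position.

    With ``exclude_proline_x`` set, windows whose central residue is proline
    (which is essentially never glycosylated) are dropped. ``occupied_sites``
    marks known-occupied Asn positions as annotation only.
    """
    occupied = set(occupied_sites)
    seq = record.sequence
    hits = []
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 2] in "ST":
            if exclude_proline_x and seq[i + 1] == "P":
                continue
            pos = i + 1
            hits.append(SequonHit(pos, seq[i : i + 3], occupied=pos in occupied))
    return hits


def _make_aligner(gap_open: float, gap_extend: float, matrix: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_identity(a: ProteinRecord, b: ProteinRecord, gap_open: float = 10.0,
                    gap_extend: float = 0.5, matrix: str = "BLOSUM62") -> float:
    """Percent identity over the full Needleman-Wunsch global alignment.

    Identity is counted as identical aligned positions divided by alignment
    length (gap columns included), times 100. BLOSUM62 with affine gaps
    (open 10, extend 0.5) by default. Among co-optimal alignments the
    aligner's tie-break depends on argument order, so the pair is put in a
    canonical order first; the result is therefore exactly symmetric.
    """
    aligner = _make_aligner(gap_open, gap_extend, matrix)
    first, second = sorted((a.sequence, b.sequence))
    alignment = next(iter(aligner.align(first, second)))
    counts = alignment.counts()
    length = alignment.length
    return 100.0 * counts.identities / length


def global_alignment_score(a: ProteinRecord, b: ProteinRecord, gap_open: float = 10.0,
                           gap_extend: float = 0.5, matrix: str = "BLOSUM62") -> float:
    """Optimal global alignment score under the same scoring as global_identity."""
    aligner = _make_aligner(gap_open, gap_extend, matrix)
    return aligner.score(a.sequence, b.sequence)


def peptide_mass(sequence: str, mode: str = "monoisotopic") -> float:
    """Neutral peptide mass in Da: sum of residue masses plus one water.

    The empty sequence returns the mass of water, which makes the function
    additive over concatenation minus one water per junction.
    """
    if mode == "monoisotopic":
        table, water = MONO_RESIDUE_MASS, WATER_MONO
    elif mode == "average":
        table, water = AVG_RESIDUE_MASS, WATER_AVG
    else:
        raise ValueError(f"mode must be 'monoisotopic' or 'average', got {mode!r}")
    seq = sequence.strip().upper()
    try:
        return sum(table[aa] for aa in seq) + water
    except KeyError as exc:
        raise SequenceError(f"unknown residue {exc.args[0]!r}") from exc


def net_charge(sequence: str, ph: float, pka_set: str | dict = "emboss") -> float:
    """Henderson-Hasselbalch net charge at a given pH.

    Sums the positive contributions of the N terminus, Arg, Lys, and His and
    the negative contributions of the C terminus, Asp, Glu, Cys, and Tyr.
    """
    pka = PKA_SETS[pka_set] if isinstance(pka_set, str) else pka_set
    seq = _validate_sequence(sequence)

    def pos(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pk))

    def neg(pk: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pk - ph))

    charge = pos(pka["n_term"]) + neg(pka["c_term"])
    charge += seq.count("R") * pos(pka["R"])
    charge += seq.count("K") * pos(pka["K"])
    if "H" in pka:
        charge += seq.count("H") * pos(pka["H"])
    for aa in "DECY":
        if aa in pka:
            charge += seq.count(aa) * neg(pka[aa])
    return charge


def isoelectric_point(sequence: str, pka_set: str | dict = "emboss",
                      tol: float = 0.01) -> float:
    """pH at which the Henderson-Hasselbalch net charge crosses zero.

    Found by bisection on [0, 14] to ``tol`` pH units; the charge function is
    strictly decreasing in pH so the root is unique.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class Peptide:
    """A digestion product with 1-based closed coordinates in its parent."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int = 0
    semi: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide coordinates inconsistent with sequence length")

    @property
    def mass(self) -> float:
        return peptide_mass(self.sequence)


def _tryptic_sites(seq: str) -> list[int]:
    """0-based indices *after* which trypsin cleaves (K/R not before P)."""
    return [i for i in range(len(seq) - 1)
            if seq[i] in "KR" and seq[i + 1] != "P"]


def digest(record: ProteinRecord, enzyme: str = "trypsin", missed_cleavages: int = 0,
           specificity: str = "full", min_length: int = 1) -> list[Peptide]:
    """In-silico digest; returns peptides with 1-based coordinates.

    Full specificity cleaves C-terminal of Lys/Arg except before Pro. Semi
    specificity additionally allows one ragged (non-tryptic) terminus inside
    every fully tryptic peptide, which models proteolytic chain ends such as
    the ragged light-chain C terminus.
    """
    if enzyme != "trypsin":
        raise ValueError(f"unsupported enzyme {enzyme!r}")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    if specificity not in ("full", "semi"):
        raise ValueError("specificity must be 'full' or 'semi'")

    seq = record.sequence
    cuts = [-1] + _tryptic_sites(seq) + [len(seq) - 1]
    full: list[Peptide] = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(cuts))):
            start0, end0 = cuts[i] + 1, cuts[j]
            pep = seq[start0 : end0 + 1]
            if len(pep) >= min_length:
                full.append(Peptide(pep, start0 + 1, end0 + 1, missed_cleavages=j - i - 1))
    if specificity == "full":
        return full

    seen: dict[tuple[int, int], Peptide] = {(p.start, p.end): p for p in full}
    for p in full:
        for new_start in range(p.start + 1, p.end - min_length + 2):
            key = (new_start, p.end)
            if key not in seen:
                seen[key] = Peptide(p.sequence[new_start - p.start :], new_start, p.end,
                                    missed_cleavages=p.missed_cleavages, semi=True)
        for new_end in range(p.start + min_length - 1, p.end):
            key = (p.start, new_end)
            if key not in seen:
                seen[key] = Peptide(p.sequence[: new_end - p.start + 1], p.start, new_end,
                                    missed_cleavages=p.missed_cleavages, semi=True)
    return sorted(seen.values(), key=lambda p: (p.start, p.end))


# ---------------------------------------------------------------------------
# FASTA and annotation I/O


def read_fasta(path) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(rec.id, str(rec.seq), rec.description))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path) -> None:
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
                   for r in records]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def annotation_report(record: ProteinRecord, annotation: ChainAnnotation | None = None,
                      exclude_proline_x: bool = False) -> dict:
    """JSON-ready summary: features with coordinates/length/mass plus sequons."""
    features = []

    def add(name: str, lo: int, hi: int) -> None:
        seq = record.subsequence(lo, hi)
        features.append({
            "feature": name, "start": lo, "end": hi, "length": hi - lo + 1,
            "mass_average": round(peptide_mass(seq, "average"), 3),
            "mass_monoisotopic": round(peptide_mass(seq, "monoisotopic"), 6),
        })

    add("full", 1, len(record))
    if annotation is not None:
        annotation.validate_against(record)
        add("signal", *annotation.signal)
        add("propeptide", *annotation.propeptide)
        add("light_chain", *annotation.light_chain)
        add("excised_peptide", *annotation.excised_peptide)
        add("heavy_chain", *annotation.heavy_chain)

    sequons = scan_sequons(record, exclude_proline_x=exclude_proline_x)
    return {
        "id": record.id,
        "length": len(record),
        "isoelectric_point": round(isoelectric_point(record.sequence), 2),
        "features": features,
        "sequons": [{"position": s.position, "window": s.window} for s in sequons],
    }


def annotation_to_tsv(report: dict) -> str:
    lines = ["feature\tstart\tend\tlength\tmass"]
    for f in report["features"]:
        lines.append(f"{f['feature']}\t{f['start']}\t{f['end']}\t{f['length']}\t{f['mass_average']}")
    return "\n".join(lines) + "\n"


def annotation_to_json(report: dict) -> str:
    return json.dumps(report, indent=2)
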