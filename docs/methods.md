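# Methods and design notes

This note records the models, conventions, numerical choices and known
limitations behind peroxikit. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Sequence annotation

**Sequons.** An N-glycosylation sequon is any N-X-S/T window; X is
unrestricted by default because the inventory of candidate sites on the
eosinophil peroxidase precursor (six sites) is defined over the plain
motif. Excluding X = P — essentially never glycosylated in vivo — is
available behind a flag, as annotation rather than occupancy prediction.

**Chain boundaries.** The default precursor annotation is signal 1–17,
propeptide 19–139 (the 121-residue convention; an alternative convention
counts 18–139 = 122 residues and both are expressible since boundaries are
plain intervals), light chain 140–244, excised linker 245–250, heavy chain
251–715. Proteolytic processing of the linker is ragged at both ends
(...R244/V245 and G250/V251...), so mature-chain residue counts are
reported from the chosen intervals, never hard-coded: the conventional
"568-residue mature protein" figure is not exactly reproduced by any single
boundary choice, and the package makes the arithmetic explicit instead.

**Global identity.** Needleman–Wunsch with BLOSUM62, gap open 10, gap
extend 0.5 (Biopython `PairwiseAligner`); identity = identical columns /
alignment length × 100, gap columns included. Published identity figures
for these proteins come from tools whose exact parameters are not stated,
so ±2 percentage points is the meaningful comparison window. Among
co-optimal alignments the aligner's tie-break depends on argument order;
the sequence pair is put in canonical order first so the function is
exactly symmetric.

**Masses and pI.** Residue masses are embedded constants derived from
elemental formulas (monoisotopic water 18.010565 Da); a peptide is the sum
of residue masses plus one water. The isoelectric point solves the
Henderson–Hasselbalch net-charge equation by bisection on pH ∈ [0, 14] to
0.01 units; the charge function is strictly decreasing so the root is
unique. The default pKa table is EMBOSS-style, with the Sillero set
selectable — pI values are pKa-set dependent by ~0.2–1 unit, which is why
coarse assertions (e.g. "pI ≥ 10" for a strongly basic protein) are the
right granularity.

**Digestion.** Trypsin cleaves after K/R except before P. `full`
specificity with n missed cleavages merges up to n+1 adjacent fragments;
`semi` additionally emits every sub-peptide of a fully tryptic peptide that
keeps one tryptic terminus, which is the standard way ragged,
processing-derived chain ends (such as a light chain ending at either
...R or ...RV) become observable in a bottom-up digest.

## Glycoproteomics

Peak lists are neutral deconvoluted monoisotopic masses; raw m/z handling
is limited to a (m/z, z) → M collapse with the proton mass 1.007276 Da.
Monosaccharide residue masses come from elemental formulas: Hex C6H10O5
162.052824, HexNAc C8H13NO5 203.079373, dHex C6H10O4 146.057909, NeuAc
C11H17NO8 291.095417, Pent C5H8O4 132.042259.

Matching assigns each peak independently to the candidate with the smallest
|ppm error| within tolerance (default 10 ppm, Orbitrap-class accuracy);
ties break toward fewer total monosaccharides, then lexicographic
composition, making the result independent of input order. Quantification
sums matched intensities per composition across peptide variants at a site
and normalizes to the site total; profiles therefore always sum to 1.
Reported two-figure shares that add to slightly more than 100% (a known
printing artifact for the light-chain terminus, 77.2% + 23.8%) are always
renormalized.

Default composition bounds (HexNAc ≤ 6, Hex ≤ 10, dHex ≤ 2, NeuAc ≤ 4,
Pent ≤ 1) cover high-mannose, hybrid and small complex N-glycans; the
HexNAc≥2-core rule is available but off by default so that the candidate
space is not silently constrained.

## Structure analytics

Parsing goes through Bio.PDB (PDB and mmCIF); alternate locations resolve
to the highest-occupancy conformer. Coordinates are Å, residue numbers are
author numbering. Geometry outputs are rigid-motion invariant by
construction and verified by random-transform property tests.

* **Disulfides**: greedy nearest-pair matching of Cys Sγ atoms under a
  2.5 Å cutoff; each cysteine joins at most one bond; leftovers are
  reported free.
* **Ca²⁺ site**: all oxygen atoms (side chain, backbone, water) within
  2.9 Å. A 7-coordinate shell is labelled pentagonal-bipyramidal when the
  widest ligand pair is within 15° of linear and the other five ligands lie
  within 15° of the equatorial plane.
* **Heme geometry**: least-squares plane (SVD) through the 24 macrocycle
  atoms (4 pyrrole N + 20 ring C). Fe_oop is the signed Fe deviation,
  positive toward the proximal His Nε2 (without a reference His the
  convention is Fe_oop ≥ 0, adequate for |Fe_oop| surveys). Dome is the
  mean signed pyrrole-N deviation; saddle is (1/8)|Σ sᵢ dᵢ| over the eight
  β-carbons with signs (+,+,−,−,+,+,−,−). These amplitude definitions are
  one reasonable operationalization of the qualitative dome/saddle modes;
  a normal-coordinate decomposition would be the heavier alternative.
* **Covalent links**: rule-driven short contacts (≤1.8 Å) — Asp/Glu
  carboxylate O vs heme methyl C for the ester links, Met Sδ vs vinyl C
  for the MPO-type sulfonium.
* **Cavity volume**: grid flood fill; points ≥ probe radius (1.4 Å) from
  every atom center are free; the seed's 6-connected component gives
  volume = count × spacing³. A component reaching the bounding box flags an
  open pocket with the truncation radius reached. The method is validated
  against the analytic volume of a sphere (±10% at 0.5 Å spacing) and by
  grid-refinement convergence; it is *not* expected to reproduce
  pocket-detection-software volumes, which are method-specific.
* **Charge patches**: per-atom Shrake–Rupley point-sampling SASA (120
  points, probe 1.4 Å); a residue is exposed above 20% relative
  accessibility (Tien et al. maxima). Exposed Arg/Lys (+1), Asp/Glu (−1),
  optionally His (+0.5) are single-linkage clustered by charged-group
  centroid within 8 Å and ranked by |net charge|. This is a deliberately
  simple surrogate for continuum electrostatics: it identifies charged
  surface clusters, not potentials.
* **Matthews coefficient**: V_M = V_cell/(Z·M) with the general triclinic
  cell-volume formula; solvent fraction 1 − 1.23/V_M, clamped to [0, 1]
  with a warning when outside the physical range.

## Thermal unfolding

Inputs are °C; kelvin is used internally for every exponential. Melt fits
use a linear baseline plus logistic steps (optionally a post-transition
slope); DSC fits use the non-two-state excess heat capacity (README
formula) plus a co-fitted linear baseline. Both use
`scipy.optimize.least_squares` with deterministic multi-start
initialization (melt: Tm grid over the data range; DSC: starts anchored on
the endotherm maximum plus a span grid) and the best RMS wins, with
parameter scaling so the very different magnitudes (baseline, Tm,
enthalpies) condition the trust-region steps. Melt fits bound widths to
[one grid step, span/3] and amplitudes to ±3× the signal range, which
excludes a degenerate spike solution (two large cancelling transitions at
the same Tm) that can otherwise absorb noise.

The equilibrium model is an *effective* description: thermal unfolding of
these proteins is irreversible, so fitted Tm and enthalpies are apparent
quantities — the same convention the instrument software uses.
Identifiability caveat measured here by simulation: for two transitions
only 3 °C apart with ΔH_vH ≈ 120–150 kcal/mol and 2% amplitude noise, the
lower Tm has an RMSE of ~0.8 °C while the upper Tm is recovered to ~0.25 °C;
for well-separated transitions both recover with |bias| and RMSE < 0.1 °C.
For optical melts at SNR 20 the per-seed maximum-likelihood Tm scatter is
~0.25 °C (1σ, matching the fit covariance), so two-transition recovery is
asserted as an RMSE over seeds rather than a per-realization guarantee.

## Synthetic data

Every generator draws from its own sub-stream (SeedSequence of
[spec seed, component id]), so adding a component never perturbs another,
and identical specs produce bit-identical files; each generator emits a
truth record consumed by the recovery tests.

* **Glycopeptide peak lists**: one peak per composition at the theoretical
  mass perturbed by a relative error drawn from Normal(0, σ_ppm) *truncated
  at 2σ* (resampled), intensity ∝ fraction × (1 + Normal(0, CV)) with
  non-positive draws resampled. The truncation keeps every generated peak
  identifiable at the standard matching tolerance of twice the mass
  accuracy; without it ~4.6% of peaks would be silently censored by the
  matcher and the recovered fractions biased, which contradicts what the
  generator is for (known-truth recovery). Effective σ is 0.88× nominal.
* **Default stated world**: site glycoform fractions use the reported
  major species (Asn363: HexNAc2Hex3 48%, HexNAc2Hex6 30%; Asn327:
  HexNAc2Hex4 36%, HexNAc2Hex3 18.5%, HexNAc2Hex5 19%, HexNAc2Hex6 14%),
  with the unreported remainder assigned once to neighboring high-mannose
  compositions (Asn363: Hex4 12%, Hex5 10%; Asn327: Hex7 12.5%) so that a
  reported share is a share of the site total. The terminus mixture uses a
  77.2/22.8 arginine/valine split (the printed 77.2/23.8 renormalized).
  The stand-in tryptic peptide sequences are synthetic: recovery statistics
  depend only on peptide mass, and the study's peptide sequences are not
  reproduced here.
* **Thermograms/melts**: forward model + linear baseline + additive
  Gaussian noise scaled to the peak amplitude (DSC default 2%, i.e. SNR 50;
  melt default 1%). Defaults: DSC transitions 82/85 °C with 120/150
  kcal/mol; melt Tm 70 °C, width 2 °C. Enthalpies for the DSC pair are
  plausible values for a ~70 kDa protein, not measured quantities.
* **Toy structures**: legal PDB naming; planted Cys pairs at 2.03 Å Sγ
  separation, an ideal 7-oxygen pentagonal bipyramid at 2.4 Å around Ca²⁺,
  an idealized porphyrin whose doming displaces the four N by 1.2×dome
  (so the refit-plane metric returns exactly `dome`), saddling displaces
  the eight β-carbons by ±saddle (plane-neutral by symmetry), Fe placed
  `fe_oop` above the shifted plane, plus optional Asp-carboxylate ester
  plant and isolated surface lysines. Cross-component contacts < 1 Å raise
  a clash error.

What the generators do **not** emulate: isotope envelopes, charge-state
deconvolution errors, chromatographic or in-source artifacts, real protein
packing/secondary structure in toy coordinates, scan-rate effects and
irreversibility in calorimetry. A green recovery test therefore
establishes that the analysis inverts its own stated forward model at the
stated noise — not that the models capture every feature of instrument
data.

## Real-data checks

The checks against the published sequences and structures (sequon
positions, mature-protein identity, Matthews bookkeeping from the crystal
cell plus sequence mass, the disulfide/Ca/ester inventory of the 1.6 Å
structure, and the Fe out-of-plane survey vs myeloperoxidase entries) need
the UniProt and PDB files. `peroxikit.fetch` downloads them into a cache
(`PEROXIKIT_DATA_DIR`, default `~/.cache/peroxikit`) and reuses cached
copies; fully offline without a cache these tests fail with an explanatory
message — by design they do not silently pass or skip. The Fe survey
restricts comparison entries to resolutions better than 2.5 Å without
covalent active-site modifications and reports the per-entry table; which
entry shows which displacement is not itemized upstream, so the check is a
range check on the median.
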