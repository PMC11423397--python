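# Methods

## The ion model and oxidation-state bookkeeping

All species are elemental compositions. Backbone fragments follow the
standard series rules: b_i = N-terminal residues 1..i plus a proton,
a_i = b_i − CO, y_j = C-terminal residues plus H2O plus a proton, and
z_j = y_j − NH3 (even-electron deamination product; the radical z• is not
generated). y″ in printed labels is notation for the ordinary y ion, not
extra hydrogens.

Coordination of a charged vanadium unit replaces protons as charge
carriers, which is visible in the sum formula of the ion. The formal
vanadium oxidation state of a single-V ion therefore follows from charge
balance alone:

    z = n_protons + OS − 2·n_oxo − n_ligands

where n_protons counts all protons the label implies. The label
convention is: fragment symbols (b6, y4″, z5, …) denote the canonical
singly protonated ion and hence contribute one proton; whole-peptide
symbols (M, AT, AT1, AT2) denote the neutral molecule; "± nH" terms are
relative to that. This convention is the one that reproduces every
reported fragment oxidation state and the reduced/oxidized precursor
pair [AT + V(IV)OL + H]2+ / [AT + V(V)OL]2+, and is locked by tests. The
plausible OS set is {+3, +4, +5} (the physiologically relevant window);
candidates outside it are dropped unless explicitly requested.
Multimetalated candidates are enumerated for full-MS annotation but
carry no per-V oxidation state.

Neutral adduct species (the currency of deconvoluted spectra) displace
q = OS − 2·n_oxo − n_ligands protons from the peptide: [AT + VO] is
AT + VO − 2H (V(IV)), [AT + VO2] is AT + VO2 − H (V(V)), [AT + VOL] is
AT + VOL − H and [AT + VOL2] is AT + VOL2.

Masses use the NIST atomic masses bundled with pyteomics; monoisotopic
masses are used for all matching (Orbitrap-class data), the average mass
is exposed but never matched against. m/z subtracts one electron mass
per charge (sub-ppm effect at these masses, but systematic). Isotope
patterns are computed by per-element polynomial convolution (binary
exponentiation) with pruning, merging peaks closer than 0.05 Da —
a unit-resolution model that is adequate for the ±1 H overlap analysis
and deliberately ignores fine structure.

## Pipeline conventions

**Tolerance.** The default matching tolerance is 10 ppm, configurable
everywhere. It is a design choice for high-resolution Orbitrap data; no
per-peak experimental ppm errors are bundled with the package.

**Deconvolution** is greedy charge-state clustering over z = 1–4, not a
full charge-deconvolution algorithm. Per-peak charges are used when the
input provides them. Otherwise charges are inferred from isotope-envelope
spacing (neighbours at 1.00335/z Da, scanned from high z to low so a z=2
envelope is not read as interleaved z=1 chains), then by cross-charge
corroboration (two interpretations agreeing on one neutral mass within
tolerance), and finally default to the smallest allowed charge. Neutral
masses within tolerance are merged to intensity-weighted centroids.

**Abundance tables** report % of the free-peptide base peak. The summed
intensity of a species covers its whole isotope envelope, not only the
monoisotopic cluster; otherwise ratios would be biased by the
composition-dependent monoisotopic fraction (about 10 % relative for a
+VOL2 adduct versus the bare peptide at ~1 kDa).

**Matching** assigns each peak to the candidate with the smallest |ppm|
error; ties break toward fewer proton adjustments, then toward OS closest
to +4. A candidate may additionally claim up to two heavier isotopologue
peaks, but monoisotopic interpretations always outrank isotopologue
claims: the +1 isotopologue of an ion one hydrogen lighter falls only
~2 mDa below a mono peak (1.00783 vs 1.00335 spacing) and must not steal
it. That near-coincidence is exactly the V(IV)/V(V) ambiguity, which is
resolved quantitatively (not per peak) by non-negative least squares:
the two theoretical envelopes of the +1H (reduced) and oxidized forms
are fitted to the observed cluster; fractions are normalized to sum to
one and are invariant to global intensity scaling.

**Fragmentation maps** average per-spectrum percentages (each MS²
spectrum normalized to its own base peak) across the spectra of the
NCE 20–35 window; spectra lacking a fragment contribute zero to its
average. Whether to pool before or after normalizing is a genuine
convention choice; this one is applied consistently and documented here.
The display classes use a strict 1.0 % threshold: exactly 1.0 % is
minor. Stability profiles use the whole 0–35 grid in steps of 5;
survival is precursor intensity over total assigned intensity.

**Localization** uses interval logic with 1-based inclusive residue
numbering: a metalated a_i/b_i constrains the site to residues 1..i, a
metalated y_j/z_j to residues (n−j+1)..n; the result is the intersection,
with a per-residue evidence score summing the abundances of covering
metalated fragments. Contradictory constraints (as produced by a peptide
with two binding residues) set a conflict flag and report both the
N-terminal and C-terminal candidate intervals — the multi-site
interpretation. Precursors carrying more than one metal are excluded
from localization.

## The synthetic-data generator

The generator's defaults are the study conditions the package is tested
under. Full-MS presets plant the tabulated speciation of each of the six
peptide/ligand systems (e.g. AT2/pic: VOL 2.82, VOL2 1.92, VO 5.32,
VO2 0.16, free peptide 100). Charges 1 and 2 carry weights 0.45/0.55,
m/z jitter is Gaussian with σ = 2 ppm, intensities get 1 % multiplicative
noise, and 50 spurious peaks with exponential intensities form the noise
floor. These last four numbers are free choices of realistic
Orbitrap-style nuisance; they are fixed once and shared by tests and the
acceptance script.

MS² series use logistic precursor survival in NCE with per-ligand
presets calibrated qualitatively to the reported behaviour: dhp
complexes detach whole at comparatively high survival midpoint (18) and
mostly release the free peptide (detach fraction 0.7); ma (midpoint 12)
and pic (midpoint 10, detach fraction 0.1) lose their ligands early so
[AT + VO] dominates the metalated channels; backbone fragmentation
switches on around NCE 28. The metal-retention rule is structural: a
fragment retains the (post-ligand-loss) [VO] moiety exactly when it
contains a planted binding residue, splitting proportionally when the
binding residues straddle the cleavage. Oxidation channels get fixed
weights (V(IV) 0.85 / V(III) 0.10 / V(V) 0.05; z-series fragments biased
to V(III) 0.85). All draws come from one numpy Generator seeded per run;
the draw order (per-channel jitter, then intensity noise, then noise
peaks) is fixed, so spectra are bit-reproducible across platforms.

What the simulator does *not* emulate: real collision-energy chemistry,
proton-mobility sequence effects, isolation-window co-selection,
detector saturation, or profile-mode peak shapes. Passing round-trip
tests therefore demonstrates that the analysis is self-consistent and
numerically correct under the stated statistical structure — not that it
would reproduce the tabulated abundances from raw instrument files,
which are not publicly deposited.

## Thermo/geometry arithmetic

G_aq = E_ele + G_therm + ΔG_solv, assembled in kcal/mol with
hartree → kcal/mol = 627.5095 and T = 298.15 K unless overridden. The
standard-state term RT ln(24.46) = 1.894 kcal/mol can be applied per
species or once per unit of net reaction molecularity — the convention
is not fixed by the arithmetic, so both are exposed behind a flag.
Reaction ΔG is linear in stoichiometry and antisymmetric under
reactant/product exchange (property-tested). Component energies for the
tabulated ligand-exchange reactions are not public: ΔG values are
exercised through constructed fixtures only and are never claimed as
recomputed physics; the same holds for calculated A_z values, which
require quantum chemistry.

Percent deviation of hyperfine couplings is computed on magnitudes,
PD = 100·(|A_z| − |A_z,exptl|)/|A_z,exptl|, rounded to one decimal. Two
formula variants circulate (signed ratio vs absolute values); the
absolute-value form is implemented because it reproduces the
conventional sign of every tabulated deviation for these (negative)
vanadyl couplings. Donor–donor distances use the law of cosines
d = √(d1² + d2² − 2 d1 d2 cos θ), with the degenerate limits |d1−d2|
(θ→0) and d1+d2 (θ→180°).

## Numerical and edge-case choices

* Compositions are immutable; subtraction below zero raises rather than
  clamping.
* Isotope patterns prune below the probability threshold and renormalize
  to Σ = 1 (±1e-9, tested).
* Deconvolution of an empty spectrum returns an empty spectrum; an
  all-zero envelope cluster is an error for the NNLS fit.
* CSV is the fixture dialect (2–3 numeric columns, `#` comments); MGF
  round-trips all metadata used here; mzML is read through a minimal
  reader for centroided spectra (uncompressed or zlib 32/64-bit float
  arrays) and is not written.
* Problem sizes in tests and the acceptance script: 20-seed full-MS
  round trips, 100-seed Monte-Carlo checks for redox fractions and
  localization — sizes chosen so the whole suite completes in well under
  a minute while keeping Monte-Carlo assertions meaningful.

## Known limitations

* No modifications, non-standard residues, internal fragments, immonium
  ions, or neutral losses beyond CO/NH3.
* Negative-mode adducts are out of scope.
* The greedy deconvolution can mis-charge isolated singleton peaks with
  no corroborating evidence (they default to the smallest allowed
  charge).
* Oxidation-state bookkeeping is formal electron counting from the sum
  formula; it says nothing about mechanism and is undefined for
  multi-vanadium ions.
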