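# Methods

This note records the models, conventions, numerical choices and known
limitations behind `msbind`, in the order data flows through the package.

## Lipid chemistry

Masses are computed from elemental formulas with IUPAC standard atomic
weights baked in at four decimal places, so results never depend on an
external table. Lipids are modeled as free acids, not salts: the ~863 Da
adduct spacing observed on a delipidated ~58 kDa transporter matches the
free-acid average mass of di-18:1 phosphatidylinositol (C45H83O13P,
863.12 Da). Whether observed adducts are protonated or deprotonated is not
determinable from adduct spacing alone; the free-acid convention is a
package decision. The phosphoinositide ladder PI → PI(4)P → PI(4,5)P2 → PIP3
is constructed by exact HPO3 (79.98 Da) increments, so ladder spacing is
exact by construction. Average (not monoisotopic) masses are used
throughout the MS layer: at ~58 kDa and instrument resolution of order 10⁴,
isotopes are unresolved. No isotope patterns or MS/MS fragments are modeled.

## Native-MS peak analysis

*Peak picking.* The noise floor is median + `min_snr` × 1.4826·MAD of the
profile. Centroid windows are partitioned at the intensity minimum between
adjacent apexes (no sample is counted twice), bounded by the contiguous
region above 10% of the baseline-subtracted apex, and capped at
2×`min_spacing` per side; centroids closer than `min_spacing` merge by
intensity-weighted mean. `min_spacing` should be set near the observed peak
FWHM (≈ 4–6 Th for the simulated 58 kDa spectra).

*Deconvolution.* Positive-ion convention m/z = (M + z·1.00728)/z. Every
(peak, charge) pair proposes a candidate mass; candidates are refined by an
intensity-weighted average of the implied masses, scored by matched
charge-state count then total matched intensity, and accepted greedily.
Candidates sharing more than half their matched peaks with an accepted
series (harmonics, subset series) are suppressed; ties break by longest
contiguous charge run, then lower mass. At least three matched charge
states are required; otherwise the result is empty with a logged
diagnostic. With adduct-laden spectra each stoichiometry forms its own
series; the apo series is the lowest-mass accepted one.

*Adducts and mole fractions.* Matching happens in neutral-mass space with a
±3 Da default tolerance; each observed peak is assigned to at most one
(lipid, stoichiometry), ties resolved by smallest |residual|. A peak is
flagged ambiguous only when a second distinct (lipid, k) matches within
half the tolerance of the best option — i.e. when residuals genuinely
cannot discriminate. Mole fractions are x_k = I_k / Σ I_j; the default
aggregates intensities across all charge states ("summed"), with a
per-charge mode retained because single-charge-state quantification is
also common practice. No ionization-efficiency correction is applied
between apo and bound species — the same assumption the intensity-based
mole-fraction method always makes.

*Statistics.* All replicate comparisons use two-tailed unpaired Welch
t-tests with significance stars at 0.05/0.01/0.001/0.0001. Groups with
zero variance on both sides and equal means give p = 1; unequal means with
zero variance on both sides are flagged degenerate and the test is skipped
with a warning.

## Sequential binding equilibria

Stepwise constants are defined against free ligand; depletion is handled by
solving the scalar mass balance with Brent's method on [0, L_tot], where the
root is bracketed analytically (the balance is −L_tot at 0 and non-negative
at L_tot). Solutions satisfy Σx_i = 1 to 1e-9 and the mass balance to
1e-6·max(1, L_tot); an independent bisection oracle in the test suite
confirms agreement to 1e-8 over 1,000 random instances.

Fitting runs in log10-K_D space, bounds [1e-3, 1e4] µM, from 8
ladder-structured starts with K_D1 spanning 1e-2–1e3 µM; ties among optima
break by lowest SSE then lowest K_D1. Estimates within 1e-3 log-units of a
bound are flagged unidentified. R² = 1 − SSE/SST with SST about the grand
mean over all species curves — a single pooled statistic per fit. Standard
deviations come from a leave-one-replicate-out jackknife; whether published
"±" values are replicate SDs or fit standard errors is generally ambiguous,
and the jackknife is this package's choice. Site-count selection uses
small-sample-corrected AIC over n = 1..4, with an SSE floor of 1e-20 per
observation so that exact synthetic data (SSE = 0) still selects the most
parsimonious model. A table that never leaves the apo state fits with all
constants at the upper bound and is flagged "no binding".

## HDX analysis

N_max = length − 1 − (prolines after the first residue); the first amide is
treated as fully back-exchanged, the standard convention of commercial HDX
processing software. No back-exchange correction is applied — RFU is a
relative quantity. Per-cell significance is a Welch t-test at α = 0.05 with
no multiple-testing correction by default, matching per-peptide star
annotations in the field; a Benjamini–Hochberg option exists. The synergy
statistic S is a four-group linear contrast; its variance is the sum of the
four group variances of the mean, with Welch–Satterthwaite degrees of
freedom, and both one-sided (S > 0) and two-sided p-values are reported.

Region-level synergy inference (`pool_synergy`) weights peptides by N_max²,
the known design precision (RFU noise is uptake noise divided by N_max),
rather than by n = 3 sample variances, which are too unstable to weight by.
Residue projection offers a transparent mean over covering peptides
(default) and a sharper shortest-covering-peptide mode; coordinates are
1-based inclusive throughout, and the B-factor output clamps values to
[−9.99, 99.99] with missing residues written as 0.00 at zero occupancy.

## Synthetic data

The generators emit exactly the statistical structure the analysis assumes,
plus a truth record, so every stage is testable by recovery.

*Titrations.* Presets carry the published first dissociation constants for
the transporter system the package emulates: PI(4,5)P2 0.7 µM (full-length)
and 9.9 µM (N-terminally truncated), ~6 µM for PI, PI(4)P and PIP3, and PE
20-fold weaker than PI (120 µM). The design is 12 concentrations 0–50 µM at
P_tot = 5 µM with n = 3 (the PE grid is scaled ×12 to 0–600 µM to bracket
its weaker constant). Higher-order constants are not printed in the source
text; presets use a geometric ladder K_D(i+1) = 2·K_Di, the ratio chosen so
that all four PI binding events exceed a 2% mole fraction at 20 µM lipid —
the detectability reported for the real system (a 3× ladder would push the
fourth event below detection there). Noise is multiplicative Gaussian
(CV 5% by default) on species intensities before renormalisation, so rows
remain exact mole fractions.

*Spectra.* Gaussian peaks (σ = 1.5 Th) at (M + Σk·m_lipid + z·m_p)/z under a
Gaussian charge envelope, over a 0.25 Th grid with a positive-offset
baseline (3σ_noise ± σ_noise); every emitted peak is traceable to a
(protein, z, k) inventory row. Ionization physics (transmission, micelle
stripping, activation) is deliberately not modeled.

*HDX.* A deterministic 549-residue stand-in sequence carries a 12-TM
major-facilitator topology: helices split into extracellular/cytoplasmic
halves where ligand effects are side-specific, two cytoplasmic interdomain
helices, and an N-terminal tail with an arginine patch at 23–28. Each
residue exchanges as 1 − exp(−kt): loops at 0.04 min⁻¹ (RFU ≈ 0.9 at
60 min), helix cores at 0.006 min⁻¹ (≈ 0.3 at 60 min), and TM8 with a fast
subpopulation (every third residue at 0.8 min⁻¹) so that protection there
is visible within 1 min. Ligand effects are per-segment rate multipliers:
the substrate protects TM8 (×0.1) and deprotects the extracellular gate
(TM1e/L1-2/TM2e/TM7e ×2); the signalling lipid protects the N terminus and
cytoplasmic face (×0.3) and deprotects extracellular helix ends (×1.7). In
the ternary state, gate segments where both ligands act get a rate boost of
1.5× the additive prediction; TM6e and TM12e carry ternary-only multipliers
(1.8, 1.4) because their opening is specific to the ternary complex;
everywhere else multipliers combine multiplicatively, which reduces to the
single-ligand effect where only one ligand acts and makes S ≈ 0 the
expected null outside the gate. An `additive_ternary` mode instead
constructs the ternary mean uptake as D_S1P + D_PIP2 − D_apo, an exact null
for the synergy statistic. Peptides tile the sequence (lengths 8–16, offset
5) plus fixed landmark peptides mirroring the uptake-plot panels of the
emulated study and one spanning peptide per segment; replicate noise is
Gaussian with SD 0.15 Da truncated to [0, N_max].

What the generator does not emulate: back-exchange, EX1/bimodal kinetics,
intrinsic-rate sequence dependence, peptide misidentification, and
ionization bias. Passing tests therefore demonstrate correctness of the
analysis chain under its stated assumptions, not robustness to every
artefact of real data.

## Problem sizes

The shipped tests and the acceptance script run at desk scale by design:
titrations are 12 concentrations × 3 replicates, spectra a few thousand
profile points, HDX tables ~7,000 rows (144 peptides × 4 states × 4
exposures × 3 replicates), and the solver/oracle cross-check uses 1,000
random instances. Each fit takes well under a second on one CPU.

## Known limitations

Competitive-binding occupancies for the competition preset use totals as
free concentrations (no multi-ligand depletion solve). Detergent
partitioning of lipid is ignored (total aqueous lipid = available lipid),
as in the analysis the package emulates. The deconvolution scorer assumes
reasonably complete charge series and can mis-rank heavily gapped series in
crowded mixtures. Raw instrument files (mzML) are not parsed — peak lists
are the entry point; this is a documented extension point, not a goal.
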