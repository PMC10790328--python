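# msbind

Quantitative lipid-binding and conformational-dynamics analysis for membrane
transporters studied by native mass spectrometry and HDX-MS.

Native MS of an intact transporter electrosprayed from a non-denaturing
detergent buffer resolves each lipid-binding event as a mass adduct on the
protein's charge states. Titrating a lipid against a fixed protein
concentration and converting peak intensities into bound-state mole fractions
yields stepwise dissociation constants — provided the analysis accounts for
ligand depletion, because the protein (typically 5 µM) is comparable in
concentration to the tightest K_D values being measured. Complementary
time-resolved hydrogen–deuterium exchange reports where on the protein a
ligand changes backbone dynamics, and whether two ligands act synergistically.
`msbind` implements both analysis chains end to end, plus a synthetic-data
generator that makes every stage verifiable by blind parameter recovery.

## The models

**Sequential ligand binding with depletion.** A protein P binds up to n
lipids L in sequential steps P·L(i−1) + L ⇌ P·L(i) with stepwise constants

    K_Di = [P·L(i−1)][L] / [P·L(i)]            (i = 1..n, free-ligand convention)

so the mole fraction of the i-bound species is
x_i = ([L]^i / ∏_{j≤i} K_Dj) / Σ_k ([L]^k / ∏_{j≤k} K_Dk), with the free
ligand [L] the unique non-negative root of the mass balance

    [L] + P_tot · Σ_i i·x_i([L]) = L_tot.

`fit_kds` minimises squared residuals between predicted and observed mole
fractions over all species and concentrations jointly, in log10-K_D space with
multi-start optimisation; replicate scatter feeds jackknife standard
deviations, and one pooled R² summarises the fit.

**Charge series and adducts.** In positive mode a species of neutral mass M
appears at m/z = (M + z·m_p)/z. `deconvolve_mass` scores candidate masses by
the number and intensity of matched charge states; `assign_lipid_adducts`
matches satellite peaks to M₀ + k·m_lipid ladders (default tolerance ±3 Da in
neutral-mass space — unambiguous against the ~80 Da phosphoinositide
phosphate spacing).

**HDX differential and synergy.** Relative fractional uptake is
RFU = D_t / N_max with N_max = length − 1 − (prolines after the first
residue). Differences versus apo (ΔRFU) are tested per peptide and exposure
with two-tailed unpaired Welch t-tests (α = 0.05). The two-ligand synergy
statistic is

    S = ΔRFU(ternary) − [ΔRFU(ligand A) + ΔRFU(ligand B)],

with S > 0 meaning the ligands together perturb a region more than the sum of
their individual effects.

## Worked example

```python
from msbind.binding import fit_kds
from msbind.simulate import TITRATION_PRESETS, gen_titration

preset = TITRATION_PRESETS["fl-pip2"]          # PI(4,5)P2 on the full-length transporter
table, truth = gen_titration(preset, seed=42)  # 12 concentrations x 3 replicates, 5% noise
fit = fit_kds(table, n_sites=4, p_tot=5.0)
```

This prints (via `examples/fit_titration.py`):

```
simulated 36 rows (truth K_D1 = 0.7 uM)
K_D1 =   0.72 +- 0.02 uM
K_D2 =   1.42 +- 0.02 uM
K_D3 =   2.80 +- 0.08 uM
K_D4 =   5.68 +- 0.15 uM
R2 = 0.9992
```

K_D1 ≈ 0.7 µM is the first (tightest) binding event recovered from noisy mole
fractions; the later constants follow the preset's geometric ladder, and the
pooled R² close to 1 says the sequential model explains all five species
curves jointly.

The other scripts in `examples/` each exercise one capability end to end:
`spectrum_to_fractions.py` (profile spectrum → centroids → zero-charge mass →
adduct stoichiometries → mole fractions), `competition_ranking.py` (equimolar
head-group competition with pairwise t-tests), and
`hdx_differential_synergy.py` (four-state HDX: early TM8 protection by the
substrate, and pooled synergy across the extracellular gate segments).

## Command line

A thin CLI mirrors the library: `msbind simulate`, `peaks-deconvolve`,
`fit-kd`, `compete`, `mixture-ratio`, `hdx-diff`, `hdx-synergy`,
`project-structure` (per-residue ΔRFU into a PDB B-factor column), and
`report` (TOML-configured end-to-end pipelines). All randomness flows from an
explicit `--seed`; outputs are diff-able CSVs plus a JSON run log.

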