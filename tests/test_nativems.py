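"""Peak picking, charge-series deconvolution, adducts, and replicate statistics."""

import numpy as np
import pandas as pd
import pytest

from msbind import chem, nativems, simulate
from msbind.binding import solve_equilibrium
from msbind.chem import PROTON_MASS
from msbind.nativems import PeakList

from conftest import exact_series_peaks


def gaussian_profile(centers, amplitudes, sigma=1.0, span=30.0, step=0.05):
    lo = min(centers) - span
    hi = max(centers) + span
    mz = np.arange(lo, hi, step)
    inten = np.zeros_like(mz)
    for c, a in zip(centers, amplitudes):
        inten += a * np.exp(-0.5 * ((mz - c) / sigma) ** 2)
    return PeakList(mz, inten)


class TestPickPeaks:
    def test_single_gaussian_centroid(self):
        peaks = nativems.pick_peaks(gaussian_profile([3000.0], [100.0]))
        assert len(peaks) == 1
        assert peaks.mz[0] == pytest.approx(3000.0, abs=0.1)

    def test_close_gaussians_merge_below_min_spacing(self):
        profile = gaussian_profile([3000.0, 3001.0], [100.0, 100.0], sigma=0.4)
        merged = nativems.pick_peaks(profile, min_spacing=2.0)
        assert len(merged) == 1
        assert merged.mz[0] == pytest.approx(3000.5, abs=0.2)
        resolved = nativems.pick_peaks(profile, min_spacing=0.5)
        assert len(resolved) == 2

    def test_all_zero_profile_yields_empty_list(self):
        profile = PeakList(np.arange(1000.0, 1010.0, 0.1), np.zeros(100))
        assert len(nativems.pick_peaks(profile)) == 0

    def test_centroid_count_matches_generator_inventory(self):
        # noise-free preset: every inventory entry appears once, except that
        # entries closer than min_spacing merge into a single centroid
        preset = simulate.SPECTRUM_PRESETS["fl-pi-20uM"]
        quiet = simulate.SpectrumPreset(
            preset.name, preset.components, noise_floor=0.0, min_rel_intensity=1e-2
        )
        profile, inventory = simulate.gen_spectrum(quiet, seed=0)
        min_spacing = 6.0
        expected = 1 + int((np.diff(np.sort(inventory["mz"])) >= min_spacing).sum())
        centroids = nativems.pick_peaks(profile, min_snr=1.0, min_spacing=min_spacing)
        assert len(centroids) == expected

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            nativems.pick_peaks(PeakList(np.array([]), np.array([])))


class TestDeconvolveMass:
    def test_exact_series_recovered_within_half_dalton(self):
        peaks = exact_series_peaks(58000.0, range(14, 18))
        series = nativems.deconvolve_mass(peaks, z_range=(10, 20))
        assert series[0].mass == pytest.approx(58000.0, abs=0.5)
        assert series[0].charges == (14, 15, 16, 17)

    def test_missing_charge_state_leaves_gap(self):
        peaks = exact_series_peaks(58000.0, [13, 14, 16, 17])
        series = nativems.deconvolve_mass(peaks, z_range=(10, 20))
        assert series[0].mass == pytest.approx(58000.0, abs=0.5)
        assert series[0].charges == (13, 14, 16, 17)

    def test_interleaved_masses_both_recovered(self):
        # a full-length/truncated mixture produces two interleaved series
        fl = exact_series_peaks(58000.0, range(14, 19), [5, 10, 12, 10, 5])
        tr = exact_series_peaks(48200.0, range(12, 17), [4, 8, 10, 8, 4])
        peaks = PeakList(np.concatenate([fl.mz, tr.mz]), np.concatenate([fl.intensity, tr.intensity]))
        series = nativems.deconvolve_mass(peaks, z_range=(10, 22))
        masses = sorted(s.mass for s in series[:2])
        assert masses[0] == pytest.approx(48200.0, abs=0.5)
        assert masses[1] == pytest.approx(58000.0, abs=0.5)

    def test_round_trip_across_charge_range(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            mass = float(rng.uniform(30000, 90000))
            z_lo = int(rng.integers(12, 18))
            charges = range(z_lo, z_lo + int(rng.integers(4, 6)))
            peaks = exact_series_peaks(mass, charges, rng.uniform(1, 10, len(list(charges))))
            series = nativems.deconvolve_mass(peaks, z_range=(12, 22))
            assert abs(series[0].mass - mass) <= 0.5

    def test_too_few_peaks_rejected_and_no_match_is_empty(self):
        with pytest.raises(ValueError):
            nativems.deconvolve_mass(exact_series_peaks(58000.0, [15, 16]))
        random_peaks = PeakList(np.array([3000.0, 3100.0, 3307.0]), np.ones(3))
        assert nativems.deconvolve_mass(random_peaks, z_range=(14, 18)) == []


def ladder_assignment(fractions, lipid_names=("PI(18:1/18:1)",), charges=(15, 16, 17)):
    """Build peaks for a base mass plus stoichiometry ladder, then assign."""
    base_mass = 58000.0
    mzs, intens = [], []
    lipid_mass = {n: chem.get_lipid(n).average_mass for n in lipid_names}
    for z in charges:
        for k, frac in enumerate(fractions):
            if frac <= 0:
                continue
            name = lipid_names[min(k - 1, len(lipid_names) - 1)] if k else None
            mass = base_mass + (k * lipid_mass[name] if name else 0.0)
            mzs.append((mass + z * PROTON_MASS) / z)
            intens.append(100.0 * frac)
    peaks = PeakList(np.array(mzs), np.array(intens))
    series = nativems.deconvolve_mass(peaks, z_range=(12, 20))
    base = min(series, key=lambda s: s.mass)
    candidates = [chem.get_lipid(n) for n in lipid_names]
    return peaks, nativems.assign_lipid_adducts(peaks, base, candidates)


class TestAdductsAndFractions:
    def test_constructed_pi_ladder_assigns_k012(self):
        _, adducts = ladder_assignment([0.5, 0.3, 0.2])
        assert sorted(adducts.table["k"].unique()) == [1, 2]
        assert not adducts.ambiguous_peaks

    def test_apo_only_spectrum_has_zero_stoichiometry(self):
        _, adducts = ladder_assignment([1.0])
        assert len(adducts.table) == 0
        fractions = nativems.mole_fractions(adducts)
        assert fractions.iloc[0]["x0"] == 1.0

    def test_competition_ladder_no_cross_assignment(self):
        # four lipids one phosphate apart: ~80 Da spacing >> 3 Da tolerance
        names = [
            "PI(18:1/18:1)",
            "PI(4)P(18:1/18:1)",
            "PI(4,5)P2(18:1/18:1)",
            "PI(3,4,5)P3(18:1/18:1)",
        ]
        base_mass = 58000.0
        z = 17
        mzs = [(base_mass + z * PROTON_MASS) / z]
        intens = [100.0]
        for name in names:
            mzs.append((base_mass + chem.get_lipid(name).average_mass + z * PROTON_MASS) / z)
            intens.append(50.0)
        # pad with two more charge states of the apo series so deconvolution works
        for z2 in (16, 18):
            mzs.append((base_mass + z2 * PROTON_MASS) / z2)
            intens.append(80.0)
        peaks = PeakList(np.array(mzs), np.array(intens))
        base = min(nativems.deconvolve_mass(peaks, z_range=(15, 19)), key=lambda s: s.mass)
        adducts = nativems.assign_lipid_adducts(peaks, base, [chem.get_lipid(n) for n in names])
        by_lipid = adducts.table.set_index("lipid")["k"]
        assert set(by_lipid.index) == set(names)
        assert (by_lipid == 1).all()
        assert not adducts.ambiguous_peaks

    def test_overlapping_candidate_ladders_flagged_ambiguous(self):
        # two candidates ~0.02 Da apart cannot be discriminated at +-3 Da
        pa = chem.get_lipid("PA(16:0/18:1)")
        lookalike = chem.LipidSpecies(
            "PA-iso", "PA", "16:0/18:1", chem.MolecularFormula.from_string("C36H69NO8P")
        )
        base_mass = 58000.0
        mzs, intens = [], []
        for z in (15, 16, 17):
            mzs.append((base_mass + z * PROTON_MASS) / z)
            intens.append(100.0)
        mzs.append((base_mass + pa.average_mass + 16 * PROTON_MASS) / 16)
        intens.append(50.0)
        peaks = PeakList(np.array(mzs), np.array(intens))
        base = min(nativems.deconvolve_mass(peaks, z_range=(14, 18)), key=lambda s: s.mass)
        adducts = nativems.assign_lipid_adducts(peaks, base, [pa, lookalike])
        assert len(adducts.ambiguous_peaks) == 1

    def test_mole_fraction_normalization_and_scale_invariance(self):
        peaks, adducts = ladder_assignment([0.5, 0.3, 0.2])
        fractions = nativems.mole_fractions(adducts)
        assert fractions.iloc[0].sum() == pytest.approx(1.0, abs=1e-9)
        assert fractions.iloc[0][["x0", "x1", "x2"]].tolist() == pytest.approx([0.5, 0.3, 0.2])
        # uniform intensity scaling leaves fractions untouched
        scaled_peaks = PeakList(peaks.mz, peaks.intensity * 37.5)
        base = min(nativems.deconvolve_mass(scaled_peaks, z_range=(12, 20)), key=lambda s: s.mass)
        scaled = nativems.assign_lipid_adducts(scaled_peaks, base, [chem.get_lipid("PI")])
        assert nativems.mole_fractions(scaled).iloc[0].tolist() == pytest.approx(
            fractions.iloc[0].tolist(), abs=1e-12
        )

    def test_per_charge_mode_rows_sum_to_one(self):
        _, adducts = ladder_assignment([0.4, 0.4, 0.2])
        per_charge = nativems.mole_fractions(adducts, aggregate="per_charge")
        sums = per_charge[[c for c in per_charge.columns if c.startswith("x")]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_assignment_stable_under_peak_order_permutation(self):
        rng = np.random.default_rng(0)
        peaks, adducts = ladder_assignment([0.4, 0.35, 0.15, 0.07, 0.03])
        perm = rng.permutation(len(peaks))
        shuffled = PeakList(peaks.mz[perm], peaks.intensity[perm])
        base = min(nativems.deconvolve_mass(shuffled, z_range=(12, 20)), key=lambda s: s.mass)
        again = nativems.assign_lipid_adducts(shuffled, base, [chem.get_lipid("PI")])
        assert nativems.mole_fractions(again).iloc[0].tolist() == pytest.approx(
            nativems.mole_fractions(adducts).iloc[0].tolist(), abs=1e-9
        )

    def test_generator_round_trip_recovers_fractions(self):
        target = [0.4, 0.35, 0.15, 0.07, 0.03]
        comp = simulate.SpectrumComponent(
            "toy",
            58000.0,
            16.0,
            1.2,
            1.0,
            tuple(("PI(18:1/18:1)" if k else None, k, f) for k, f in enumerate(target)),
        )
        profile, _ = simulate.gen_spectrum(simulate.SpectrumPreset("toy", (comp,)), seed=8)
        centroids = nativems.pick_peaks(profile, min_spacing=6.0)
        base = min(nativems.deconvolve_mass(centroids, z_range=(12, 22)), key=lambda s: s.mass)
        adducts = nativems.assign_lipid_adducts(centroids, base, [chem.get_lipid("PI")])
        recovered = nativems.mole_fractions(adducts).iloc[0]
        for k, frac in enumerate(target):
            assert recovered[f"x{k}"] == pytest.approx(frac, abs=0.02)


class TestCompetitionAndMixture:
    def test_identical_replicates_not_significant(self):
        result = nativems.competition_compare({"PI": [3.0, 4.0, 5.0], "PE": [3.0, 4.0, 5.0]})
        assert result.pairwise["p_value"].iloc[0] == pytest.approx(1.0)
        assert result.pairwise["stars"].iloc[0] == "ns"

    def test_clear_separation_is_significant(self):
        result = nativems.competition_compare({"a": [3.0, 4.0, 5.0], "b": [13.0, 14.0, 15.0]})
        assert result.pairwise["p_value"].iloc[0] < 0.01

    def test_equilibrium_predicted_competition_ranks_pip2_first(self):
        # equimolar competition against the full-length first constants
        kds = {"PI": 6.0, "PI4P": 6.0, "PIP2": 0.7, "PIP3": 6.0}
        occ = simulate.competitive_occupancy(kds, {k: 5.0 for k in kds})
        rng = np.random.default_rng(1)
        intensities = {
            name: 1000.0 * occ[name] * (1 + 0.05 * rng.standard_normal(3)) for name in kds
        }
        result = nativems.competition_compare(intensities)
        assert result.ranking[0] == "PIP2"
        pip2_rows = result.pairwise[
            (result.pairwise["lipid_a"] == "PIP2") | (result.pairwise["lipid_b"] == "PIP2")
        ]
        assert (pip2_rows["p_value"] < 0.05).all()

    def test_mismatched_replicates_rejected(self):
        with pytest.raises(ValueError):
            nativems.competition_compare({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})

    def test_mixture_equal_intensities_gives_unit_ratios(self):
        data = pd.DataFrame(
            {
                "protein": ["fl"] * 3 + ["trunc"] * 3,
                "replicate": [1, 2, 3] * 2,
                "apo_intensity": [100.0] * 6,
                "bound_intensity": [100.0] * 6,
            }
        )
        result = nativems.mixture_bound_ratio(data)
        assert result.ratios["mean"].tolist() == [1.0, 1.0]
        assert result.p_value == 1.0

    def test_mixture_higher_affinity_gives_higher_ratio(self):
        # occupancy oracle at fixed free ligand: theta = L / (K_D + L)
        free_l, kd_a, kd_b = 10.0, 5.0, 25.0
        rows = []
        rng = np.random.default_rng(2)
        for protein, kd in (("A", kd_a), ("B", kd_b)):
            theta = free_l / (kd + free_l)
            for rep in range(1, 4):
                noise = 1 + 0.03 * rng.standard_normal()
                rows.append((protein, rep, 100.0 * (1 - theta), 100.0 * theta * noise))
        data = pd.DataFrame(rows, columns=["protein", "replicate", "apo_intensity", "bound_intensity"])
        result = nativems.mixture_bound_ratio(data)
        means = dict(zip(result.ratios["protein"], result.ratios["mean"]))
        assert means["A"] > means["B"]

    def test_mixture_degenerate_variance_skips_test(self):
        data = pd.DataFrame(
            {
                "protein": ["A"] * 3 + ["B"] * 3,
                "replicate": [1, 2, 3] * 2,
                "apo_intensity": [1.0] * 6,
                "bound_intensity": [1.0] * 3 + [2.0] * 3,
            }
        )
        with pytest.warns(UserWarning, match="variance"):
            result = nativems.mixture_bound_ratio(data)
        assert result.degenerate and result.p_value is None

    def test_mixture_missing_apo_rejected(self):
        data = pd.DataFrame(
            {
                "protein": ["A", "B"],
                "replicate": [1, 1],
                "apo_intensity": [0.0, 1.0],
                "bound_intensity": [1.0, 1.0],
            }
        )
        with pytest.raises(ValueError, match="apo"):
            nativems.mixture_bound_ratio(data)

    def test_significance_star_thresholds(self):
        assert nativems.significance_stars(0.3) == "ns"
        assert nativems.significance_stars(0.03) == "*"
        assert nativems.significance_stars(0.004) == "**"
        assert nativems.significance_stars(5e-4) == "***"
        assert nativems.significance_stars(5e-5) == "****"
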