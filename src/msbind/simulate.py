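"""Synthetic titrations, native-MS peak lists, and four-state HDX tables.

The generators emit data with exactly the statistical structure the analysis
modules assume, plus a truth record, so every stage of the pipeline can be
verified by recovery at desk scale:

* titrations: sequential-binding mole fractions on a concentration grid with
  multiplicative intensity noise before renormalisation;
* spectra: Gaussian peaks at (M + sum k*m_lipid + z*m_p)/z with a Gaussian
  charge envelope and an additive noise floor, with a peak inventory;
* HDX: a 549-residue membrane-transporter stand-in tiled by peptic peptides,
  with per-residue first-order exchange rates, per-state per-segment rate
  multipliers, and replicate noise on uptake.

Preset dissociation constants carry the measured first binding constants for
the transporter study the package emulates (PI(4,5)P2 0.7 uM full-length /
9.9 uM N-terminally truncated; ~6 uM for PI, PI(4)P and PIP3; PE 20-fold
weaker than PI); higher-order constants follow a 3x ladder because only the
first constants are printed.  HDX presets encode early protection of TM8 by
the substrate, late deprotection of the extracellular gate (TM1/L1-2/TM2/TM7),
cytoplasmic protection plus extracellular deprotection by the signalling
lipid, and super-additive gate opening in the ternary complex.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binding import BindingModel, TitrationDesign, predict_titration, solve_equilibrium
from .chem import PROTON_MASS, LipidSpecies, get_lipid
from .hdx import max_uptake

__all__ = [
    "TitrationPreset",
    "SpectrumPreset",
    "SpectrumComponent",
    "HDXPreset",
    "Segment",
    "TITRATION_PRESETS",
    "SPECTRUM_PRESETS",
    "HDX_PRESETS",
    "GRID_0_50",
    "GRID_0_600",
    "SEGMENTS",
    "GATE_SEGMENTS",
    "default_sequence",
    "kd_ladder",
    "gen_titration",
    "gen_spectrum",
    "gen_hdx",
    "gen_null_hdx",
    "competitive_occupancy",
]

# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------

#: 12-point total-lipid grid, 0-50 uM (protein at 5 uM).
GRID_0_50 = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0, 20.0, 28.0, 38.0, 50.0)
#: The same grid scaled x12 to bracket a ~120 uM first binding constant.
GRID_0_600 = tuple(12.0 * c for c in GRID_0_50)


def kd_ladder(kd1: float, n_sites: int = 4, ratio: float = 2.0) -> tuple[float, ...]:
    """Stepwise constants K_D(i+1) = ratio * K_Di.

    Only the first binding constants are printed for the transporter study;
    the geometric ladder reproduces the decreasing occupancy of higher
    stoichiometries.  The ratio of 2 keeps all four binding events above a 2%
    mole fraction at 20 uM lipid in the full-length PI scenario, matching the
    observation that at least four binding events are detectable there.
    """
    return tuple(kd1 * ratio**i for i in range(n_sites))


@dataclass(frozen=True)
class TitrationPreset:
    """A named titration scenario: binding truth, design, and noise level."""

    name: str
    model: BindingModel
    design: TitrationDesign
    noise_cv: float = 0.05

    def with_noise(self, noise_cv: float) -> "TitrationPreset":
        return replace(self, noise_cv=noise_cv)


def _titration_preset(name: str, kd1: float, grid=GRID_0_50, noise_cv: float = 0.05) -> TitrationPreset:
    return TitrationPreset(
        name,
        BindingModel(kd_ladder(kd1)),
        TitrationDesign(grid, p_tot=5.0, replicates=3),
        noise_cv,
    )


TITRATION_PRESETS: dict[str, TitrationPreset] = {
    p.name: p
    for p in (
        _titration_preset("fl-pip2", 0.7),
        _titration_preset("trunc-pip2", 9.9),
        _titration_preset("fl-pi", 6.0),
        _titration_preset("fl-pi4p", 6.0),
        _titration_preset("fl-pip3", 6.0),
        _titration_preset("fl-pe", 120.0, grid=GRID_0_600),
    )
}


def gen_titration(
    preset: TitrationPreset, seed: int, noise_cv: float | None = None
) -> tuple[pd.DataFrame, BindingModel]:
    """Simulate a replicate mole-fraction table; returns (table, truth model).

    Multiplicative Gaussian noise (coefficient of variation ``noise_cv``) is
    applied to the per-species intensities before renormalisation, so rows
    remain exact mole fractions.  Zero noise returns the model prediction
    exactly, once per replicate.
    """
    rng = np.random.default_rng(seed)
    cv = preset.noise_cv if noise_cv is None else noise_cv
    clean = predict_titration(preset.model, preset.design)
    frac_cols = [c for c in clean.columns if c.startswith("x")]
    rows = []
    for rep in range(1, preset.design.replicates + 1):
        for _, row in clean.iterrows():
            intens = row[frac_cols].to_numpy(float)
            if cv > 0:
                intens = np.clip(intens * (1.0 + cv * rng.standard_normal(len(intens))), 0.0, None)
                if intens.sum() == 0:  # pragma: no cover - cv would have to be huge
                    intens = row[frac_cols].to_numpy(float)
            fracs = intens / intens.sum()
            rows.append([row["lipid_conc_uM"], rep, *fracs])
    table = pd.DataFrame(rows, columns=["lipid_conc_uM", "replicate", *frac_cols])
    return table, preset.model


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectrumComponent:
    """One protein in a spectrum: mass, charge envelope, and bound species.

    ``species`` is a tuple of (lipid name or None, stoichiometry, fraction);
    fractions must sum to 1 within the component.
    """

    label: str
    mass: float
    z_center: float
    z_width: float
    abundance: float
    species: tuple[tuple[str | None, int, float], ...]

    def __post_init__(self) -> None:
        total = sum(f for _, _, f in self.species)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component {self.label!r}: species fractions sum to {total}")


@dataclass(frozen=True)
class SpectrumPreset:
    name: str
    components: tuple[SpectrumComponent, ...]
    peak_sigma: float = 1.5  # Th; unresolved-isotope peak width at ~58 kDa
    noise_floor: float = 0.5  # additive Gaussian noise sd, in intensity units
    grid_step: float = 0.25  # Th
    z_limits: tuple[int, int] = (5, 30)
    base_intensity: float = 1000.0
    min_rel_intensity: float = 1e-3


def competitive_occupancy(kds: dict[str, float], conc: dict[str, float]) -> dict[str, float]:
    """Single-site competitive occupancies x_lipid = (L_i/K_i)/(1 + sum L_j/K_j).

    Free concentrations are approximated by totals (documented preset
    simplification); the apo fraction is returned under key ``None``.
    """
    terms = {name: conc[name] / kds[name] for name in kds}
    denom = 1.0 + sum(terms.values())
    occ: dict[str | None, float] = {name: t / denom for name, t in terms.items()}
    occ[None] = 1.0 / denom
    return occ


def _envelope_charges(comp: SpectrumComponent, limits: tuple[int, int]) -> dict[int, float]:
    lo = max(limits[0], int(np.floor(comp.z_center - 3 * comp.z_width)))
    hi = min(limits[1], int(np.ceil(comp.z_center + 3 * comp.z_width)))
    weights = {
        z: float(np.exp(-0.5 * ((z - comp.z_center) / comp.z_width) ** 2))
        for z in range(lo, hi + 1)
    }
    total = sum(weights.values())
    return {z: w / total for z, w in weights.items()}


def gen_spectrum(preset: SpectrumPreset, seed: int):
    """Simulate a profile spectrum; returns (PeakList profile, inventory).

    Every emitted peak is traceable to a (protein, z, k) tuple in the
    inventory frame (protein, lipid, z, k, mz, intensity).
    """
    from .nativems import PeakList  # local import to avoid cycle

    rng = np.random.default_rng(seed)
    inventory = []
    for comp in preset.components:
        zw = _envelope_charges(comp, preset.z_limits)
        for z, w in zw.items():
            for lipid_name, k, fraction in comp.species:
                if fraction <= 0:
                    continue
                lipid_mass = get_lipid(lipid_name).average_mass if lipid_name else 0.0
                mass = comp.mass + k * lipid_mass
                mz = (mass + z * PROTON_MASS) / z
                intensity = preset.base_intensity * comp.abundance * w * fraction
                inventory.append(
                    {
                        "protein": comp.label,
                        "lipid": lipid_name,
                        "z": z,
                        "k": k,
                        "mz": mz,
                        "intensity": intensity,
                    }
                )
    inv = pd.DataFrame(inventory)
    inv = inv[inv["intensity"] >= preset.min_rel_intensity * inv["intensity"].max()]
    inv = inv.sort_values("mz").reset_index(drop=True)

    lo = inv["mz"].min() - 30.0
    hi = inv["mz"].max() + 30.0
    grid = np.arange(lo, hi, preset.grid_step)
    profile = np.zeros_like(grid)
    for row in inv.itertuples():
        profile += row.intensity * np.exp(-0.5 * ((grid - row.mz) / preset.peak_sigma) ** 2)
    if preset.noise_floor > 0:
        # chemical baseline: positive offset with Gaussian scatter
        baseline = rng.normal(3.0 * preset.noise_floor, preset.noise_floor, len(grid))
        profile = np.clip(profile + baseline, 0.0, None)
    return PeakList(grid, profile, label=preset.name), inv


def _titration_spectrum(
    name: str,
    mass: float,
    model: BindingModel,
    l_tot: float,
    lipid: str,
    p_tot: float = 5.0,
    z_center: float = 16.0,
    z_width: float = 1.2,
) -> SpectrumPreset:
    state = solve_equilibrium(model, p_tot, l_tot)
    species = tuple(
        (lipid if k > 0 else None, k, frac) for k, frac in enumerate(state.fractions)
    )
    comp = SpectrumComponent(name, mass, z_center, z_width, 1.0, species)
    return SpectrumPreset(name, (comp,))


def _competition_spectrum(name: str, mass: float = 58000.0) -> SpectrumPreset:
    # equimolar panel at 5 uM each against the full-length first constants
    kds = {"PI(18:1/18:1)": 6.0, "PI(4)P(18:1/18:1)": 6.0, "PI(4,5)P2(18:1/18:1)": 0.7, "PI(3,4,5)P3(18:1/18:1)": 6.0}
    conc = {k: 5.0 for k in kds}
    occ = competitive_occupancy(kds, conc)
    species = tuple(
        (lipid, 0 if lipid is None else 1, frac) for lipid, frac in occ.items()
    )
    comp = SpectrumComponent(name, mass, 17.0, 1.0, 1.0, species)
    return SpectrumPreset(name, (comp,))


def _mixture_spectrum(
    name: str,
    masses: tuple[float, float] = (58000.0, 48200.0),
    kds: tuple[float, float] = (5.0, 25.0),
    free_ligand: float = 10.0,
    lipid: str = "S1P(d18:1)",
) -> SpectrumPreset:
    comps = []
    for label, mass, kd, zc in zip(("full-length", "truncated"), masses, kds, (16.0, 14.0)):
        theta = free_ligand / (kd + free_ligand)
        species = ((None, 0, 1.0 - theta), (lipid, 1, theta))
        comps.append(SpectrumComponent(label, mass, zc, 1.0, 1.0, species))
    return SpectrumPreset(name, tuple(comps))


SPECTRUM_PRESETS: dict[str, SpectrumPreset] = {
    "fl-apo": SpectrumPreset(
        "fl-apo",
        (SpectrumComponent("full-length", 58000.0, 16.0, 1.2, 1.0, ((None, 0, 1.0),)),),
    ),
    "fl-pi-20uM": _titration_spectrum(
        "fl-pi-20uM", 58000.0, TITRATION_PRESETS["fl-pi"].model, 20.0, "PI(18:1/18:1)"
    ),
    "competition-fl": _competition_spectrum("competition-fl"),
    "mixture-s1p": _mixture_spectrum("mixture-s1p"),
}


# ---------------------------------------------------------------------------
# HDX
# ---------------------------------------------------------------------------

EXPOSURES_MIN = (1.0, 60.0, 180.0, 360.0)


@dataclass(frozen=True)
class Segment:
    name: str
    start: int
    end: int
    kind: str  # "loop", "tm", or "tm_mixed"


# A 12-TM major-facilitator topology stand-in, 549 residues.  Helices are
# split into extracellular (e) and cytoplasmic (c) halves where the ligand
# effects are side-specific; ICH1/2 are the cytoplasmic interdomain helices.
SEGMENTS: tuple[Segment, ...] = (
    Segment("nterm", 1, 100, "loop"),
    Segment("TM1c", 101, 113, "tm"),
    Segment("TM1e", 114, 126, "tm"),
    Segment("L1-2", 127, 142, "loop"),
    Segment("TM2e", 143, 155, "tm"),
    Segment("TM2c", 156, 168, "tm"),
    Segment("L2-3", 169, 180, "loop"),
    Segment("TM3", 181, 202, "tm"),
    Segment("L3-4", 203, 210, "loop"),
    Segment("TM4", 211, 232, "tm"),
    Segment("L4-5", 233, 242, "loop"),
    Segment("TM5", 243, 256, "tm"),
    Segment("TM6e", 257, 271, "tm"),
    Segment("TM6c", 272, 284, "tm"),
    Segment("ICH1", 285, 300, "loop"),
    Segment("ICH2", 301, 315, "loop"),
    Segment("TM7c", 316, 330, "tm"),
    Segment("TM7e", 331, 345, "tm"),
    Segment("L7-8", 346, 352, "loop"),
    Segment("TM8", 353, 375, "tm_mixed"),
    Segment("L8-9", 376, 385, "loop"),
    Segment("TM9", 386, 408, "tm"),
    Segment("L9-10", 409, 415, "loop"),
    Segment("TM10", 416, 438, "tm"),
    Segment("L10-11", 439, 448, "loop"),
    Segment("TM11c", 449, 462, "tm"),
    Segment("TM11e", 463, 478, "tm"),
    Segment("L11-12", 479, 484, "loop"),
    Segment("TM12e", 485, 497, "tm"),
    Segment("TM12c", 498, 512, "tm"),
    Segment("cterm", 513, 549, "loop"),
)

#: Extracellular gate: helix ends whose opening admits/releases the substrate.
GATE_SEGMENTS = ("TM1e", "L1-2", "TM2e", "TM6e", "TM7e", "TM11e", "TM12e")

# Base exchange rates (1/min): loops exchange fast (RFU ~0.9 at 60 min), TM
# cores slowly (~0.3 at 60 min); TM8 carries a fast-exchanging subpopulation
# so that protection there is visible already at 1 min.
RATE_BY_KIND = {"loop": 0.04, "tm": 0.006}
TM_MIXED_FAST_RATE = 0.8
TM_MIXED_FAST_EVERY = 3  # every 3rd residue exchanges fast

# Substrate (S1P): early protection of TM8 (lateral entry), late deprotection
# of the extracellular gate helices.
S1P_MULT = {"TM8": 0.1, "TM1e": 2.0, "L1-2": 2.0, "TM2e": 2.0, "TM7e": 2.0}

# Signalling lipid (PIP2): rapid protection of the N terminus and the
# cytoplasmic face; allosteric deprotection of the extracellular helix ends.
PIP2_MULT = {
    "nterm": 0.3,
    "TM1c": 0.3,
    "TM2c": 0.3,
    "L2-3": 0.3,
    "L4-5": 0.3,
    "ICH1": 0.3,
    "ICH2": 0.3,
    "TM8": 0.3,
    "L10-11": 0.3,
    "TM1e": 1.7,
    "TM2e": 1.7,
    "TM7e": 1.7,
    "TM11e": 1.7,
}

#: Synergy factor: the ternary rate boost is 1.5x the additive prediction.
TERNARY_BOOST = 1.5
#: Gate segments whose synergy is ternary-specific (no single-ligand effect).
TERNARY_ONLY_MULT = {"TM6e": 1.8, "TM12e": 1.4}

#: Landmark peptides mirroring the study's uptake-plot panels (start, end).
LANDMARK_PEPTIDES = (
    (28, 34),
    (115, 120),
    (117, 126),
    (127, 142),
    (143, 147),
    (158, 164),
    (259, 263),
    (335, 340),
    (336, 340),
    (363, 372),
    (470, 478),
)


def _ternary_mult(segment: str) -> float:
    ms = S1P_MULT.get(segment, 1.0)
    mp = PIP2_MULT.get(segment, 1.0)
    if segment in TERNARY_ONLY_MULT:
        return TERNARY_ONLY_MULT[segment]
    if segment in GATE_SEGMENTS and (ms > 1.0 or mp > 1.0):
        # super-additive opening of the extracellular gate
        return 1.0 + TERNARY_BOOST * ((ms - 1.0) + (mp - 1.0))
    # protections (and no-effect segments) combine multiplicatively, which
    # reduces to the single-ligand effect when only one ligand acts
    return ms * mp


TERNARY_MULT = {
    seg.name: _ternary_mult(seg.name)
    for seg in SEGMENTS
    if _ternary_mult(seg.name) != 1.0
}


@dataclass(frozen=True)
class HDXPreset:
    """Four-state HDX scenario over a segment-annotated sequence."""

    name: str
    sequence: str
    segments: tuple[Segment, ...] = SEGMENTS
    state_multipliers: dict = field(
        default_factory=lambda: {"apo": {}, "S1P": dict(S1P_MULT), "PIP2": dict(PIP2_MULT), "ternary": dict(TERNARY_MULT)}
    )
    exposures_min: tuple[float, ...] = EXPOSURES_MIN
    replicates: int = 3
    noise_sd_da: float = 0.15
    tile_lengths: tuple[int, int] = (8, 16)
    tile_offset: int = 5
    landmarks: tuple[tuple[int, int], ...] = LANDMARK_PEPTIDES
    include_segment_peptides: bool = True
    additive_ternary: bool = False


@functools.lru_cache(maxsize=None)
def default_sequence(length: int = 549) -> str:
    """Deterministic 549-residue stand-in sequence with an N-terminal
    arginine patch at 23-28 (the real UniProt sequence can be supplied via
    FASTA but is not required)."""
    rng = np.random.default_rng(5490)
    alphabet = np.array(list("ACDEFGHIKLMNQRSTVWY"))
    seq = list(rng.choice(alphabet, size=length))
    # sprinkle prolines at ~4% so N_max < length - 1 for some peptides
    for i in rng.choice(np.arange(4, length), size=length // 25, replace=False):
        seq[i] = "P"
    seq[0] = "M"
    for i in range(22, 28):
        seq[i] = "R"
    return "".join(seq)


def _segment_of(segments: tuple[Segment, ...]) -> dict[int, Segment]:
    lookup = {}
    for seg in segments:
        for r in range(seg.start, seg.end + 1):
            lookup[r] = seg
    return lookup


def _residue_rates(preset: HDXPreset, state: str) -> np.ndarray:
    """Per-residue exchange rate (1/min), index 0 unused."""
    lookup = _segment_of(preset.segments)
    n = len(preset.sequence)
    rates = np.zeros(n + 1)
    mult = preset.state_multipliers.get(state, {})
    for r in range(1, n + 1):
        seg = lookup.get(r)
        if seg is None:
            base = RATE_BY_KIND["loop"]
            m = 1.0
        else:
            if seg.kind == "tm_mixed":
                fast = (r - seg.start) % TM_MIXED_FAST_EVERY == 0
                base = TM_MIXED_FAST_RATE if fast else RATE_BY_KIND["tm"]
            else:
                base = RATE_BY_KIND[seg.kind]
            m = mult.get(seg.name, 1.0)
        rates[r] = base * m
    return rates


def _tile_peptides(preset: HDXPreset, rng: np.random.Generator) -> list[tuple[int, int]]:
    n = len(preset.sequence)
    peptides = []
    start = 1
    lo, hi = preset.tile_lengths
    while start <= n - lo + 1:
        length = int(rng.integers(lo, hi + 1))
        end = min(start + length - 1, n)
        peptides.append((start, end))
        start += preset.tile_offset
    peptides.extend(preset.landmarks)
    if preset.include_segment_peptides:
        for seg in preset.segments:
            if seg.end - seg.start + 1 >= lo:
                peptides.append((seg.start, min(seg.end, seg.start + hi - 1)))
    # deduplicate, keep deterministic order
    return sorted(set(peptides))


def _mean_uptake(
    start: int, end: int, t: float, rates: np.ndarray, sequence: str
) -> tuple[float, int]:
    """Closed-form mean uptake: sum over exchange-competent residues of
    1 - exp(-k_res * t).  The peptide's first residue and prolines do not
    contribute (back-exchange / no amide H)."""
    pep_seq = sequence[start - 1 : end]
    n_max = max_uptake(pep_seq)
    uptake = 0.0
    for offset in range(1, len(pep_seq)):
        if pep_seq[offset] == "P":
            continue
        uptake += 1.0 - np.exp(-rates[start + offset] * t)
    return uptake, n_max


def gen_hdx(preset: HDXPreset, seed: int, states: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Simulate a tidy four-state uptake table (one row per replicate).

    Gaussian noise (sd ``noise_sd_da``) is added to the closed-form mean
    uptake and truncated to [0, N_max].  With ``additive_ternary`` the
    ternary mean uptake is constructed as D_S1P + D_PIP2 - D_apo, an exactly
    additive null for the synergy statistic.
    """
    rng = np.random.default_rng(seed)
    states = states or tuple(preset.state_multipliers)
    peptides = _tile_peptides(preset, rng)
    rate_cache = {s: _residue_rates(preset, s) for s in preset.state_multipliers}
    rows = []
    for start, end in peptides:
        pep_seq = preset.sequence[start - 1 : end]
        n_max = max_uptake(pep_seq)
        if n_max == 0:
            continue
        for t in preset.exposures_min:
            means = {}
            for s in preset.state_multipliers:
                means[s], _ = _mean_uptake(start, end, t, rate_cache[s], preset.sequence)
            if preset.additive_ternary and "ternary" in means:
                means["ternary"] = float(
                    np.clip(means["S1P"] + means["PIP2"] - means["apo"], 0.0, n_max)
                )
            for s in states:
                for rep in range(1, preset.replicates + 1):
                    uptake = means[s]
                    if preset.noise_sd_da > 0:
                        uptake = float(
                            np.clip(uptake + rng.normal(0.0, preset.noise_sd_da), 0.0, n_max)
                        )
                    rows.append(
                        {
                            "protein": preset.name,
                            "start": start,
                            "end": end,
                            "sequence": pep_seq,
                            "state": s,
                            "exposure_min": t,
                            "replicate": rep,
                            "uptake_da": uptake,
                        }
                    )
    return pd.DataFrame(rows)


HDX_PRESETS: dict[str, HDXPreset] = {
    "hdx-synergy": HDXPreset("hdx-synergy", default_sequence()),
    "hdx-additive": HDXPreset("hdx-additive", default_sequence(), additive_ternary=True),
    "hdx-noiseless": HDXPreset("hdx-noiseless", default_sequence(), noise_sd_da=0.0),
}


def gen_null_hdx(
    n_peptides: int,
    seed: int,
    noise_sd_da: float = 0.15,
    replicates: int = 3,
    exposure_min: float = 60.0,
) -> pd.DataFrame:
    """Null uptake table: two identically distributed states per peptide.

    Used to calibrate the per-cell t-test (empirical type-I error at a given
    alpha should match the nominal level).
    """
    rng = np.random.default_rng(seed)
    seq_pool = default_sequence()
    rows = []
    for i in range(n_peptides):
        length = int(rng.integers(8, 17))
        start = int(rng.integers(1, len(seq_pool) - length))
        pep_seq = seq_pool[start - 1 : start + length - 1]
        n_max = max_uptake(pep_seq)
        if n_max == 0:
            pep_seq = "A" * length
            n_max = length - 1
        mean = 0.4 * n_max
        for state in ("apo", "S1P"):
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "protein": "null",
                        "start": 1 + i * 100,  # disjoint coordinates per peptide
                        "end": i * 100 + length,
                        "sequence": pep_seq,
                        "state": state,
                        "exposure_min": exposure_min,
                        "replicate": rep,
                        "uptake_da": float(np.clip(mean + rng.normal(0, noise_sd_da), 0, n_max)),
                    }
                )
    return pd.DataFrame(rows)
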