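"""Native-MS peak-list analysis: deconvolution, adducts, fractions, statistics.

A native mass spectrum of an intact protein-detergent complex shows one peak
per charge state z at m/z = (M + z*m_p)/z (positive mode, m_p the proton
mass).  Lipid binding appears as satellite series displaced by the neutral
lipid mass divided by z.  This module turns centroided peak lists into:

* a zero-charge mass via exhaustive charge-series scoring,
* lipid-adduct stoichiometry assignments against a candidate lipid panel,
* bound-state mole fractions (intensity of each species over the total),
* competition rankings and mixture bound/apo ratios with replicate t-tests.

Intensities of apo and lipid-bound species are compared without any
ionization-efficiency correction, the standard assumption behind
intensity-derived mole fractions in native MS.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .chem import PROTON_MASS, LipidSpecies

__all__ = [
    "PeakList",
    "ChargeSeriesAssignment",
    "AdductAssignment",
    "CompetitionResult",
    "MixtureRatioResult",
    "pick_peaks",
    "deconvolve_mass",
    "assign_lipid_adducts",
    "mole_fractions",
    "competition_compare",
    "mixture_bound_ratio",
    "significance_stars",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakList:
    """Ordered (m/z, intensity) pairs; input order is normalised by m/z."""

    mz: np.ndarray
    intensity: np.ndarray
    label: str = ""
    replicate: int | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if len(mz) > 1 and np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be unique")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class ChargeSeriesAssignment:
    """One neutral mass with its matched charge states and mass residuals."""

    mass: float
    charges: tuple[int, ...]
    peak_indices: tuple[int, ...]
    residuals_da: tuple[float, ...]
    intensity: float

    @property
    def n_states(self) -> int:
        return len(self.charges)


def pick_peaks(profile: PeakList, min_snr: float = 3.0, min_spacing: float = 2.0) -> PeakList:
    """Centroid a profile spectrum.

    Local maxima above a noise floor (median + min_snr * 1.4826*MAD) become
    centroids via an intensity-weighted mean over a +-min_spacing/2 window;
    maxima closer than ``min_spacing`` Th are merged into one centroid.  An
    all-zero profile yields an empty peak list.
    """
    if len(profile) == 0:
        raise ValueError("profile spectrum is empty")
    inten = profile.intensity
    if not np.any(inten > 0):
        return PeakList(np.array([]), np.array([]), label=profile.label, replicate=profile.replicate)
    med = float(np.median(inten))
    mad = float(np.median(np.abs(inten - med)))
    noise = 1.4826 * mad
    threshold = med + min_snr * noise if noise > 0 else float(inten.max()) * 1e-6
    step = float(np.median(np.diff(profile.mz))) if len(profile) > 1 else 1.0
    distance = max(1, int(round(min_spacing / step)))
    idx, _ = signal.find_peaks(inten, height=threshold, distance=distance)

    # windows are partitioned at the intensity minimum between adjacent apexes
    # so no sample is counted twice, then bounded by the contiguous region
    # above 10% of the apex height (baseline-subtracted), capped per side
    left_bound = np.empty(len(idx), dtype=int)
    right_bound = np.empty(len(idx), dtype=int)
    for n, i in enumerate(idx):
        left_bound[n] = 0 if n == 0 else idx[n - 1] + int(np.argmin(inten[idx[n - 1] : i + 1]))
        right_bound[n] = (
            len(inten) - 1 if n == len(idx) - 1 else i + int(np.argmin(inten[i : idx[n + 1] + 1]))
        )
    centroids = []
    for n, i in enumerate(idx):
        height = inten[i] - med
        floor_i = med + 0.1 * height
        lo = i
        while (
            lo > left_bound[n]
            and inten[lo - 1] >= floor_i
            and profile.mz[i] - profile.mz[lo - 1] <= 2 * min_spacing
        ):
            lo -= 1
        hi = i
        while (
            hi < right_bound[n]
            and inten[hi + 1] >= floor_i
            and profile.mz[hi + 1] - profile.mz[i] <= 2 * min_spacing
        ):
            hi += 1
        w = np.clip(inten[lo : hi + 1] - med, 0.0, None)  # baseline-subtracted weights
        if w.sum() == 0:
            continue
        centroids.append((float(np.average(profile.mz[lo : hi + 1], weights=w)), float(w.sum())))

    # merge centroids closer than min_spacing (intensity-weighted)
    merged: list[tuple[float, float]] = []
    for mz, ii in sorted(centroids):
        if merged and mz - merged[-1][0] < min_spacing:
            pmz, pi = merged[-1]
            tot = pi + ii
            merged[-1] = ((pmz * pi + mz * ii) / tot, tot)
        else:
            merged.append((mz, ii))
    if not merged:
        return PeakList(np.array([]), np.array([]), label=profile.label, replicate=profile.replicate)
    mzs, ints = map(np.asarray, zip(*merged))
    return PeakList(mzs, ints, label=profile.label, replicate=profile.replicate)


def _match_series(
    mass: float, peaks: PeakList, z_range: tuple[int, int], tol_da: float
) -> tuple[list[int], list[int], list[float]]:
    """Nearest-peak matching of the predicted series for one candidate mass."""
    charges, indices, residuals = [], [], []
    for z in range(z_range[0], z_range[1] + 1):
        target = (mass + z * PROTON_MASS) / z
        j = int(np.searchsorted(peaks.mz, target))
        best_j, best_err = -1, tol_da / z
        for cand in (j - 1, j):
            if 0 <= cand < len(peaks):
                err = abs(peaks.mz[cand] - target)
                if err < best_err:
                    best_j, best_err = cand, err
        if best_j >= 0:
            charges.append(z)
            indices.append(best_j)
            residuals.append(z * (peaks.mz[best_j] - PROTON_MASS) - mass)
    return charges, indices, residuals


def _longest_run(charges: list[int]) -> int:
    best = run = 1
    for a, b in itertools.pairwise(charges):
        run = run + 1 if b == a + 1 else 1
        best = max(best, run)
    return best


def deconvolve_mass(
    peaks: PeakList,
    z_range: tuple[int, int] = (5, 30),
    mass_window: tuple[float, float] | None = None,
    tol_da: float = 1.5,
    min_states: int = 3,
    max_series: int = 4,
) -> list[ChargeSeriesAssignment]:
    """Exhaustive charge-series scan returning ranked neutral-mass assignments.

    Every (peak, charge) pair proposes a candidate mass; candidates are scored
    by matched charge-state count weighted by intensity, refined by an
    intensity-weighted mass average, and accepted greedily.  Harmonic or
    subset series (sharing most matched peaks with a better assignment) are
    suppressed.  Fewer than ``min_states`` matched charge states anywhere
    yields an empty list with a logged diagnostic.
    """
    if len(peaks) < 3:
        raise ValueError("need at least 3 peaks to deconvolve a charge series")
    if not (5 <= z_range[0] <= z_range[1] <= 30):
        raise ValueError("z_range must lie within [5, 30]")

    seen: set[float] = set()
    candidates = []
    for mz in peaks.mz:
        for z in range(z_range[0], z_range[1] + 1):
            mass = z * (mz - PROTON_MASS)
            if mass_window is not None and not (mass_window[0] <= mass <= mass_window[1]):
                continue
            key = round(mass / (tol_da / 2.0))
            if key in seen:
                continue
            seen.add(key)
            candidates.append(mass)

    scored = []
    for mass in candidates:
        # two refinement passes: match, re-estimate mass, re-match
        for _ in range(2):
            charges, indices, _ = _match_series(mass, peaks, z_range, tol_da)
            if len(charges) < min_states:
                break
            w = peaks.intensity[indices]
            implied = [z * (peaks.mz[j] - PROTON_MASS) for z, j in zip(charges, indices)]
            mass = float(np.average(implied, weights=w)) if w.sum() > 0 else float(np.mean(implied))
        charges, indices, residuals = _match_series(mass, peaks, z_range, tol_da)
        if len(charges) < min_states:
            continue
        inten = float(peaks.intensity[indices].sum())
        scored.append(
            ChargeSeriesAssignment(mass, tuple(charges), tuple(indices), tuple(residuals), inten)
        )

    if not scored:
        best = 0
        for mass in candidates:
            charges, _, _ = _match_series(mass, peaks, z_range, tol_da)
            best = max(best, len(charges))
        logger.warning(
            "deconvolution found no candidate matching >= %d charge states (best: %d)",
            min_states,
            best,
        )
        return []

    scored.sort(
        key=lambda a: (a.n_states, a.intensity, _longest_run(list(a.charges)), -a.mass),
        reverse=True,
    )
    accepted: list[ChargeSeriesAssignment] = []
    used: set[int] = set()
    for cand in scored:
        if len(accepted) >= max_series:
            break
        if any(abs(cand.mass - a.mass) < 2 * tol_da for a in accepted):
            continue
        overlap = len(set(cand.peak_indices) & used) / len(cand.peak_indices)
        if overlap > 0.5:
            continue
        accepted.append(cand)
        used.update(cand.peak_indices)
    return accepted


@dataclass
class AdductAssignment:
    """Lipid-adduct stoichiometries on top of a base charge series.

    ``table`` has one row per assigned adduct peak (charge, lipid, k, mz,
    intensity, residual_da); ``apo`` holds the base-series peak intensities.
    """

    base_mass: float
    max_stoich: int
    table: pd.DataFrame
    apo: pd.DataFrame
    ambiguous_peaks: tuple[int, ...] = ()


def assign_lipid_adducts(
    peaks: PeakList,
    base: ChargeSeriesAssignment,
    candidates: list[LipidSpecies],
    tol_da: float = 3.0,
    max_stoich: int = 4,
) -> AdductAssignment:
    """Match peaks above each base charge state to M0 + k * lipid-mass ladders.

    Matching happens in neutral-mass space with tolerance ``tol_da``; each
    observed peak is assigned to at most one (lipid, stoichiometry), ties
    resolved by smallest |residual| with the ambiguity recorded per peak
    rather than silently discarded.
    """
    if not candidates:
        raise ValueError("need at least one candidate lipid")
    matches = []  # (|residual|, peak index, z, lipid name, k, residual)
    base_peaks = set(base.peak_indices)
    for z in base.charges:
        for lipid in candidates:
            for k in range(1, max_stoich + 1):
                target_mass = base.mass + k * lipid.average_mass
                target = (target_mass + z * PROTON_MASS) / z
                j = int(np.searchsorted(peaks.mz, target))
                for cand in (j - 1, j):
                    if not (0 <= cand < len(peaks)) or cand in base_peaks:
                        continue
                    residual = z * (peaks.mz[cand] - PROTON_MASS) - target_mass
                    if abs(residual) <= tol_da:
                        matches.append((abs(residual), cand, z, lipid.name, k, residual))

    matches.sort(key=lambda m: (m[0], m[1], m[2]))
    assigned: dict[int, tuple] = {}
    options: dict[int, list[tuple[float, str, int]]] = {}
    for absr, idx, z, name, k, residual in matches:
        options.setdefault(idx, []).append((absr, name, k))
        if idx not in assigned:
            assigned[idx] = (z, name, k, residual)
    # ambiguous: a distinct (lipid, k) competes within tol/2 of the best match,
    # i.e. the residuals cannot discriminate the candidates
    ambiguous = []
    for idx, opts in options.items():
        best_r, best_name, best_k = min(opts)
        rivals = [
            o for o in opts if (o[1], o[2]) != (best_name, best_k) and o[0] - best_r < tol_da / 2
        ]
        if rivals:
            ambiguous.append(idx)
    ambiguous = tuple(sorted(ambiguous))
    if ambiguous:
        logger.warning("ambiguous adduct assignment for peaks %s", ambiguous)

    rows = [
        {
            "charge": z,
            "lipid": name,
            "k": k,
            "peak_index": idx,
            "mz": float(peaks.mz[idx]),
            "intensity": float(peaks.intensity[idx]),
            "residual_da": residual,
        }
        for idx, (z, name, k, residual) in sorted(assigned.items())
    ]
    table = pd.DataFrame(rows, columns=["charge", "lipid", "k", "peak_index", "mz", "intensity", "residual_da"])
    apo = pd.DataFrame(
        {
            "charge": list(base.charges),
            "peak_index": list(base.peak_indices),
            "intensity": [float(peaks.intensity[j]) for j in base.peak_indices],
        }
    )
    return AdductAssignment(base.mass, max_stoich, table, apo, ambiguous)


def mole_fractions(adducts: AdductAssignment, aggregate: str = "summed") -> pd.DataFrame:
    """Bound-state mole fractions x_0..x_n from assigned intensities.

    ``aggregate="summed"`` normalises by the total intensity of all observed
    species across charge states (one row); ``"per_charge"`` returns one row
    per charge state.  Rows sum to 1 exactly.
    """
    n = adducts.max_stoich
    cols = [f"x{i}" for i in range(n + 1)]
    frames = []
    charges = sorted(set(adducts.apo["charge"]).union(adducts.table.get("charge", pd.Series(dtype=int))))
    for z in charges:
        inten = np.zeros(n + 1)
        inten[0] = adducts.apo.loc[adducts.apo["charge"] == z, "intensity"].sum()
        sub = adducts.table[adducts.table["charge"] == z] if len(adducts.table) else adducts.table
        if len(sub):
            for k, grp in sub.groupby("k"):
                inten[int(k)] += grp["intensity"].sum()
        frames.append((z, inten))
    if aggregate == "summed":
        total_vec = np.sum([v for _, v in frames], axis=0)
        total = total_vec.sum()
        if total <= 0:
            raise ValueError("zero total intensity; cannot form mole fractions")
        return pd.DataFrame([total_vec / total], columns=cols)
    if aggregate == "per_charge":
        rows = []
        for z, vec in frames:
            total = vec.sum()
            if total <= 0:
                raise ValueError(f"zero total intensity at charge {z}")
            rows.append([z, *(vec / total)])
        return pd.DataFrame(rows, columns=["charge", *cols])
    raise ValueError("aggregate must be 'summed' or 'per_charge'")


def significance_stars(p: float) -> str:
    """Figure-legend star convention at 0.05/0.01/0.001/0.0001."""
    if np.isnan(p):
        return "na"
    for threshold, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < threshold:
            return stars
    return "ns"


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed unpaired (Welch) t-test p-value with degenerate handling."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


@dataclass
class CompetitionResult:
    """Per-lipid intensity summary, ranking, and pairwise tests."""

    summary: pd.DataFrame
    pairwise: pd.DataFrame

    @property
    def ranking(self) -> list[str]:
        return list(self.summary.sort_values("mean", ascending=False)["lipid"])


def competition_compare(intensities: dict[str, np.ndarray] | pd.DataFrame) -> CompetitionResult:
    """Rank lipids by bound-peak intensity in a competition experiment.

    Input: replicate intensities of the singly bound peak per lipid, either a
    mapping lipid -> array or a tidy frame with columns lipid/replicate/
    intensity.  All lipids must carry the same replicate labels.  Pairwise
    two-tailed unpaired t-tests get figure-style significance stars.
    """
    if isinstance(intensities, pd.DataFrame):
        groups = {
            str(name): grp.sort_values("replicate")["intensity"].to_numpy(float)
            for name, grp in intensities.groupby("lipid")
        }
        labels = {
            str(name): tuple(grp.sort_values("replicate")["replicate"])
            for name, grp in intensities.groupby("lipid")
        }
        if len(set(labels.values())) > 1:
            raise ValueError(f"replicate labels differ between lipids: {labels}")
    else:
        groups = {str(k): np.asarray(v, float) for k, v in intensities.items()}
        if len({len(v) for v in groups.values()}) > 1:
            raise ValueError("all lipids must have the same number of replicates")
    if len(groups) < 2:
        raise ValueError("need at least two lipids to compare")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need at least two replicates per lipid")

    summary = pd.DataFrame(
        {
            "lipid": list(groups),
            "mean": [float(np.mean(v)) for v in groups.values()],
            "sd": [float(np.std(v, ddof=1)) for v in groups.values()],
            "n": [len(v) for v in groups.values()],
        }
    )
    summary["rank"] = summary["mean"].rank(ascending=False).astype(int)
    rows = []
    for a, b in itertools.combinations(groups, 2):
        p = _welch(groups[a], groups[b])
        rows.append(
            {
                "lipid_a": a,
                "lipid_b": b,
                "mean_diff": float(np.mean(groups[a]) - np.mean(groups[b])),
                "p_value": p,
                "stars": significance_stars(p),
            }
        )
    return CompetitionResult(summary, pd.DataFrame(rows))


@dataclass
class MixtureRatioResult:
    """Bound/apo intensity ratios for two co-analysed proteins."""

    ratios: pd.DataFrame
    p_value: float | None
    degenerate: bool

    @property
    def stars(self) -> str:
        return "na" if self.p_value is None else significance_stars(self.p_value)


def mixture_bound_ratio(data: pd.DataFrame) -> MixtureRatioResult:
    """Per-protein bound/apo ratio from a two-protein, one-ligand mixture.

    ``data`` columns: protein, replicate, apo_intensity, bound_intensity.  The
    ratio I_bound/I_apo is formed per replicate and compared across the two
    proteins by a two-tailed unpaired t-test; zero within-group variance in
    both groups is flagged degenerate and the test skipped with a warning.
    """
    proteins = list(dict.fromkeys(data["protein"]))
    if len(proteins) != 2:
        raise ValueError(f"expected exactly two proteins, got {proteins}")
    if (data["apo_intensity"] <= 0).any() or data["apo_intensity"].isna().any():
        raise ValueError("missing or non-positive apo peak intensity")
    work = data.copy()
    work["ratio"] = work["bound_intensity"] / work["apo_intensity"]
    groups = [work.loc[work["protein"] == p, "ratio"].to_numpy(float) for p in proteins]
    summary = (
        work.groupby("protein", sort=False)["ratio"].agg(["mean", "std", "count"]).reset_index()
    )
    if np.var(groups[0]) == 0 and np.var(groups[1]) == 0:
        if float(np.mean(groups[0])) == float(np.mean(groups[1])):
            return MixtureRatioResult(summary, 1.0, False)
        warnings.warn(
            "zero within-group variance in both proteins; t-test skipped", stacklevel=2
        )
        return MixtureRatioResult(summary, None, True)
    p = _welch(groups[0], groups[1])
    return MixtureRatioResult(summary, p, False)
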