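"""Sequential ligand-binding equilibria with depletion, and K_D fitting.

The model: a protein P binds up to n lipids L in sequential steps
``P.L_{i-1} + L <-> P.L_i`` with stepwise dissociation constants
``K_Di = [P.L_{i-1}][L] / [P.L_i]`` defined against *free* ligand.  The mole
fraction of the i-bound species is

    x_i = ([L]^i / prod_{j<=i} K_Dj) / sum_k ([L]^k / prod_{j<=k} K_Dk)

and the free-ligand concentration [L] is the unique non-negative root of the
mass balance ``[L] + P_tot * sum_i i*x_i([L]) = L_tot``.  Depletion matters
here because the protein concentration (5 uM in a typical native-MS titration)
is comparable to the first dissociation constants being measured; the
no-depletion approximation would bias the fits.

Fitting minimises squared residuals between predicted and observed mole
fractions over every species and concentration jointly, in log10-K_D space
with bounds, from multiple ladder-structured starting points.  Replicate
scatter feeds jackknife standard deviations.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

__all__ = [
    "BindingModel",
    "TitrationDesign",
    "EquilibriumState",
    "BindingFit",
    "EquilibriumError",
    "solve_equilibrium",
    "predict_titration",
    "fit_kds",
    "select_n_sites",
    "fraction_columns",
]

#: Default optimiser bounds on each K_D, in uM.
KD_BOUNDS = (1e-3, 1e4)


class EquilibriumError(RuntimeError):
    """Mass-balance root finding failed; carries bracketing diagnostics."""


@dataclass(frozen=True)
class BindingModel:
    """Stepwise dissociation constants K_D1..K_Dn in uM."""

    kds: tuple[float, ...]

    def __post_init__(self) -> None:
        kds = tuple(float(k) for k in self.kds)
        if len(kds) < 1:
            raise ValueError("at least one binding site is required")
        if any(k <= 0 or not math.isfinite(k) for k in kds):
            raise ValueError(f"all K_D values must be positive and finite: {kds}")
        object.__setattr__(self, "kds", kds)

    @property
    def n_sites(self) -> int:
        return len(self.kds)


@dataclass(frozen=True)
class TitrationDesign:
    """Total-concentration grid for a titration (concentrations in uM)."""

    l_tot_grid: tuple[float, ...]
    p_tot: float = 5.0
    replicates: int = 3

    def __post_init__(self) -> None:
        grid = tuple(float(c) for c in self.l_tot_grid)
        if self.p_tot <= 0:
            raise ValueError("p_tot must be positive")
        if any(c < 0 for c in grid):
            raise ValueError("total lipid concentrations must be non-negative")
        if any(b <= a for a, b in itertools.pairwise(grid)):
            raise ValueError("l_tot_grid must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        object.__setattr__(self, "l_tot_grid", grid)


@dataclass(frozen=True)
class EquilibriumState:
    """Free-ligand concentration and species mole fractions at one design point."""

    free_ligand: float
    fractions: tuple[float, ...]

    @property
    def bound_per_protein(self) -> float:
        return sum(i * x for i, x in enumerate(self.fractions))


def _species_fractions(kds: np.ndarray, free_l: float) -> np.ndarray:
    """Mole fractions x_0..x_n at a given free-ligand concentration."""
    # terms[i] = L^i / prod_{j<=i} K_Dj, computed iteratively for stability
    terms = np.empty(len(kds) + 1)
    terms[0] = 1.0
    for i, kd in enumerate(kds):
        terms[i + 1] = terms[i] * free_l / kd
    return terms / terms.sum()


def solve_equilibrium(
    model: BindingModel, p_tot: float, l_tot: float, rtol: float = 1e-12
) -> EquilibriumState:
    """Solve the depletion mass balance for one (P_tot, L_tot) design point."""
    if p_tot <= 0:
        raise ValueError("p_tot must be positive")
    if l_tot < 0:
        raise ValueError("l_tot must be non-negative")
    kds = np.asarray(model.kds)
    if l_tot == 0.0:
        fractions = tuple(1.0 if i == 0 else 0.0 for i in range(model.n_sites + 1))
        return EquilibriumState(0.0, fractions)

    def balance(free_l: float) -> float:
        x = _species_fractions(kds, free_l)
        bound = float(np.dot(np.arange(len(x)), x))
        return free_l + p_tot * bound - l_tot

    try:
        # balance(0) = -l_tot < 0 and balance(l_tot) >= 0, so the root is bracketed
        free_l = brentq(balance, 0.0, l_tot, xtol=1e-14 * max(1.0, l_tot), rtol=1e-15)
    except Exception as exc:  # pragma: no cover - defensive, bracket is analytic
        raise EquilibriumError(
            f"mass balance failed for l_tot={l_tot}: f(0)={balance(0.0):.3g}, "
            f"f(l_tot)={balance(l_tot):.3g}"
        ) from exc
    fractions = _species_fractions(kds, free_l)
    residual = abs(free_l + p_tot * np.dot(np.arange(len(fractions)), fractions) - l_tot)
    if residual > rtol * max(1.0, l_tot) * 1e2:
        raise EquilibriumError(
            f"mass balance residual {residual:.3g} exceeds tolerance at l_tot={l_tot}"
        )
    return EquilibriumState(float(free_l), tuple(float(x) for x in fractions))


def fraction_columns(n_sites: int) -> list[str]:
    return [f"x{i}" for i in range(n_sites + 1)]


def predict_titration(model: BindingModel, design: TitrationDesign) -> pd.DataFrame:
    """Noise-free mole-fraction table: one row per total-lipid concentration."""
    rows = []
    for l_tot in design.l_tot_grid:
        state = solve_equilibrium(model, design.p_tot, l_tot)
        rows.append([l_tot, *state.fractions])
    return pd.DataFrame(rows, columns=["lipid_conc_uM", *fraction_columns(model.n_sites)])


@dataclass
class BindingFit:
    """Result of fitting stepwise K_Ds to a mole-fraction table."""

    kds: tuple[float, ...]
    kd_sd: tuple[float, ...] | None
    r_squared: float
    sse: float
    converged: bool
    at_bounds: tuple[bool, ...]
    no_binding: bool
    n_sites: int
    residuals: pd.DataFrame = field(repr=False)
    n_obs: int = 0

    @property
    def kd1(self) -> float:
        return self.kds[0]


def _observed_matrix(data: pd.DataFrame, n_species: int) -> tuple[np.ndarray, np.ndarray]:
    """Extract (concentrations, fractions matrix) from a mole-fraction table."""
    cols = [c for c in data.columns if c.startswith("x") and c[1:].isdigit()]
    cols = sorted(cols, key=lambda c: int(c[1:]))
    obs = np.zeros((len(data), n_species))
    for j, col in enumerate(cols):
        if j < n_species:
            obs[:, j] = data[col].to_numpy(float)
    concs = data["lipid_conc_uM"].to_numpy(float)
    row_sums = obs.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-6):
        # data rows must be normalized mole fractions (columns beyond the
        # modeled stoichiometry still count toward the sum)
        extra = sum(data[c].to_numpy(float) for c in cols[n_species:]) if len(cols) > n_species else 0.0
        if np.any(np.abs(row_sums + extra - 1.0) > 1e-6):
            raise ValueError("mole-fraction rows must sum to 1")
    return concs, obs


def _predict_matrix(kds: np.ndarray, concs: np.ndarray, p_tot: float, n_species: int) -> np.ndarray:
    model = BindingModel(tuple(kds))
    pred = np.zeros((len(concs), n_species))
    cache: dict[float, tuple[float, ...]] = {}
    for i, l_tot in enumerate(concs):
        if l_tot not in cache:
            cache[l_tot] = solve_equilibrium(model, p_tot, l_tot).fractions
        frac = cache[l_tot]
        pred[i, : len(frac)] = frac
    return pred


def _single_fit(
    concs: np.ndarray,
    obs: np.ndarray,
    n_sites: int,
    p_tot: float,
    weights: np.ndarray | None,
    n_starts: int,
    bounds: tuple[float, float],
) -> tuple[np.ndarray, float, bool]:
    n_species = obs.shape[1]
    log_bounds = (math.log10(bounds[0]), math.log10(bounds[1]))
    w = np.ones_like(obs) if weights is None else weights

    def residuals(log_kds: np.ndarray) -> np.ndarray:
        pred = _predict_matrix(10.0 ** log_kds, concs, p_tot, n_species)
        return ((pred - obs) * w).ravel()

    # ladder-structured starts spanning 1e-2..1e3 uM for K_D1
    centers = np.logspace(-2, 3, n_starts)
    best = None
    for center in centers:
        start = np.log10(center * 3.0 ** np.arange(n_sites))
        start = np.clip(start, log_bounds[0] + 1e-9, log_bounds[1] - 1e-9)
        try:
            sol = least_squares(
                residuals,
                start,
                bounds=log_bounds,
                method="trf",
                xtol=1e-12,
                ftol=1e-14,
                gtol=1e-12,
            )
        except EquilibriumError:  # pragma: no cover - solver is robust on grid
            continue
        sse = float(np.sum(sol.fun**2))
        key = (sse, 10.0 ** sol.x[0])
        if best is None or key < best[0]:
            best = (key, sol.x, sol.success)
    if best is None:  # pragma: no cover
        raise RuntimeError("all optimization starts failed")
    _, log_kds, success = best
    return log_kds, best[0][0], bool(success)


def fit_kds(
    data: pd.DataFrame,
    n_sites: int,
    p_tot: float = 5.0,
    n_starts: int = 8,
    bounds: tuple[float, float] = KD_BOUNDS,
    weights: np.ndarray | None = None,
    jackknife: bool = True,
) -> BindingFit:
    """Weighted least-squares fit of K_D1..K_Dn to a mole-fraction table.

    ``data`` needs columns ``lipid_conc_uM``, ``x0..xk`` and optionally
    ``replicate``.  The fit runs in log10-K_D space from ``n_starts``
    ladder-structured starting points; ties among optima are broken by lowest
    SSE then lowest K_D1.  Standard deviations come from a leave-one-replicate-
    out jackknife when replicate labels are present.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    n_conc = data["lipid_conc_uM"].nunique()
    if n_conc < n_sites + 2:
        raise ValueError(
            f"need at least n_sites + 2 = {n_sites + 2} distinct concentrations, got {n_conc}"
        )
    n_species = max(
        n_sites + 1,
        1 + max((int(c[1:]) for c in data.columns if c.startswith("x") and c[1:].isdigit()), default=0),
    )
    concs, obs = _observed_matrix(data, n_species)
    log_kds, sse, converged = _single_fit(concs, obs, n_sites, p_tot, weights, n_starts, bounds)
    kds = tuple(float(k) for k in 10.0 ** log_kds)

    log_lo, log_hi = math.log10(bounds[0]), math.log10(bounds[1])
    at_bounds = tuple(bool(lk - log_lo < 1e-3 or log_hi - lk < 1e-3) for lk in log_kds)
    if any(at_bounds):
        warnings.warn("fit hit K_D bounds; estimates there are not identified", stacklevel=2)

    pred = _predict_matrix(np.asarray(kds), concs, p_tot, n_species)
    resid = obs - pred
    sst = float(np.sum((obs - obs.mean()) ** 2))
    r_squared = 1.0 - sse / sst if sst > 0 else float("nan")

    # "no binding": the data never leave the apo state appreciably
    no_binding = bool(obs[:, 1:].sum() < 0.01 * len(obs)) or all(at_bounds)

    kd_sd: tuple[float, ...] | None = None
    if jackknife and "replicate" in data.columns:
        reps = data["replicate"].unique()
        if len(reps) >= 2:
            jack = []
            for rep in reps:
                sub = data[data["replicate"] != rep]
                c_j, o_j = _observed_matrix(sub, n_species)
                lk_j, _, _ = _single_fit(c_j, o_j, n_sites, p_tot, None, n_starts, bounds)
                jack.append(10.0 ** lk_j)
            jack_arr = np.asarray(jack)
            m = len(reps)
            kd_sd = tuple(
                float(np.sqrt((m - 1) / m * np.sum((jack_arr[:, i] - jack_arr[:, i].mean()) ** 2)))
                for i in range(n_sites)
            )

    resid_df = pd.DataFrame(resid, columns=fraction_columns(n_species - 1))
    resid_df.insert(0, "lipid_conc_uM", concs)
    return BindingFit(
        kds=kds,
        kd_sd=kd_sd,
        r_squared=r_squared,
        sse=sse,
        converged=converged,
        at_bounds=at_bounds,
        no_binding=no_binding,
        n_sites=n_sites,
        residuals=resid_df,
        n_obs=obs.size,
    )


def select_n_sites(
    data: pd.DataFrame,
    p_tot: float = 5.0,
    max_sites: int = 4,
    **fit_kwargs,
) -> tuple[int, dict[int, BindingFit]]:
    """Fit n = 1..max_sites and select by small-sample-corrected AIC.

    Returns the chosen site count and the full per-n fit dictionary.  A flat
    (all-apo) table selects a model flagged ``no_binding`` with K_Ds at the
    upper bound.
    """
    fits: dict[int, BindingFit] = {}
    scores: dict[int, float] = {}
    for n in range(1, max_sites + 1):
        try:
            fit = fit_kds(data, n, p_tot=p_tot, jackknife=False, **fit_kwargs)
        except ValueError:
            continue
        fits[n] = fit
        n_obs = fit.n_obs
        k = n
        # AICc on gaussian SSE; floor avoids log(0) on exact synthetic data
        sse = max(fit.sse, n_obs * 1e-20)
        aicc = n_obs * math.log(sse / n_obs) + 2 * k
        if n_obs - k - 1 > 0:
            aicc += 2 * k * (k + 1) / (n_obs - k - 1)
        scores[n] = aicc
    if not fits:
        raise ValueError("no site count could be fitted to this table")
    chosen = min(scores, key=lambda n: (scores[n], n))
    return chosen, fits
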