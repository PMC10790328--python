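"""HDX-MS uptake analysis: RFU, differential uptake, synergy, projection.

Hydrogen-deuterium exchange MS reports backbone-amide solvent protection per
peptic peptide over a time course.  Relative fractional uptake (RFU) is the
measured deuterium uptake divided by the peptide's theoretical maximum
N_max = length - 1 - (prolines after the first residue): the first amide is
treated as fully back-exchanged and prolines have no amide hydrogen.  No
back-exchange correction is applied; RFU is a relative quantity.

Differential analysis compares a ligand-bound state against apo per peptide
and exposure (dRFU = RFU_state - RFU_apo) with a two-tailed unpaired Welch
t-test at alpha = 0.05 per cell (a Benjamini-Hochberg option exists but is
off by default, matching per-peptide star annotations).  The two-ligand
synergy statistic is S = dRFU_ternary - (dRFU_ligand1 + dRFU_ligand2); S > 0
means the two ligands together perturb a region more than the sum of their
individual effects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STATES",
    "Peptide",
    "CoverageStats",
    "max_uptake",
    "compute_rfu",
    "delta_rfu",
    "synergy",
    "coverage_stats",
    "project_to_residues",
    "heatmap_matrix",
    "pool_synergy",
]

logger = logging.getLogger(__name__)

#: Canonical state labels: apo, substrate, lipid, and the ternary complex.
STATES = ("apo", "S1P", "PIP2", "ternary")

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

_PEPTIDE_KEY = ["start", "end", "sequence"]


def max_uptake(sequence: str) -> int:
    """Number of exchange-competent backbone amides, N_max = L - 1 - prolines(2..L)."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    bad = set(sequence.upper()) - _STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues in {sequence!r}: {sorted(bad)}")
    return len(sequence) - 1 - sequence.upper()[1:].count("P")


@dataclass(frozen=True)
class Peptide:
    """A peptic peptide in 1-based inclusive coordinates."""

    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end < start for peptide {self.start}-{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match span "
                f"{self.start}-{self.end}"
            )

    @property
    def n_max(self) -> int:
        return max_uptake(self.sequence)

    @property
    def usable(self) -> bool:
        return self.n_max > 0


def _require_columns(df: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"uptake table is missing columns {missing}")


def compute_rfu(measurements: pd.DataFrame, min_replicates: int = 2) -> pd.DataFrame:
    """Mean RFU and SD per (peptide, state, exposure).

    Input is a tidy uptake table with columns start/end/sequence/state/
    exposure_min/replicate/uptake_da.  Groups with a single replicate raise;
    groups with two get a warning (the design expects n = 3).
    """
    _require_columns(
        measurements, _PEPTIDE_KEY + ["state", "exposure_min", "replicate", "uptake_da"]
    )
    if (measurements["uptake_da"] < 0).any():
        raise ValueError("negative uptake values")
    rows = []
    for (start, end, seq, state, t), grp in measurements.groupby(
        _PEPTIDE_KEY + ["state", "exposure_min"], sort=True
    ):
        n_max = max_uptake(seq)
        if n_max == 0:
            raise ValueError(f"peptide {start}-{end} ({seq!r}) has no exchangeable amides")
        n = len(grp)
        if n < min_replicates:
            raise ValueError(
                f"peptide {start}-{end} state {state} t={t}: only {n} replicate(s)"
            )
        if n == 2:
            logger.warning("peptide %s-%s state %s t=%s has only 2 replicates", start, end, state, t)
        uptake = grp["uptake_da"].to_numpy(float)
        rows.append(
            {
                "start": start,
                "end": end,
                "sequence": seq,
                "state": state,
                "exposure_min": t,
                "n": n,
                "n_max": n_max,
                "uptake_mean_da": float(uptake.mean()),
                "rfu": float(uptake.mean()) / n_max,
                "rfu_sd": float(uptake.std(ddof=1)) / n_max,
            }
        )
    return pd.DataFrame(rows).sort_values(["start", "end", "exposure_min"]).reset_index(drop=True)


def _replicate_rfus(measurements: pd.DataFrame) -> pd.DataFrame:
    out = measurements.copy()
    n_max = out["sequence"].map(max_uptake)
    if (n_max == 0).any():
        bad = out.loc[n_max == 0, "sequence"].unique()
        raise ValueError(f"peptides with no exchangeable amides: {bad}")
    out["rfu"] = out["uptake_da"] / n_max
    return out


def delta_rfu(
    measurements: pd.DataFrame,
    state: str,
    apo_state: str = "apo",
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-(peptide, exposure) dRFU = RFU_state - RFU_apo with Welch t-tests.

    Peptides present in only one of the two states are excluded and logged.
    Output rows are ordered by peptide start/end then exposure, ready for
    heatmap pivoting via :func:`heatmap_matrix`.
    """
    _require_columns(
        measurements, _PEPTIDE_KEY + ["state", "exposure_min", "replicate", "uptake_da"]
    )
    present = set(measurements["state"])
    for s in (state, apo_state):
        if s not in present:
            raise ValueError(f"state {s!r} not present in table (has {sorted(present)})")
    work = _replicate_rfus(measurements[measurements["state"].isin([state, apo_state])])
    rows = []
    for (start, end, seq, t), grp in work.groupby(_PEPTIDE_KEY + ["exposure_min"], sort=True):
        a = grp.loc[grp["state"] == apo_state, "rfu"].to_numpy(float)
        b = grp.loc[grp["state"] == state, "rfu"].to_numpy(float)
        if len(a) == 0 or len(b) == 0:
            logger.info("peptide %s-%s t=%s present in one state only; excluded", start, end, t)
            continue
        diff = float(b.mean() - a.mean())
        se = float(np.sqrt(np.var(b, ddof=1) / len(b) + np.var(a, ddof=1) / len(a)))
        if np.var(a) == 0 and np.var(b) == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            with warnings.catch_warnings():
                # near-identical replicates trip a precision RuntimeWarning
                warnings.simplefilter("ignore", RuntimeWarning)
                p = float(stats.ttest_ind(b, a, equal_var=False).pvalue)
        rows.append(
            {
                "start": start,
                "end": end,
                "sequence": seq,
                "exposure_min": t,
                "delta_rfu": diff,
                "se": se,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no peptide/exposure pairs shared between the two states")
    if bh_correction:
        out["p_adjusted"] = _benjamini_hochberg(out["p_value"].to_numpy())
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out.sort_values(["start", "end", "exposure_min"]).reset_index(drop=True)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def heatmap_matrix(differential: pd.DataFrame, value: str = "delta_rfu") -> pd.DataFrame:
    """Pivot a differential table to peptides (rows, ordered by start/end) x exposures."""
    return differential.pivot_table(
        index=["start", "end"], columns="exposure_min", values=value, sort=True
    )


def synergy(
    measurements: pd.DataFrame,
    alpha: float = 0.05,
    states: tuple[str, str, str, str] = STATES,
) -> pd.DataFrame:
    """Synergy S = dRFU_ternary - (dRFU_state1 + dRFU_state2) per peptide/exposure.

    Equivalently S = mean(ternary) - mean(s1) - mean(s2) + mean(apo) on the
    RFU scale; its variance is propagated across the four replicate groups and
    tested with a Welch-Satterthwaite t distribution.  One-sided (S > 0) and
    two-sided p-values are both reported; peptides missing any state are
    skipped and logged.
    """
    apo_state, state_a, state_b, ternary_state = states
    work = _replicate_rfus(measurements[measurements["state"].isin(states)])
    rows = []
    for (start, end, seq, t), grp in work.groupby(_PEPTIDE_KEY + ["exposure_min"], sort=True):
        series = {s: grp.loc[grp["state"] == s, "rfu"].to_numpy(float) for s in states}
        if any(len(v) < 2 for v in series.values()):
            logger.info("peptide %s-%s t=%s missing a state; skipped from synergy", start, end, t)
            continue
        means = {s: v.mean() for s, v in series.items()}
        s_stat = float(
            means[ternary_state] - means[state_a] - means[state_b] + means[apo_state]
        )
        contrib = {s: np.var(v, ddof=1) / len(v) for s, v in series.items()}
        var = float(sum(contrib.values()))
        if var == 0:
            p_two, p_one = (1.0, 0.5) if s_stat == 0 else (0.0, 0.0 if s_stat > 0 else 1.0)
            se = 0.0
        else:
            se = float(np.sqrt(var))
            dof = var**2 / sum(c**2 / (len(series[s]) - 1) for s, c in contrib.items())
            tval = s_stat / se
            p_two = float(2 * stats.t.sf(abs(tval), dof))
            p_one = float(stats.t.sf(tval, dof))
        rows.append(
            {
                "start": start,
                "end": end,
                "sequence": seq,
                "exposure_min": t,
                "synergy": s_stat,
                "se": se,
                "p_one_sided": p_one,
                "p_two_sided": p_two,
                "significant": p_one < alpha,
            }
        )
    if not rows:
        raise ValueError("no peptide/exposure pairs carry all four states")
    return pd.DataFrame(rows).sort_values(["start", "end", "exposure_min"]).reset_index(drop=True)


def pool_synergy(synergy_table: pd.DataFrame) -> tuple[float, float, float]:
    """Precision-weighted pooled synergy over a set of peptides.

    Returns (pooled S, pooled SE, one-sided p for S > 0) for region-level
    inference where individual short peptides are underpowered.  Peptides are
    weighted by N_max^2 — the known design precision, since RFU noise scales
    as 1/N_max — rather than by the n = 3 sample variances, whose estimates
    are too unstable to weight by.
    """
    s = synergy_table["synergy"].to_numpy(float)
    se = synergy_table["se"].to_numpy(float)
    w = synergy_table["sequence"].map(max_uptake).to_numpy(float) ** 2
    w = w / w.sum()
    pooled = float(np.sum(w * s))
    pooled_se = float(np.sqrt(np.sum(w**2 * se**2)))
    if pooled_se == 0:
        return pooled, 0.0, 0.0 if pooled > 0 else 1.0
    z = pooled / pooled_se
    return pooled, pooled_se, float(stats.norm.sf(z))


@dataclass(frozen=True)
class CoverageStats:
    n_peptides: int
    coverage_percent: float
    mean_redundancy: float


def coverage_stats(peptides: list[tuple[int, int]] | list[Peptide], sequence_length: int) -> CoverageStats:
    """Sequence coverage (%) and mean redundancy from a peptide map.

    Coverage is the union of residue intervals over the sequence length;
    redundancy is total peptide residues over covered residues.
    """
    covered: set[int] = set()
    total_len = 0
    n = 0
    for pep in peptides:
        start, end = (pep.start, pep.end) if isinstance(pep, Peptide) else (pep[0], pep[1])
        if start < 1 or end > sequence_length or end < start:
            raise ValueError(f"peptide {start}-{end} outside sequence of length {sequence_length}")
        covered.update(range(start, end + 1))
        total_len += end - start + 1
        n += 1
    if not covered:
        return CoverageStats(0, 0.0, 0.0)
    return CoverageStats(n, 100.0 * len(covered) / sequence_length, total_len / len(covered))


def project_to_residues(
    differential: pd.DataFrame,
    mode: str = "mean",
    value: str = "delta_rfu",
    length: int | None = None,
) -> pd.Series:
    """Project peptide-level values onto residues.

    ``mode="mean"`` averages over all covering peptides; ``mode="min_length"``
    takes the value of the shortest covering peptide (sharper localisation;
    ties broken by earliest start).  The table must contain a single exposure.
    Uncovered residues are NaN.
    """
    if differential.empty:
        raise ValueError("empty differential table")
    if differential["exposure_min"].nunique() > 1:
        raise ValueError("filter the differential table to a single exposure first")
    if mode not in ("mean", "min_length"):
        raise ValueError("mode must be 'mean' or 'min_length'")
    length = int(length or differential["end"].max())
    track = pd.Series(np.nan, index=pd.RangeIndex(1, length + 1, name="residue"), name=value)
    if mode == "mean":
        sums = np.zeros(length + 1)
        counts = np.zeros(length + 1)
        for row in differential.itertuples():
            sums[row.start : row.end + 1] += getattr(row, value)
            counts[row.start : row.end + 1] += 1
        mask = counts[1:] > 0
        track[mask] = sums[1:][mask] / counts[1:][mask]
    else:
        best_len = np.full(length + 1, np.inf)
        ordered = differential.sort_values(["start", "end"])
        for row in ordered.itertuples():
            plen = row.end - row.start + 1
            for r in range(row.start, row.end + 1):
                if plen < best_len[r]:
                    best_len[r] = plen
                    track.iloc[r - 1] = getattr(row, value)
    return track
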