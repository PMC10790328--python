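"""End-to-end pipelines chaining simulation/IO, fitting, and HDX analysis.

Each pipeline is deterministic given its configuration and seed, writes
diff-able CSV reports plus a JSON run log recording the package version and
every parameter, and aborts with a stage-tagged error on bad input.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .binding import BindingModel, TitrationDesign, fit_kds, predict_titration
from .hdx import STATES, delta_rfu, project_to_residues, synergy
from .io import (
    read_hdx_state_csv,
    read_mole_fractions_csv,
    write_bfactor_pdb,
    write_fit_report_csv,
    write_table_csv,
)

__all__ = ["RunConfig", "PipelineError", "run_binding_pipeline", "run_hdx_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration.

    Unknown keys in a config file are rejected rather than ignored, so typos
    cannot silently change an analysis.
    """

    input_dir: str = ""
    output_dir: str = "results"
    seed: int = 0
    n_sites: int = 4
    p_tot: float = 5.0
    aggregation: str = "summed"
    projection_mode: str = "mean"
    alpha: float = 0.05
    max_stoich: int = 4
    hdx_states: tuple[str, ...] = STATES
    structure_pdb: str = ""
    projection_exposure_min: float = 60.0

    def __post_init__(self) -> None:
        if self.aggregation not in ("summed", "per_charge"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.projection_mode not in ("mean", "min_length"):
            raise ValueError(f"unknown projection mode {self.projection_mode!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_sites < 1 or self.max_stoich < 1:
            raise ValueError("n_sites and max_stoich must be >= 1")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as handle:
            raw = tomllib.load(handle)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; known: {sorted(known)}")
        if "hdx_states" in raw:
            raw["hdx_states"] = tuple(raw["hdx_states"])
        return cls(**raw)


def _write_log(config: RunConfig, outdir: Path, extra: dict) -> None:
    log = {"msbind_version": __version__, "python": sys.version.split()[0]}
    log.update(dataclasses.asdict(config))
    log["hdx_states"] = list(config.hdx_states)
    log.update(extra)
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")


def run_binding_pipeline(config: RunConfig):
    """Mole-fraction CSVs -> pooled K_D fit -> report + predicted curves."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    indir = Path(config.input_dir)
    files = sorted(indir.glob("*.csv")) if indir.is_dir() else []
    if not files:
        raise PipelineError(f"input: no input mole-fraction CSVs found in {indir!s}")
    try:
        data = pd.concat([read_mole_fractions_csv(f) for f in files], ignore_index=True)
    except ValueError as exc:
        raise PipelineError(f"input: {exc}") from exc
    try:
        fit = fit_kds(data, n_sites=config.n_sites, p_tot=config.p_tot)
    except ValueError as exc:
        raise PipelineError(f"fit: {exc}") from exc
    write_fit_report_csv(fit, outdir / "fit_report.csv")
    grid = tuple(sorted(data["lipid_conc_uM"].unique()))
    curves = predict_titration(BindingModel(fit.kds), TitrationDesign(grid, p_tot=config.p_tot))
    write_table_csv(curves, outdir / "predicted_curves.csv")
    _write_log(config, outdir, {"stage": "binding", "n_input_files": len(files)})
    return fit


def run_hdx_pipeline(config: RunConfig):
    """State-data CSV -> per-state differentials, synergy, residue track."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    indir = Path(config.input_dir)
    files = sorted(indir.glob("*.csv")) if indir.is_dir() else []
    if not files:
        raise PipelineError(f"input: no HDX state-data CSVs found in {indir!s}")
    data = pd.concat([read_hdx_state_csv(f) for f in files], ignore_index=True)

    apo_state = config.hdx_states[0]
    observed = set(data["state"])
    unknown = observed - set(config.hdx_states)
    if unknown:
        raise PipelineError(
            f"input: unknown state labels {sorted(unknown)}; expected {list(config.hdx_states)}"
        )
    if len(observed) < 2 or apo_state not in observed:
        raise PipelineError(f"input: need the {apo_state!r} state plus at least one other")

    results: dict[str, pd.DataFrame] = {}
    for state in config.hdx_states[1:]:
        if state not in observed:
            continue
        diff = delta_rfu(data, state, apo_state=apo_state, alpha=config.alpha)
        write_table_csv(diff, outdir / f"differential_{state}.csv")
        results[f"differential_{state}"] = diff
    if observed >= set(config.hdx_states):
        syn = synergy(data, alpha=config.alpha, states=config.hdx_states)
        write_table_csv(syn, outdir / "synergy.csv")
        results["synergy"] = syn

    # per-peptide uptake plot tables (mean +- SD per state and exposure)
    from .hdx import compute_rfu

    uptake = compute_rfu(data)
    write_table_csv(uptake, outdir / "uptake_curves.csv")
    results["uptake"] = uptake

    if config.structure_pdb and results:
        first_state = config.hdx_states[1]
        diff = results.get(f"differential_{first_state}")
        if diff is not None:
            sub = diff[diff["exposure_min"] == config.projection_exposure_min]
            track = project_to_residues(sub, mode=config.projection_mode)
            write_bfactor_pdb(config.structure_pdb, outdir / "projection.pdb", track)
            write_table_csv(
                track.rename("delta_rfu").reset_index(), outdir / "residue_track.csv"
            )
    _write_log(config, outdir, {"stage": "hdx", "states": sorted(observed)})
    return results
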