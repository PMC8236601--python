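"""Orchestration of the four-stage workflow and its file artifacts.

Stages run in a fixed order -- WSS fixtures, stimulus reduction, endothelial
pore/transport state, Darcy + inflammation, growth -- each consuming the
previous stage's product. ``run_pipeline`` executes all of them into a run
directory with per-stage artifacts (CSV/HDF5/JSON) and a manifest carrying
the configuration hash, so identical configurations reproduce identical
outputs bit for bit.

``run_midcourse`` implements the two-pass experiment: integrate to a split
time, narrow the lumen with the accumulated growth, update the WSS via the
fixture flow model (Poiseuille R^-3 rescale plus a post-stenotic disturbance
surrogate) and finish the horizon on the updated stimulus.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig, config_hash
from .endothelium import (LDLPermeability, PoreState, build_pore_state,
                          ldl_apparent_permeability, ldl_influx)
from .errors import SolverError
from .growth import GrowthResult, compute_growth, update_geometry
from .haemo_fixtures import WSSTimeSeriesField, synthetic_wss_field, write_wss_table
from .stimulus import StimulusField, atheroprone_mask, compute_stimulus, shape_index
from .units import YEAR
from .wall_model import (SPECIES, InflammationResult, make_wall_mesh,
                         run_inflammation)

__all__ = ["run_pipeline", "run_single", "run_midcourse", "MidcourseResult",
           "stage_fixtures", "stage_stimulus", "stage_pores"]

log = logging.getLogger(__name__)

#: post-stenotic disturbance surrogate of the fixture flow model: downstream
#: of a constriction whose area stenosis exceeds the onset fraction, OSI is
#: raised to the peak stenosis fraction over a fixed recovery length
STENOSIS_DISTURBANCE_ONSET = 0.20   # area-stenosis fraction
RECOVERY_LENGTH_DIAMETERS = 4.0     # in healthy lumen diameters
OSI_DISTURBANCE_CAP = 0.45


def _mesh(config: SimulationConfig):
    g = config.geometry
    return make_wall_mesh(g.length, g.nx, g.nr, g.thickness, g.lumen_radius)


def stage_fixtures(config: SimulationConfig) -> WSSTimeSeriesField:
    """Generate the endothelial WSS time-series field."""
    mesh = _mesh(config)
    return synthetic_wss_field(config.waveform, config.patch, mesh.s,
                               lumen_radius=mesh.lumen_radius,
                               blood=config.blood, seed=config.seed)


def stage_stimulus(config: SimulationConfig,
                   wss: WSSTimeSeriesField) -> StimulusField:
    """Reduce the WSS history to TAWSS/OSI/SI and the atheroprone mask."""
    return compute_stimulus(wss, config.mode, config.correlation)


def stage_pores(config: SimulationConfig, stim: StimulusField
                ) -> tuple[PoreState, LDLPermeability, np.ndarray]:
    """Pore statistics, apparent LDL permeability and gated LDL influx."""
    pore = build_pore_state(stim.si, config.pore, config.p_lumen_mmhg)
    perm = ldl_apparent_permeability(pore, config.ldl, config.pore)
    j_ldl = ldl_influx(config.ldl.c_ldl_lumen, perm, config.ldl)
    return pore, perm, j_ldl * stim.atheroprone


def run_single(config: SimulationConfig,
               stimulus: StimulusField | None = None,
               horizon: float | None = None,
               initial_state=None) -> tuple[InflammationResult, GrowthResult]:
    """One full (single-pass) simulation: inflammation plus growth."""
    mesh = _mesh(config)
    if stimulus is None:
        stimulus = stage_stimulus(config, stage_fixtures(config))
    result = run_inflammation(
        mesh, stimulus,
        reaction_params=config.reaction,
        pore_params=config.pore,
        ldl_params=config.ldl,
        corr_params=config.correlation,
        p_lumen_mmhg=config.p_lumen_mmhg,
        horizon=horizon if horizon is not None else config.patient.horizon,
        options=config.solver,
        tawss_factor_literal=config.tawss_factor_literal,
        initial_state=initial_state,
        ldl_adventitia_bc=config.ldl_adventitia_bc,
    )
    return result, compute_growth(result, config.growth)


def _updated_stimulus(config: SimulationConfig, stim: StimulusField,
                      growth: GrowthResult) -> StimulusField:
    """Stimulus on the narrowed lumen via the fixture flow model.

    TAWSS rescales by (R0/R_new)^3 (Poiseuille at conserved flow); where the
    peak area stenosis exceeds the disturbance onset, a post-stenotic
    recirculation surrogate raises OSI downstream of the constriction over a
    few diameters. SI and the atheroprone mask are then re-evaluated.
    """
    r0, r_new = growth.lumen_radius0, growth.lumen_radius_new
    tawss = stim.tawss * (r0 / r_new) ** 3
    osi = stim.osi.copy()
    sev = growth.sr_profile / 100.0
    peak = float(sev.max())
    if peak >= STENOSIS_DISTURBANCE_ONSET:
        s = stim.node_positions
        constricted = sev >= STENOSIS_DISTURBANCE_ONSET
        s_edge = float(s[constricted].max())
        zone = (s > s_edge) & (
            s <= s_edge + RECOVERY_LENGTH_DIAMETERS * 2.0 * float(r0.max())
        )
        osi[zone] = np.maximum(osi[zone], min(OSI_DISTURBANCE_CAP, peak))
        log.info("post-stenotic disturbance active over %d stations "
                 "(peak area stenosis %.1f%%)", int(zone.sum()), 100 * peak)
    si = shape_index(config.mode, tawss, osi, config.correlation)
    mask = atheroprone_mask(tawss, osi, config.mode, config.correlation)
    return StimulusField(stim.node_positions.copy(), tawss, osi, si, mask,
                         stim.mode)


@dataclass
class MidcourseResult:
    """Outcome of the split-horizon geometry-update experiment."""

    single_pass: GrowthResult
    at_split: GrowthResult
    two_pass: GrowthResult
    stimulus_initial: StimulusField
    stimulus_updated: StimulusField
    run_single_pass: InflammationResult
    run_second_leg: InflammationResult


def run_midcourse(config: SimulationConfig,
                  split_time_years: float) -> MidcourseResult:
    """Split a run at ``split_time_years``, update geometry + WSS, finish.

    The wall species state carries across the split; the final growth is
    evaluated from the total species change over the full horizon, so a
    degenerate split at (or beyond) the horizon reproduces the single-pass
    result exactly.
    """
    horizon = config.patient.horizon
    split = split_time_years * YEAR
    mesh = _mesh(config)
    stim0 = stage_stimulus(config, stage_fixtures(config))
    run_sp, growth_sp = run_single(config, stimulus=stim0)
    if split >= horizon:
        return MidcourseResult(growth_sp, growth_sp, growth_sp,
                               stim0, stim0, run_sp, run_sp)

    run1, growth1 = run_single(config, stimulus=stim0, horizon=split)
    stim2 = _updated_stimulus(config, stim0, growth1)
    run2, _ = run_single(config, stimulus=stim2, horizon=horizon - split,
                         initial_state=run1.final)
    # total growth over the full horizon from the combined species change
    run2_total = InflammationResult(
        mesh, stim2, run2.pore, run2.perm, run2.darcy,
        [0.0, horizon], [run1.states[0], run2.final],
        run2.ledger, run1.n_steps + run2.n_steps, horizon,
    )
    growth_tp = compute_growth(run2_total, config.growth)
    return MidcourseResult(growth_sp, growth1, growth_tp, stim0, stim2,
                           run_sp, run2_total)


# --------------------------------------------------------------------------
# file-based pipeline
# --------------------------------------------------------------------------

def _write_checkpoints(path, result: InflammationResult) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("times_s", data=np.asarray(result.times))
        fh.create_dataset(
            "states", data=np.stack([s.data for s in result.states])
        )
        fh.attrs["species"] = ",".join(SPECIES)
        fh.create_dataset("s_axial_m", data=result.mesh.s)


def _yearly_summary(result: InflammationResult) -> pd.DataFrame:
    rows = []
    for t, state in zip(result.times, result.states):
        row = {"t_years": t / YEAR}
        for k, name in enumerate(SPECIES):
            row[f"max_{name}"] = float(state.data[..., k].max())
            row[f"mean_{name}"] = float(state.data[..., k].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: SimulationConfig, outdir,
                 update_at_years: float | None = None) -> dict:
    """Execute all stages into ``outdir``; returns the run summary dict.

    Every stage writes its artifact; failures abort with the stage name
    while earlier artifacts are retained.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config_hash(config),
                "package_version": __version__,
                "mode": config.mode, "seed": config.seed,
                "stages": []}

    def _stage(name, fn):
        try:
            value = fn()
        except (SolverError, Exception) as exc:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise SolverError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(name)
        return value

    wss = _stage("fixtures", lambda: stage_fixtures(config))
    write_wss_table(wss, out / "wss.csv")

    stim = _stage("stimulus", lambda: stage_stimulus(config, wss))
    stim.to_csv(out / "stimulus.csv")

    pore, perm, j_ldl = _stage("pores", lambda: stage_pores(config, stim))
    pd.DataFrame({
        "s_axial_m": stim.node_positions, "si": pore.si, "mc": pore.mc,
        "lc": pore.lc, "phi_lj": pore.phi_lj, "lp_lj": pore.lp_lj,
        "jv": pore.jv, "p_app": perm.p_app, "j_ldl": j_ldl,
    }).to_csv(out / "pores.csv", index=False, float_format="%.17g")

    if update_at_years is not None:
        mid = _stage("simulate+growth",
                     lambda: run_midcourse(config, update_at_years))
        result, growth = mid.run_second_leg, mid.two_pass
        mid.stimulus_updated.to_csv(out / "stimulus_updated.csv")
        extra = {"sr_single_pass": mid.single_pass.sr,
                 "sr_at_split": mid.at_split.sr,
                 "update_at_years": update_at_years}
    else:
        result, growth = _stage("simulate+growth",
                                lambda: run_single(config, stimulus=stim))
        extra = {}

    _write_checkpoints(out / "checkpoints.h5", result)
    _yearly_summary(result).to_csv(out / "species_summary.csv", index=False)
    growth.to_frame(result.mesh).to_csv(out / "growth.csv", index=False,
                                        float_format="%.17g")

    summary = {
        "sr_percent": growth.sr,
        "sr_station_m": float(result.mesh.s[growth.worst_station]),
        "horizon_years": growth.horizon / YEAR,
        "mode": config.mode,
        "n_steps": result.n_steps,
        "ledger": result.ledger,
        **extra,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
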