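"""Volumetric plaque growth and stenosis quantification.

Only the bulky constituents contribute to plaque volume: foam cells
(spheres of radius ``r_fc``), synthetic smooth muscle cells (ellipsoid-like,
volume (4/3) pi r^2 l as printed in the source correlation) and collagen
(through its density). Under small-strain isotropic growth the volumetric
source is

    div v = dC_FC/dt * Vol_FC + d(dC_SSMC)/dt * Vol_SSMC + dC_G/dt / rho_G,

realized by default as (final - initial)/horizon from the end state of the
inflammation run. Growth is applied columnarly: the transmural integral of
``div v * horizon`` at each axial station becomes an inward endothelial
displacement with the adventitia fixed, and the stenosis ratio

    SR(%) = (1 - A_plaque / A_healthy) * 100

is evaluated at the most occluded station.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .units import YEAR
from .wall_model import InflammationResult, WallMesh, _I

__all__ = [
    "GrowthParams",
    "GrowthResult",
    "cell_volumes",
    "growth_divergence",
    "update_geometry",
    "stenosis_ratio",
    "compute_growth",
    "midcourse_update",
]

log = logging.getLogger(__name__)

#: the lumen radius is never reduced below this fraction of the original
MIN_RADIUS_FRACTION = 0.05


@dataclass
class GrowthParams:
    """Cell geometry and collagen density entering the volume bookkeeping."""

    r_fc: float = 15.264e-6     # foam-cell radius (m)
    r_ssmc: float = 3.75e-6     # SSMC radius (m)
    l_ssmc: float = 115e-6      # SSMC length (m)
    rho_g: float = 1000.0       # collagen density (kg/m^3)
    ssmc_half_length: bool = False  # toggle: true ellipsoid with semi-axis l/2

    def __post_init__(self) -> None:
        for name in ("r_fc", "r_ssmc", "l_ssmc", "rho_g"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"GrowthParams.{name} must be > 0")


@dataclass
class GrowthResult:
    """Growth source, lumen displacement and stenosis of one run."""

    div_v: np.ndarray             # volumetric growth source (1/s), (nx, nr)
    wall_displacement: np.ndarray  # inward endothelial displacement (m), (nx,)
    lumen_radius0: np.ndarray     # healthy radius profile (m)
    lumen_radius_new: np.ndarray  # post-growth radius profile (m)
    sr: float                     # stenosis ratio (%) at the worst station
    sr_profile: np.ndarray        # stenosis ratio (%) per station
    horizon: float                # growth horizon (s)

    @property
    def worst_station(self) -> int:
        return int(np.argmax(self.sr_profile))

    def to_frame(self, mesh: WallMesh) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s_axial_m": mesh.s,
                "radius0_m": self.lumen_radius0,
                "radius_new_m": self.lumen_radius_new,
                "displacement_m": self.wall_displacement,
                "sr_percent": self.sr_profile,
            }
        )


def cell_volumes(params: GrowthParams | None = None) -> dict[str, float]:
    """Volumes (m^3) of one foam cell and one synthetic SMC.

    The SSMC volume uses the printed correlation (4/3) pi R^2 l with ``l``
    the full cell length; ``ssmc_half_length`` switches to the geometric
    ellipsoid with semi-axis l/2 (half the printed value).
    """
    p = params or GrowthParams()
    vol_fc = (4.0 / 3.0) * np.pi * p.r_fc**3
    length = p.l_ssmc / 2.0 if p.ssmc_half_length else p.l_ssmc
    vol_ssmc = (4.0 / 3.0) * np.pi * p.r_ssmc**2 * length
    return {"vol_fc": vol_fc, "vol_ssmc": vol_ssmc}


def growth_divergence(delta_fc: np.ndarray, delta_ssmc: np.ndarray,
                      delta_g: np.ndarray,
                      params: GrowthParams | None = None) -> np.ndarray:
    """Volumetric growth source div v from species rate-of-change fields.

    The ``delta_*`` arguments are time derivatives (concentration change per
    second vs the initial state); in the final-stationary-step mode the
    caller passes (final - initial)/horizon.
    """
    p = params or GrowthParams()
    delta_fc = np.asarray(delta_fc, dtype=float)
    delta_ssmc = np.asarray(delta_ssmc, dtype=float)
    delta_g = np.asarray(delta_g, dtype=float)
    if not delta_fc.shape == delta_ssmc.shape == delta_g.shape:
        raise InvalidParameterError("growth delta fields must share one shape")
    vols = cell_volumes(p)
    return (delta_fc * vols["vol_fc"] + delta_ssmc * vols["vol_ssmc"]
            + delta_g / p.rho_g)


def stenosis_ratio(area_with_plaque: float, area_without: float) -> float:
    """Percent area stenosis, (1 - A_plaque/A_healthy) * 100."""
    if area_without <= 0:
        raise InvalidParameterError("healthy lumen area must be > 0")
    if area_with_plaque > area_without * (1.0 + 1e-12):
        raise InvalidParameterError(
            "lumen area with plaque exceeds the healthy area (negative SR)"
        )
    if area_with_plaque < 0:
        raise InvalidParameterError("lumen area must be >= 0")
    return (1.0 - area_with_plaque / area_without) * 100.0


def update_geometry(mesh: WallMesh, div_v: np.ndarray,
                    horizon: float) -> GrowthResult:
    """Convert the growth source into lumen narrowing and stenosis.

    Columnar small-strain isotropic growth: per axial station the added
    volume per unit endothelial area is the transmural integral of
    ``div_v * horizon``, applied as inward displacement with the adventitia
    fixed. The lumen radius is floored at 5 % of the healthy radius (capped
    displacements are logged).
    """
    div_v = np.asarray(div_v, dtype=float)
    if div_v.shape != (mesh.nx, mesh.nr):
        raise InvalidParameterError(
            f"div_v shape {div_v.shape} != mesh shape {(mesh.nx, mesh.nr)}"
        )
    if not np.all(np.isfinite(div_v)):
        raise InvalidParameterError("div_v must be finite")
    displacement = div_v.sum(axis=1) * mesh.dr * horizon
    r0 = mesh.lumen_radius
    floor = MIN_RADIUS_FRACTION * r0
    r_new = r0 - displacement
    capped = r_new < floor
    if np.any(capped):
        log.warning("lumen displacement capped at %d of %d stations",
                    int(capped.sum()), mesh.nx)
        r_new = np.maximum(r_new, floor)
    r_new = np.minimum(r_new, r0)  # growth never widens the lumen
    sr_profile = (1.0 - (r_new / r0) ** 2) * 100.0
    return GrowthResult(div_v, r0 - r_new, r0.copy(), r_new,
                        float(sr_profile.max()), sr_profile, horizon)


def compute_growth(result: InflammationResult,
                   params: GrowthParams | None = None) -> GrowthResult:
    """Final-stationary-step growth from an inflammation run.

    Species deltas are taken between the final checkpoint and the initial
    state and divided by the horizon (the four-step workflow's closing
    stationary step).
    """
    p = params or GrowthParams()
    first, last = result.states[0].data, result.states[-1].data
    h = result.horizon
    div_v = growth_divergence(
        (last[..., _I["fc"]] - first[..., _I["fc"]]) / h,
        (last[..., _I["ssmc"]] - first[..., _I["ssmc"]]) / h,
        (last[..., _I["g"]] - first[..., _I["g"]]) / h,
        p,
    )
    return update_geometry(result.mesh, div_v, h)


def midcourse_update(config, split_time_years: float):
    """Two-pass run: grow to the split time, update the geometry and WSS,
    then finish the horizon on the updated state.

    Thin forwarding wrapper over the pipeline orchestrator (kept here so the
    growth API owns the experiment; imported lazily to avoid a module cycle).
    Returns a :class:`~plaquesim.pipeline.MidcourseResult` with both the
    single-pass and the two-pass outcomes.
    """
    from .pipeline import run_midcourse

    return run_midcourse(config, split_time_years)
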