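"""Three-pore Kedem–Katchalsky transport across the endothelium.

The endothelium is modelled as a membrane with three parallel pathways:
normal junctions, leaky junctions (widened clefts around mitotic/dying cells)
and vesicular transcytosis. The shape index SI of the endothelial cells sets
the local density of leaky junctions through two experimental correlations

    MC = 0.003797 * exp(14.75 * SI)        (mitotic cells per 0.64 mm^2)
    LC = 0.307 + 0.805 * MC^0.453          (leaky cells per 0.64 mm^2)

from which the leaky-junction area fraction, hydraulic conductivity, plasma
flux J_v, apparent LDL permeability and the endothelial solute influx boundary
conditions of the wall model follow. Large molecules such as LDL (radius
11 nm) cannot pass normal junctions, so their transport is carried by leaky
junctions plus a vesicular contribution fixed at 10 % of the leaky-junction
one.

The single-slit hindered-transport closure (partition coefficient, diffusive
hindrance, solvent-drag reflection, entrance-gradient factor) is exposed as
pluggable functions so an alternative pore theory can be substituted without
touching callers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import InvalidParameterError
from .units import BODY_TEMPERATURE, BOLTZMANN, DAY, MMHG

__all__ = [
    "PoreModelParams",
    "PoreState",
    "LDLTransportParams",
    "LDLPermeability",
    "mitotic_count",
    "leaky_count",
    "leaky_fraction",
    "pressure_drop",
    "single_lj_conductivity",
    "lj_conductivity",
    "plasma_flux",
    "ldl_apparent_permeability",
    "ldl_influx",
    "monocyte_influx",
    "build_pore_state",
    "stokes_einstein_diffusivity",
    "slit_partition",
    "slit_diffusive_hindrance",
    "slit_reflection_coefficient",
]


@dataclass
class PoreModelParams:
    """Geometry and hydraulics of the endothelial pore model.

    Units: lengths m, viscosity Pa s, conductivities m/(s Pa), pressures of
    ``dp_table``/``p_adv`` in mmHg (converted where used), ``k_w`` m^2.
    """

    r_cell: float = 15e-6          # endothelial cell radius
    w_l: float = 20e-9             # leaky-junction half-width
    l_lj: float = 2e-6             # leaky-junction length
    mu_p: float = 0.001            # plasma viscosity
    rho_p: float = 1050.0          # plasma density
    lp_nj: float = 1.984e-12       # normal-junction hydraulic conductivity
    a_unit: float = 0.64e-6        # unit area of the experimental correlations
    dp_table: tuple = ((70.0, 18.0), (180.0, 28.0))  # mmHg -> mmHg
    p_adv: float = 17.5            # adventitial pressure (mmHg)
    k_w: float = 1.2e-18           # Darcian wall permeability
    eps_w: float = 0.96            # intima porosity

    def __post_init__(self) -> None:
        for name in ("r_cell", "w_l", "l_lj", "mu_p", "rho_p", "lp_nj",
                     "a_unit", "k_w", "eps_w"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"PoreModelParams.{name} must be > 0")


@dataclass
class PoreState:
    """Per-node pore statistics and plasma fluxes (all arrays node-shaped)."""

    si: np.ndarray
    mc: np.ndarray
    lc: np.ndarray
    phi_lj: np.ndarray
    ap_s: np.ndarray
    lp_slj: float
    lp_lj: np.ndarray
    jv_nj: np.ndarray
    jv_lj: np.ndarray
    jv_v: np.ndarray
    jv: np.ndarray


def stokes_einstein_diffusivity(radius: float, mu: float = 0.001,
                                temperature: float = BODY_TEMPERATURE) -> float:
    """Free diffusivity of a sphere in plasma, kT/(6 pi mu a)."""
    return BOLTZMANN * temperature / (6.0 * np.pi * mu * radius)


def slit_partition(alpha: float) -> float:
    """Steric partition coefficient of a sphere in a slit, 1 - alpha."""
    return 1.0 - alpha


def slit_diffusive_hindrance(alpha: float) -> float:
    """Centerline diffusive hindrance H_d for a sphere in a slit.

    Polynomial fit valid on alpha in [0, 1) (Dechadilok–Deen form).
    """
    return (1.0 - 1.004 * alpha + 0.418 * alpha**3
            + 0.21 * alpha**4 - 0.169 * alpha**5)


def slit_reflection_coefficient(alpha: float) -> float:
    """Solvent-drag reflection sigma_f = 1 - W, W = phi*(3 - phi^2)/2.

    Parabolic velocity profile across the slit, partitioned solute, no
    hydrodynamic lag: W is the ratio of solute to solvent mean velocity.
    """
    phi = slit_partition(alpha)
    return 1.0 - phi * (3.0 - phi**2) / 2.0


@dataclass
class LDLTransportParams:
    """Parameters of LDL (and monocyte) transport across the endothelium.

    ``d_free`` defaults to the Stokes–Einstein value at body temperature for
    the 11 nm LDL radius. The hindered-transport closure functions are
    pluggable; explicit ``*_override`` values win over the closure.
    """

    a_m: float = 11e-9                     # LDL molecule radius (m)
    d_free: float | None = None            # free diffusivity (m^2/s)
    ldl_dep: float = 1e-2                  # deposited fraction (dimensionless)
    c_ldl_lumen: float = 6.98              # lumen LDL (mol/m^3)
    c_ldl_adv_frac: float = 11.6e-3        # adventitial LDL fraction of lumen
    k_lag: float = 0.893                   # solute lag coefficient of LDL
    rho_ldl: float = 1063.0                # LDL density (kg/m^3)
    mw_ldl: float = 386.65                 # LDL molecular weight (g/mol)
    m_r: float = 6.636e-4 / DAY            # monocyte recruitment (m^4/(mol s))
    c_m_lumen: float = 550e9               # lumen monocytes (cells/m^3)
    partition_fn: Callable[[float], float] = slit_partition
    hindrance_fn: Callable[[float], float] = slit_diffusive_hindrance
    reflection_fn: Callable[[float], float] = slit_reflection_coefficient
    z_lj_override: float | None = None
    sigma_f_lj_override: float | None = None
    p_slj_override: float | None = None

    def __post_init__(self) -> None:
        if self.d_free is None:
            self.d_free = stokes_einstein_diffusivity(self.a_m)


@dataclass
class LDLPermeability:
    """Permeability decomposition of the endothelium for LDL (m/s)."""

    alpha_lj: float
    chi: float
    p_slj: float
    z_lj: float
    sigma_f_lj: float
    p_lj: np.ndarray
    p_app_lj: np.ndarray
    p_app_v: np.ndarray
    p_app: np.ndarray


def mitotic_count(si):
    """Mitotic cells per 0.64 mm^2 unit area, 0.003797*exp(14.75*SI)."""
    si = np.asarray(si, dtype=float)
    if np.any((si < 0) | (si > 1)):
        raise InvalidParameterError("shape index must be in [0, 1]")
    out = 0.003797 * np.exp(14.75 * si)
    return out[()] if out.ndim == 0 else out


def leaky_count(mc):
    """Leaky cells per 0.64 mm^2 unit area, 0.307 + 0.805*MC^0.453."""
    mc = np.asarray(mc, dtype=float)
    if np.any(mc < 0):
        raise InvalidParameterError("mitotic count must be >= 0")
    out = 0.307 + 0.805 * mc**0.453
    return out[()] if out.ndim == 0 else out


def leaky_fraction(lc, params: PoreModelParams | None = None):
    """Leaky-junction area fraction Phi_lj = LC*pi*R_cell^2 / A_unit."""
    p = params or PoreModelParams()
    lc = np.asarray(lc, dtype=float)
    out = lc * np.pi * p.r_cell**2 / p.a_unit
    return out[()] if out.ndim == 0 else out


def pressure_drop(p_lumen_mmhg: float, params: PoreModelParams | None = None) -> float:
    """Endothelial pressure drop (mmHg) by linear interpolation of the anchors.

    Anchors default to (70 -> 18) and (180 -> 28) mmHg; values outside the
    anchor range extrapolate linearly with a warning.
    """
    p = params or PoreModelParams()
    xs = np.array([row[0] for row in p.dp_table], dtype=float)
    ys = np.array([row[1] for row in p.dp_table], dtype=float)
    if not (xs[0] <= p_lumen_mmhg <= xs[-1]):
        warnings.warn(
            f"intraluminal pressure {p_lumen_mmhg} mmHg outside the "
            f"[{xs[0]}, {xs[-1]}] mmHg anchor range; extrapolating",
            stacklevel=2,
        )
    slope = (ys[-1] - ys[0]) / (xs[-1] - xs[0])
    if p_lumen_mmhg <= xs[0]:
        return float(ys[0] + slope * (p_lumen_mmhg - xs[0]))
    if p_lumen_mmhg >= xs[-1]:
        return float(ys[-1] + slope * (p_lumen_mmhg - xs[-1]))
    return float(np.interp(p_lumen_mmhg, xs, ys))


def single_lj_conductivity(params: PoreModelParams | None = None) -> float:
    """Hydraulic conductivity of one leaky junction, w_l^2/(3 mu_p l_lj)."""
    p = params or PoreModelParams()
    return p.w_l**2 / (3.0 * p.mu_p * p.l_lj)


def lj_conductivity(phi_lj, params: PoreModelParams | None = None):
    """Leaky-junction conductivity Lp_lj and area fraction Ap/S.

    Returns ``(lp_lj, ap_s)`` with Ap/S = (4 w_l / R_cell) * Phi_lj and
    Lp_lj = Ap/S * Lp_slj.
    """
    p = params or PoreModelParams()
    phi_lj = np.asarray(phi_lj, dtype=float)
    if np.any(phi_lj < 0):
        raise InvalidParameterError("phi_lj must be >= 0")
    ap_s = (4.0 * p.w_l / p.r_cell) * phi_lj
    lp_lj = ap_s * single_lj_conductivity(p)
    if ap_s.ndim == 0:
        return lp_lj[()], ap_s[()]
    return lp_lj, ap_s


def plasma_flux(lp_lj, params: PoreModelParams | None = None,
                p_lumen_mmhg: float = 100.0):
    """Plasma volume flux J_v (m/s) through the three pathways.

    The vesicular contribution is identically zero (kept for audit output);
    J_v = Lp_nj*dP + Lp_lj*dP with dP the endothelial pressure drop in Pa.
    """
    p = params or PoreModelParams()
    lp_lj = np.asarray(lp_lj, dtype=float)
    dp_pa = pressure_drop(p_lumen_mmhg, p) * MMHG
    jv_nj = np.broadcast_to(p.lp_nj * dp_pa, lp_lj.shape).copy()
    jv_lj = lp_lj * dp_pa
    jv_v = np.zeros_like(jv_lj)
    return jv_nj, jv_lj, jv_v, jv_nj + jv_lj + jv_v


def build_pore_state(si, params: PoreModelParams | None = None,
                     p_lumen_mmhg: float = 100.0) -> PoreState:
    """Chain SI -> MC -> LC -> Phi_lj -> Lp_lj -> J_v for a node array."""
    p = params or PoreModelParams()
    si = np.atleast_1d(np.asarray(si, dtype=float))
    mc = mitotic_count(si)
    lc = leaky_count(mc)
    phi = leaky_fraction(lc, p)
    lp_lj, ap_s = lj_conductivity(phi, p)
    jv_nj, jv_lj, jv_v, jv = plasma_flux(lp_lj, p, p_lumen_mmhg)
    return PoreState(si, mc, lc, phi, ap_s, single_lj_conductivity(p),
                     lp_lj, jv_nj, jv_lj, jv_v, jv)


def ldl_apparent_permeability(
    pore: PoreState,
    params: LDLTransportParams | None = None,
    pore_params: PoreModelParams | None = None,
) -> LDLPermeability:
    """Apparent endothelial permeability of LDL.

    P_app = P_app,lj + P_app,v with P_app,v = 0.1*P_app,lj and

        P_app,lj = P_lj/Z_lj + Jv_lj*(1 - sigma_f,lj),
        P_lj     = (Ap/S / chi) * P_slj,

    where chi = 1 - alpha_lj and P_slj comes from the slit-pore hindered-
    diffusion closure (or its override).
    """
    lp = params or LDLTransportParams()
    pp = pore_params or PoreModelParams()
    alpha = lp.a_m / pp.w_l
    if alpha >= 1.0:
        raise InvalidParameterError(
            f"LDL radius {lp.a_m} m exceeds leaky-junction half-width {pp.w_l} m"
        )
    chi = 1.0 - alpha
    if lp.p_slj_override is not None:
        p_slj = lp.p_slj_override
    else:
        p_slj = lp.partition_fn(alpha) * lp.hindrance_fn(alpha) * lp.d_free / pp.l_lj
    z_lj = 1.0 if lp.z_lj_override is None else lp.z_lj_override
    sigma = (lp.reflection_fn(alpha) if lp.sigma_f_lj_override is None
             else lp.sigma_f_lj_override)
    p_lj = (pore.ap_s / chi) * p_slj
    p_app_lj = p_lj / z_lj + pore.jv_lj * (1.0 - sigma)
    p_app_v = 0.1 * p_app_lj
    return LDLPermeability(alpha, chi, p_slj, z_lj, sigma,
                           p_lj, p_app_lj, p_app_v, p_app_lj + p_app_v)


def ldl_influx(c_ldl_lumen: float, perm: LDLPermeability,
               params: LDLTransportParams | None = None):
    """Endothelial LDL solute flux J_S,LDL (mol/(m^2 s)).

    Kedem–Katchalsky flux through leaky junctions plus the 10 % vesicular
    pathway: 1.1 * (C_LDL,l * LDL_dep) * P_app,lj with LDL_dep the deposited
    *fraction* (dimensionless).
    """
    lp = params or LDLTransportParams()
    if c_ldl_lumen < 0:
        raise InvalidParameterError("lumen LDL concentration must be >= 0")
    return 1.1 * c_ldl_lumen * lp.ldl_dep * perm.p_app_lj


def monocyte_influx(factor, c_ldlox_wall, params: LDLTransportParams | None = None,
                    saturation=1.0):
    """Endothelial monocyte flux J_s,m (cells/(m^2 s)).

    m_r * stimulus factor * C_LDLox,w * C_m,l, optionally multiplied by the
    wall-side saturation max(0, 1 - C_m,w/C_m,th) supplied by the caller.
    Recruitment vanishes without oxidized LDL at the wall.
    """
    lp = params or LDLTransportParams()
    c_ldlox_wall = np.asarray(c_ldlox_wall, dtype=float)
    if np.any(c_ldlox_wall < 0):
        raise InvalidParameterError("wall oxidized-LDL concentration must be >= 0")
    out = lp.m_r * np.asarray(factor, dtype=float) * c_ldlox_wall * lp.c_m_lumen
    out = out * np.clip(np.asarray(saturation, dtype=float), 0.0, None)
    return out[()] if out.ndim == 0 else out
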