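"""Darcy plasma flow and the nine-species inflammation network in the wall.

The arterial wall (intima/media) is a 2D axial x transmural porous domain.
Plasma filtration obeys Darcy's law with the endothelial plasma flux J_v
imposed as inflow and the adventitial pressure anchored; nine species --
LDL, oxidized LDL, monocytes, macrophages, cytokines, contractile and
synthetic smooth muscle cells, foam cells and collagen -- evolve by
convection-diffusion-reaction:

    dc/dt + div(-D grad c) + K_lag * u_w . grad c = f(c).

Only LDL convects (with the solute lag K_lag); LDL, oxidized LDL, monocytes
and macrophages diffuse; the remaining species are reaction-only. The
reaction network couples LDL oxidation, macrophage uptake and foam-cell
formation, cytokine signalling, smooth-muscle phenotype switching and
collagen turnover, and is integrated with a vectorized L-stable TR-BDF2
scheme nested inside an operator-split macro step (reaction, then implicit
finite-volume transport). A mass ledger tracks endothelial influx,
adventitial exchange and oxidative conversion of LDL so that conservation can
be audited per run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import ConfigurationError, InvalidParameterError, SolverError
from .units import DAY, MMHG, YEAR
from . import endothelium as endo
from . import stimulus as stim_mod

__all__ = [
    "SPECIES",
    "WallMesh",
    "make_wall_mesh",
    "DarcyState",
    "SpeciesFields",
    "ReactionParams",
    "SolverOptions",
    "reaction_sources",
    "reaction_jacobian",
    "integrate_reactions",
    "darcy_solve",
    "SpeciesTransport",
    "advance_species",
    "run_inflammation",
    "InflammationResult",
]

#: species order used throughout field arrays of shape (..., 9)
SPECIES = ("ldl", "ldlox", "m", "M", "c", "csmc", "ssmc", "fc", "g")
_I = {name: k for k, name in enumerate(SPECIES)}

#: species with diffusion (Table defaults); LDL additionally convects
DIFFUSING = ("ldl", "ldlox", "m", "M")


# --------------------------------------------------------------------------
# mesh
# --------------------------------------------------------------------------

@dataclass
class WallMesh:
    """Structured axial x transmural wall mesh (cell-centered).

    Fields live on ``(nx, nr)`` arrays; transmural index ``j = 0`` is the
    cell adjacent to the endothelium, ``j = nr - 1`` adjacent to the
    adventitia. The thin-wall approximation treats the wall as locally
    Cartesian (unit circumferential depth).
    """

    s: np.ndarray            # axial cell centers (m), shape (nx,)
    ds: float
    nr: int
    thickness: float         # wall thickness (m)
    lumen_radius: np.ndarray  # per-station healthy lumen radius (m)

    def __post_init__(self) -> None:
        if self.nr < 3:
            raise InvalidParameterError("need >= 3 transmural nodes")
        if not self.thickness > 0:
            raise InvalidParameterError("thickness must be > 0")
        self.s = np.asarray(self.s, dtype=float)
        self.lumen_radius = np.broadcast_to(
            np.asarray(self.lumen_radius, dtype=float), self.s.shape
        ).copy()

    @property
    def nx(self) -> int:
        return self.s.size

    @property
    def dr(self) -> float:
        return self.thickness / self.nr

    @property
    def r(self) -> np.ndarray:
        """Transmural cell centers, 0 at the endothelium."""
        return (np.arange(self.nr) + 0.5) * self.dr

    @property
    def cell_volume(self) -> float:
        return self.ds * self.dr


def make_wall_mesh(length: float = 0.06, nx: int = 50, nr: int = 20,
                   thickness: float = 0.7e-3,
                   lumen_radius: float | np.ndarray = 2e-3) -> WallMesh:
    """Uniform wall mesh over an axial extent ``[0, length]``."""
    ds = length / nx
    s = (np.arange(nx) + 0.5) * ds
    return WallMesh(s, ds, nr, thickness, lumen_radius)


# --------------------------------------------------------------------------
# parameters and state containers
# --------------------------------------------------------------------------

@dataclass
class ReactionParams:
    """Kinetics, thresholds and wall diffusivities of the nine species.

    All rates in SI (s^-1 or per the stated composite unit); literature
    values quoted per day are converted here.
    """

    d_ldl: float = 2.85e-4            # LDL oxidation rate (1/s)
    d_m: float = 1.15e-6              # monocyte -> macrophage differentiation (1/s)
    m_d: float = (1.0 / 60.0) / DAY   # monocyte natural death (1/s)
    ldl_ox_r: float = 2.45e-23        # LDLox uptake per macrophage (m^3/(cells s))
    n_fc: float = 2.72e-11            # LDLox a macrophage ingests to foam (mol/cells)
    c_r: float = 3e-10                # cytokine production (m^3/(cells s))
    d_c: float = 2.3148e-5            # cytokine degradation (1/s)
    s_r: float = 0.0036               # CSMC differentiation (1/s)
    p_ss: float = 0.24 / DAY          # SSMC proliferation (1/s)
    g_r: float = 2.472e-21            # collagen secretion (kg/(cells s))
    d_g: float = (1.0 / 30.0) / DAY   # collagen degradation (1/s)
    k_c: float = 0.65093              # cytokine threshold factor
    r_apop: float = 0.087             # SSMC apoptosis rate (1/s)
    c_m_th: float = 550e9             # monocyte threshold (cells/m^3)
    c_c_th: float = 1.235e13          # cytokine threshold (mol/m^3)
    c_ssmc_th: float = 4.764e13       # SSMC threshold (cells/m^3)
    c_csmc0: float = 3.16e13          # initial CSMC concentration (cells/m^3)
    d_ldl_w: float = 8e-13            # wall diffusivities (m^2/s)
    d_ldlox_w: float = 8e-13
    d_m_w: float = 8e-15
    d_M_w: float = 1e-15
    k_lag: float = 0.893              # solute lag coefficient of LDL

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"ReactionParams.{name} must be >= 0")

    def diffusivities(self) -> dict[str, float]:
        return {"ldl": self.d_ldl_w, "ldlox": self.d_ldlox_w,
                "m": self.d_m_w, "M": self.d_M_w}

    def reference_scales(self) -> np.ndarray:
        """Characteristic magnitude per species, used in error norms."""
        return np.array([7.0, 7.0, self.c_m_th, self.c_m_th, self.c_c_th,
                         self.c_csmc0, self.c_ssmc_th, self.c_csmc0, 1.0])

    def guard_levels(self) -> np.ndarray:
        """Blow-up guard: abort when any field exceeds 1e3 x its reference.

        Printed thresholds are used where they exist (m, c, ssmc); species
        without one use a generic reference (lumen LDL for the lipids, the
        SMC threshold for cell species, collagen density scale for collagen).
        """
        return 1e3 * np.array([7.0, 7.0, self.c_m_th, self.c_ssmc_th,
                               self.c_c_th, self.c_ssmc_th, self.c_ssmc_th,
                               self.c_ssmc_th, 1000.0])


@dataclass
class SolverOptions:
    """Time-integration controls of the inflammation run."""

    dt_init: float = 3600.0           # first macro step (s)
    dt_max: float = 30.0 * DAY        # macro step cap (s)
    dt_growth: float = 1.3            # macro step ramp factor
    rtol: float = 1e-5                # reaction integrator relative tolerance
    atol_scale: float = 1e-6          # atol = atol_scale * species reference
    max_newton: int = 12
    max_retries: int = 20
    checkpoint_interval: float = YEAR


@dataclass
class SpeciesFields:
    """Nine concentration fields on the wall mesh, ``data[(nx, nr, 9)]``."""

    data: np.ndarray

    @classmethod
    def initial(cls, mesh: WallMesh, params: ReactionParams) -> "SpeciesFields":
        """All-zero wall except the contractile SMC population."""
        data = np.zeros((mesh.nx, mesh.nr, len(SPECIES)))
        data[:, :, _I["csmc"]] = params.c_csmc0
        return cls(data)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[..., _I[name]]

    def copy(self) -> "SpeciesFields":
        return SpeciesFields(self.data.copy())

    def total_mass(self, mesh: WallMesh) -> np.ndarray:
        """Per-species content integrated over the wall (per unit depth)."""
        return self.data.sum(axis=(0, 1)) * mesh.cell_volume


@dataclass
class DarcyState:
    """Wall pressure (Pa) and face-normal filtration velocities (m/s).

    ``u_r`` has shape ``(nx, nr + 1)`` (transmural faces, positive toward the
    adventitia; face 0 is the endothelium); ``u_s`` has shape ``(nx + 1, nr)``
    (axial faces, positive toward increasing s).
    """

    p: np.ndarray
    u_r: np.ndarray
    u_s: np.ndarray


# --------------------------------------------------------------------------
# reaction network
# --------------------------------------------------------------------------

def reaction_sources(y: np.ndarray, p: ReactionParams) -> np.ndarray:
    """Volumetric source/sink of every species, shape-preserving.

    ``y[..., :]`` follows :data:`SPECIES`. LDL oxidizes; oxidized LDL is
    consumed by macrophages, which turn into foam cells after ingesting
    ``n_fc`` of it; cytokines produced by that interaction drive the
    contractile->synthetic SMC switch; SSMCs proliferate logistically, die by
    apoptosis and secrete collagen, which degrades first-order.
    """
    y = np.asarray(y, dtype=float)
    ldl, lox, m, M, c, csmc, ssmc, fc, g = (y[..., k] for k in range(9))
    f = np.empty_like(y)
    uptake = p.ldl_ox_r * lox * M
    s1 = c / (p.k_c * p.c_c_th + c)
    s2 = c / (p.c_c_th / 2.0 + c)
    f[..., _I["ldl"]] = -p.d_ldl * ldl
    f[..., _I["ldlox"]] = p.d_ldl * ldl - uptake
    f[..., _I["m"]] = -(p.d_m + p.m_d) * m
    f[..., _I["M"]] = p.d_m * m - uptake / p.n_fc
    f[..., _I["c"]] = p.c_r * lox * M - p.d_c * c
    f[..., _I["csmc"]] = -csmc * p.s_r * s1
    f[..., _I["ssmc"]] = (csmc * p.s_r * s1
                          + p.p_ss * s2 * ssmc * (1.0 - ssmc / p.c_ssmc_th)
                          - p.r_apop * ssmc)
    f[..., _I["fc"]] = uptake / p.n_fc
    f[..., _I["g"]] = p.g_r * ssmc - p.d_g * g
    return f


def reaction_jacobian(y: np.ndarray, p: ReactionParams) -> np.ndarray:
    """Analytic Jacobian of :func:`reaction_sources`, shape ``(..., 9, 9)``."""
    y = np.asarray(y, dtype=float)
    lox = y[..., _I["ldlox"]]
    M = y[..., _I["M"]]
    c = y[..., _I["c"]]
    csmc = y[..., _I["csmc"]]
    ssmc = y[..., _I["ssmc"]]
    jac = np.zeros(y.shape[:-1] + (9, 9))
    k1 = p.k_c * p.c_c_th
    k2 = p.c_c_th / 2.0
    s1 = c / (k1 + c)
    ds1 = k1 / (k1 + c) ** 2
    s2 = c / (k2 + c)
    ds2 = k2 / (k2 + c) ** 2

    jac[..., 0, 0] = -p.d_ldl
    jac[..., 1, 0] = p.d_ldl
    jac[..., 1, 1] = -p.ldl_ox_r * M
    jac[..., 1, 3] = -p.ldl_ox_r * lox
    jac[..., 2, 2] = -(p.d_m + p.m_d)
    jac[..., 3, 2] = p.d_m
    jac[..., 3, 1] = -(p.ldl_ox_r / p.n_fc) * M
    jac[..., 3, 3] = -(p.ldl_ox_r / p.n_fc) * lox
    jac[..., 4, 1] = p.c_r * M
    jac[..., 4, 3] = p.c_r * lox
    jac[..., 4, 4] = -p.d_c
    jac[..., 5, 4] = -p.s_r * csmc * ds1
    jac[..., 5, 5] = -p.s_r * s1
    jac[..., 6, 4] = (p.s_r * csmc * ds1
                      + p.p_ss * ds2 * ssmc * (1.0 - ssmc / p.c_ssmc_th))
    jac[..., 6, 5] = p.s_r * s1
    jac[..., 6, 6] = p.p_ss * s2 * (1.0 - 2.0 * ssmc / p.c_ssmc_th) - p.r_apop
    jac[..., 7, 1] = (p.ldl_ox_r / p.n_fc) * M
    jac[..., 7, 3] = (p.ldl_ox_r / p.n_fc) * lox
    jac[..., 8, 6] = p.g_r
    jac[..., 8, 8] = -p.d_g
    return jac


_GAMMA = 2.0 - np.sqrt(2.0)
_C_BDF2 = (1.0 - _GAMMA) / (2.0 - _GAMMA)
_W_G = 1.0 / (_GAMMA * (2.0 - _GAMMA))
_W_N = (1.0 - _GAMMA) ** 2 / (_GAMMA * (2.0 - _GAMMA))
_C_ERR = (-3.0 * _GAMMA**2 + 4.0 * _GAMMA - 2.0) / (12.0 * (2.0 - _GAMMA))


def _newton_stage(y_guess, rhs, coef, p, weights, max_iter):
    """Solve y - coef*f(y) = rhs for a batch of nodes; None on failure."""
    y = y_guess.copy()
    eye = np.eye(9)
    for _ in range(max_iter):
        jac = reaction_jacobian(y, p)
        mat = eye - coef * jac
        res = y - coef * reaction_sources(y, p) - rhs
        try:
            delta = np.linalg.solve(mat, res[..., None])[..., 0]
        except np.linalg.LinAlgError:
            return None
        y = y - delta
        if not np.all(np.isfinite(y)):
            return None
        err = np.sqrt(np.mean((delta / weights) ** 2))
        if err < 1e-3:
            return y
    return None


def integrate_reactions(y0: np.ndarray, t_span: float, p: ReactionParams,
                        rtol: float = 1e-5, atol: np.ndarray | None = None,
                        h0: float | None = None, max_newton: int = 12,
                        max_steps: int = 200_000) -> np.ndarray:
    """Advance the reaction network over ``t_span`` for a batch of nodes.

    Adaptive TR-BDF2 (trapezoidal stage to ``gamma*h``, BDF2 completion),
    L-stable and second order, with an embedded third-derivative error
    estimate. ``y0`` has shape ``(..., 9)``; the integration is vectorized
    over the leading axes with a shared step size.
    """
    if atol is None:
        atol = rtol * p.reference_scales()
    y = np.asarray(y0, dtype=float).copy()
    t = 0.0
    h = min(h0 or t_span, t_span)
    steps = 0
    while t < t_span * (1.0 - 1e-14):
        h = min(h, t_span - t)
        if steps > max_steps:
            raise SolverError("reaction integrator exceeded max_steps")
        steps += 1
        weights = atol + rtol * np.abs(y)
        f0 = reaction_sources(y, p)
        # trapezoidal stage to t + gamma*h
        rhs_g = y + (_GAMMA * h / 2.0) * f0
        y_g = _newton_stage(y + _GAMMA * h * f0, rhs_g, _GAMMA * h / 2.0,
                            p, weights, max_newton)
        y_new = None
        if y_g is not None:
            # BDF2 completion stage to t + h
            rhs_n = _W_G * y_g - _W_N * y
            y_new = _newton_stage(y_g, rhs_n, _C_BDF2 * h, p, weights, max_newton)
        if y_new is None:
            h *= 0.25
            if h < 1e-12 * t_span:
                raise SolverError("reaction Newton iteration failed to converge")
            continue
        f_g = reaction_sources(y_g, p)
        f_n = reaction_sources(y_new, p)
        est = 2.0 * _C_ERR * h * ((f_n - f_g) / (1.0 - _GAMMA)
                                  - (f_g - f0) / _GAMMA)
        # filter the estimate through the stage matrix so that stiff
        # components do not force the step below their (resolved) transients
        mat = np.eye(9) - (_C_BDF2 * h) * reaction_jacobian(y_new, p)
        try:
            est = np.linalg.solve(mat, est[..., None])[..., 0]
        except np.linalg.LinAlgError:
            pass
        err = np.sqrt(np.mean((est / weights) ** 2))
        if err <= 1.0:
            t += h
            # round tiny Newton undershoots up to exact zero
            y = np.where(y_new < 0, np.where(y_new > -weights, 0.0, y_new), y_new)
            if np.any(y < 0):
                y = np.maximum(y, 0.0)
        h = h * min(4.0, max(0.1, 0.9 * (max(err, 1e-10)) ** (-1.0 / 3.0)))
    return y


# --------------------------------------------------------------------------
# Darcy flow
# --------------------------------------------------------------------------

def darcy_solve(mesh: WallMesh, pore, params: endo.PoreModelParams | None = None,
                p_lumen_mmhg: float = 100.0,
                adventitia_anchor: bool = True) -> DarcyState:
    """Steady Darcy pressure and filtration velocity in the wall.

    Boundary data: the endothelial plasma flux ``J_v`` per axial station is
    imposed as normal inflow, the adventitial pressure is anchored at
    ``params.p_adv`` (Dirichlet) and the lateral edges are no-flux. Velocity
    follows ``u = -(k_w/mu_p) grad p`` (flow runs down the pressure
    gradient, lumen to adventitia).
    """
    pp = params or endo.PoreModelParams()
    jv = pore.jv if isinstance(pore, endo.PoreState) else np.asarray(pore, dtype=float)
    if jv.shape != (mesh.nx,):
        raise InvalidParameterError("J_v must have one value per axial station")
    if not adventitia_anchor:
        raise ConfigurationError(
            "all-Neumann Darcy problem is singular; the adventitial pressure "
            "anchor is required"
        )
    nx, nr = mesh.nx, mesh.nr
    ds, dr = mesh.ds, mesh.dr
    kappa = pp.k_w / pp.mu_p
    p_adv_pa = pp.p_adv * MMHG
    n = nx * nr
    idx = lambda i, j: i * nr + j  # noqa: E731

    rows, cols, vals = [], [], []
    b = np.zeros(n)
    # transmural interior faces
    w_r = kappa * ds / dr
    for j in range(1, nr):
        a = idx(np.arange(nx), j - 1)
        c = idx(np.arange(nx), j)
        for (r_, c_, v_) in ((a, a, w_r), (a, c, -w_r), (c, c, w_r), (c, a, -w_r)):
            rows.append(r_)
            cols.append(c_)
            vals.append(np.full(nx, v_))
    # axial interior faces
    w_s = kappa * dr / ds
    for i in range(1, nx):
        a = idx(i - 1, np.arange(nr))
        c = idx(i, np.arange(nr))
        for (r_, c_, v_) in ((a, a, w_s), (a, c, -w_s), (c, c, w_s), (c, a, -w_s)):
            rows.append(r_)
            cols.append(c_)
            vals.append(np.full(nr, v_))
    # endothelium: prescribed volumetric inflow per station
    cells = idx(np.arange(nx), 0)
    b[cells] += jv * ds
    # adventitia: Dirichlet through the half cell
    w_d = kappa * ds / (dr / 2.0)
    cells = idx(np.arange(nx), nr - 1)
    rows.append(cells)
    cols.append(cells)
    vals.append(np.full(nx, w_d))
    b[cells] += w_d * p_adv_pa

    mat = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    p_flat = splu(mat.tocsc()).solve(b)
    p = p_flat.reshape(nx, nr)

    u_r = np.zeros((nx, nr + 1))
    u_r[:, 0] = jv
    u_r[:, 1:nr] = -kappa * (p[:, 1:] - p[:, :-1]) / dr
    u_r[:, nr] = -kappa * (p_adv_pa - p[:, nr - 1]) / (dr / 2.0)
    u_s = np.zeros((nx + 1, nr))
    u_s[1:nx, :] = -kappa * (p[1:, :] - p[:-1, :]) / ds
    return DarcyState(p, u_r, u_s)


# --------------------------------------------------------------------------
# species transport
# --------------------------------------------------------------------------

class SpeciesTransport:
    """Implicit finite-volume diffusion/convection operators on the mesh.

    One sparse operator per diffusing species, assembled once (the flow and
    the stimulus are frozen during a run). LDL carries upwinded convection at
    ``k_lag`` times the filtration velocity; its adventitial boundary is
    one-way by default (``"outflow"``: convective export only, no diffusive
    re-entry from the adventitial LDL level) with the two-way Dirichlet at
    ``c_ldl_adv`` available as ``"dirichlet"``. The other diffusing species
    have zero-flux walls except the endothelial influx.
    """

    def __init__(self, mesh: WallMesh, darcy: DarcyState | None,
                 params: ReactionParams,
                 c_ldl_adv: float = 0.0,
                 ldl_adventitia_bc: str = "outflow",
                 linear_reactions_in_transport: bool = True) -> None:
        if ldl_adventitia_bc not in ("outflow", "dirichlet"):
            raise ConfigurationError(
                "ldl_adventitia_bc must be 'outflow' or 'dirichlet'"
            )
        self.mesh = mesh
        self.params = params
        self.c_ldl_adv = c_ldl_adv
        self.ldl_adventitia_bc = ldl_adventitia_bc
        self._u_adv = (params.k_lag * darcy.u_r[:, mesh.nr]
                       if darcy is not None else np.zeros(mesh.nx))
        # LDL oxidation and monocyte differentiation/death are linear and
        # much faster than the macro step (turnover ~1 h and ~9 d against
        # steps up to 30 d), so they are solved inside the implicit transport
        # operators (exact reaction-transport balance at any step size); the
        # converted mass is handed to the oxidized-LDL / macrophage fields
        # consistently and the reaction substep runs with those rates zeroed.
        self.linear_reactions_in_transport = linear_reactions_in_transport
        self._decay = {}
        if linear_reactions_in_transport:
            self._decay = {"ldl": params.d_ldl, "m": params.d_m + params.m_d}
        self.ops: dict[str, sp.csr_matrix] = {}
        self.rhs_const: dict[str, np.ndarray] = {}
        self._lu_cache: dict[tuple[str, float], object] = {}
        diff = params.diffusivities()
        for name in DIFFUSING:
            conv = name == "ldl" and darcy is not None
            dirichlet = name == "ldl" and ldl_adventitia_bc == "dirichlet"
            mat, rhs = self._assemble(diff[name], darcy if conv else None,
                                      dirichlet)
            if name in self._decay:
                mat = (mat + self._decay[name]
                       * sp.identity(mat.shape[0], format="csr")).tocsr()
            self.ops[name] = mat
            self.rhs_const[name] = rhs

    def _assemble(self, d_coef: float, darcy: DarcyState | None,
                  adv_dirichlet: bool):
        mesh = self.mesh
        nx, nr, ds, dr = mesh.nx, mesh.nr, mesh.ds, mesh.dr
        n = nx * nr
        idx = lambda i, j: i * nr + j  # noqa: E731
        rows, cols, vals = [], [], []
        rhs = np.zeros(n)

        def add(r_, c_, v_):
            rows.append(np.atleast_1d(r_))
            cols.append(np.atleast_1d(c_))
            vals.append(np.broadcast_to(v_, np.atleast_1d(r_).shape).astype(float))

        # diffusion, transmural faces
        w = d_coef / dr**2
        for j in range(1, nr):
            a = idx(np.arange(nx), j - 1)
            c = idx(np.arange(nx), j)
            add(a, a, w), add(a, c, -w), add(c, c, w), add(c, a, -w)
        # diffusion, axial faces
        w = d_coef / ds**2
        for i in range(1, nx):
            a = idx(i - 1, np.arange(nr))
            c = idx(i, np.arange(nr))
            add(a, a, w), add(a, c, -w), add(c, c, w), add(c, a, -w)
        # adventitial Dirichlet through the half cell
        if adv_dirichlet:
            cells = idx(np.arange(nx), nr - 1)
            w = 2.0 * d_coef / dr**2
            add(cells, cells, w)
            rhs[cells] += w * self.c_ldl_adv
        # upwinded convection at k_lag * u
        if darcy is not None:
            klag = self.params.k_lag
            for j in range(1, nr):
                u = klag * darcy.u_r[:, j]
                a = idx(np.arange(nx), j - 1)
                c = idx(np.arange(nx), j)
                up = np.where(u > 0, a, c)
                rate = np.abs(u) / dr
                sgn_out = np.where(u > 0, 1.0, -1.0)
                # outflow from upwind cell, inflow to the other
                add(up, up, rate)
                other = np.where(u > 0, c, a)
                add(other, up, -rate)
            for i in range(1, nx):
                u = klag * darcy.u_s[i, :]
                a = idx(i - 1, np.arange(nr))
                c = idx(i, np.arange(nr))
                up = np.where(u > 0, a, c)
                rate = np.abs(u) / ds
                add(up, up, rate)
                other = np.where(u > 0, c, a)
                add(other, up, -rate)
            # advective outflow through the adventitial face
            u_out = klag * darcy.u_r[:, nr]
            cells = idx(np.arange(nx), nr - 1)
            add(cells, cells, np.maximum(u_out, 0.0) / dr)
        mat = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        return mat, rhs

    def _lu(self, name: str, dt: float):
        key = (name, float(dt))
        if key not in self._lu_cache:
            if len(self._lu_cache) > 64:
                self._lu_cache.clear()
            n = self.ops[name].shape[0]
            mat = sp.identity(n, format="csc") + dt * self.ops[name].tocsc()
            self._lu_cache[key] = splu(mat)
        return self._lu_cache[key]

    def step(self, state: SpeciesFields, influx: dict[str, np.ndarray],
             dt: float,
             saturated_influx: dict[str, tuple[np.ndarray, float]] | None = None,
             ) -> dict[str, float]:
        """One implicit transport step in place; returns boundary-flux audit.

        ``influx[name]`` is the endothelial solute flux per station (amount
        /(m^2 s)), entering the ``j = 0`` cells as a Neumann source.
        ``saturated_influx[name] = (j0, c_th)`` instead applies the flux
        ``j0 * (1 - c/c_th)`` with the wall-side concentration taken
        implicitly, which keeps the endothelial cells bounded by ``c_th``
        at any step size.
        """
        mesh = self.mesh
        nx, nr, dr, ds = mesh.nx, mesh.nr, mesh.dr, mesh.ds
        endo_cells = np.arange(nx) * nr
        saturated_influx = saturated_influx or {}
        audit: dict[str, float] = {}
        for name in DIFFUSING:
            c = state[name].reshape(-1).copy()
            rhs = c + dt * self.rhs_const[name]
            j_in = influx.get(name)
            if j_in is not None:
                rhs[endo_cells] += dt * j_in / dr
                audit[f"influx_{name}"] = float(np.sum(j_in) * ds * dt)
            if self.linear_reactions_in_transport:
                if name == "ldlox":
                    # oxidation source consistent with the implicit LDL loss
                    rhs += dt * self.params.d_ldl * state["ldl"].reshape(-1)
                elif name == "M":
                    # monocyte differentiation consistent with the implicit
                    # monocyte turnover (the m_d fraction dies)
                    rhs += dt * self.params.d_m * state["m"].reshape(-1)
            sat = saturated_influx.get(name)
            if sat is not None:
                j0, c_th = sat
                j0 = np.where(c[endo_cells] >= c_th, 0.0, j0)
                rhs[endo_cells] += dt * j0 / dr
                n = self.ops[name].shape[0]
                diag = np.zeros(n)
                diag[endo_cells] = j0 / (dr * c_th)
                mat = (sp.identity(n, format="csc")
                       + dt * (self.ops[name].tocsc() + sp.diags(diag).tocsc()))
                c_new = splu(mat).solve(rhs)
                j_act = j0 * (1.0 - c_new[endo_cells] / c_th)
                audit[f"influx_{name}"] = (audit.get(f"influx_{name}", 0.0)
                                           + float(np.sum(j_act) * ds * dt))
            else:
                c_new = self._lu(name, dt).solve(rhs)
            state[name][...] = c_new.reshape(nx, nr)
            if name == "ldl" and self.linear_reactions_in_transport:
                audit["oxidized_ldl"] = float(
                    dt * self.params.d_ldl * c_new.sum() * mesh.cell_volume
                )
            if name == "ldl":
                # adventitial exchange evaluated on the implicit solution
                edge = state["ldl"][:, nr - 1]
                convective = np.maximum(self._u_adv, 0.0) * edge
                if self.ldl_adventitia_bc == "dirichlet":
                    d_coef = self.params.diffusivities()["ldl"]
                    diffusive = 2.0 * d_coef / dr * (edge - self.c_ldl_adv)
                else:
                    diffusive = 0.0
                audit["outflux_adv_ldl"] = float(
                    np.sum(diffusive + convective) * ds * dt
                )
        return audit


def advance_species(state: SpeciesFields, transport: SpeciesTransport,
                    influx: dict[str, np.ndarray], params: ReactionParams,
                    dt: float, options: SolverOptions | None = None,
                    saturated_influx: dict | None = None,
                    ) -> tuple[SpeciesFields, dict[str, float]]:
    """One operator-split macro step: stiff reaction solve, then transport.

    Returns the advanced state (a copy) and a step audit with the oxidized
    LDL mass and the boundary fluxes (all per unit circumferential depth).
    """
    from dataclasses import replace as _replace

    opts = options or SolverOptions()
    mesh = transport.mesh
    new = state.copy()
    flat = new.data.reshape(-1, 9)
    if transport.linear_reactions_in_transport:
        # the linear LDL and monocyte kinetics live in the transport solve
        rp = _replace(params, d_ldl=0.0, d_m=0.0, m_d=0.0)
    else:
        rp = params
    ldl_before = float(flat[:, _I["ldl"]].sum()) * mesh.cell_volume
    flat[...] = integrate_reactions(flat, dt, rp, rtol=opts.rtol,
                                    atol=opts.atol_scale * params.reference_scales(),
                                    h0=dt, max_newton=opts.max_newton)
    ldl_after = float(flat[:, _I["ldl"]].sum()) * mesh.cell_volume
    audit = {"oxidized_ldl": ldl_before - ldl_after}
    step_audit = transport.step(new, influx, dt, saturated_influx)
    audit["oxidized_ldl"] += step_audit.pop("oxidized_ldl", 0.0)
    audit.update(step_audit)
    clipped = np.minimum(new.data, 0.0).sum(axis=(0, 1)) * mesh.cell_volume
    if np.any(clipped < 0):
        audit["clipped_mass"] = float(-clipped.sum())
        np.maximum(new.data, 0.0, out=new.data)
    return new, audit


# --------------------------------------------------------------------------
# full inflammation run
# --------------------------------------------------------------------------

@dataclass
class InflammationResult:
    """Checkpointed trajectory of a wall inflammation run."""

    mesh: WallMesh
    stimulus: stim_mod.StimulusField
    pore: endo.PoreState
    perm: endo.LDLPermeability
    darcy: DarcyState
    times: list
    states: list
    ledger: dict
    n_steps: int
    horizon: float

    @property
    def final(self) -> SpeciesFields:
        return self.states[-1]


def run_inflammation(
    mesh: WallMesh,
    stimulus: stim_mod.StimulusField,
    reaction_params: ReactionParams | None = None,
    pore_params: endo.PoreModelParams | None = None,
    ldl_params: endo.LDLTransportParams | None = None,
    corr_params: stim_mod.CorrelationParams | None = None,
    p_lumen_mmhg: float = 100.0,
    horizon: float = 30.0 * YEAR,
    options: SolverOptions | None = None,
    tawss_factor_literal: bool = False,
    initial_state: SpeciesFields | None = None,
    ldl_adventitia_bc: str = "outflow",
) -> InflammationResult:
    """Integrate the wall species from 0 to ``horizon`` under a frozen stimulus.

    The stimulus, the pore state, the endothelial permeability and the Darcy
    flow are computed once (one-way coupling); species influx is applied only
    at atheroprone endothelial stations, and the monocyte influx saturates as
    the wall-side monocyte concentration approaches its threshold. The macro
    step ramps geometrically from ``dt_init`` to ``dt_max``; a blow-up guard
    aborts when any field exceeds 1e3 x its reference level.
    """
    rp = reaction_params or ReactionParams()
    pp = pore_params or endo.PoreModelParams()
    lp = ldl_params or endo.LDLTransportParams()
    cp = corr_params or stim_mod.CorrelationParams()
    opts = options or SolverOptions()

    pore = endo.build_pore_state(stimulus.si, pp, p_lumen_mmhg)
    perm = endo.ldl_apparent_permeability(pore, lp, pp)
    darcy = darcy_solve(mesh, pore, pp, p_lumen_mmhg)
    mask = stimulus.atheroprone.astype(float)
    j_ldl = endo.ldl_influx(lp.c_ldl_lumen, perm, lp) * mask
    m_factor = stim_mod.monocyte_flux_factor(
        stimulus.mode, stimulus.tawss, stimulus.osi, cp,
        tawss_factor_literal=tawss_factor_literal,
    )
    c_adv = lp.c_ldl_adv_frac * lp.c_ldl_lumen
    transport = SpeciesTransport(mesh, darcy, rp, c_ldl_adv=c_adv,
                                 ldl_adventitia_bc=ldl_adventitia_bc)

    state = (initial_state.copy() if initial_state is not None
             else SpeciesFields.initial(mesh, rp))
    guard = rp.guard_levels()
    ledger = {"influx_ldl": 0.0, "influx_m": 0.0, "outflux_adv_ldl": 0.0,
              "oxidized_ldl": 0.0, "clipped_mass": 0.0,
              "initial_ldl": float(state["ldl"].sum()) * mesh.cell_volume}
    times = [0.0]
    states = [state.copy()]
    checkpoints = list(np.arange(opts.checkpoint_interval, horizon,
                                 opts.checkpoint_interval)) + [horizon]
    next_cp = 0
    t, dt, n_steps = 0.0, min(opts.dt_init, horizon), 0
    while t < horizon * (1.0 - 1e-12):
        target = checkpoints[next_cp]
        dt_step = min(dt, target - t)
        # unsaturated monocyte flux; the wall-side (1 - c_m/c_m,th)
        # saturation is applied implicitly inside the transport solve
        j_m0 = endo.monocyte_influx(m_factor, state["ldlox"][:, 0], lp) * mask
        state, audit = advance_species(
            state, transport, {"ldl": j_ldl}, rp, dt_step, opts,
            saturated_influx={"m": (j_m0, rp.c_m_th)},
        )
        for key_src, key_dst in (("influx_ldl", "influx_ldl"),
                                 ("influx_m", "influx_m"),
                                 ("outflux_adv_ldl", "outflux_adv_ldl"),
                                 ("oxidized_ldl", "oxidized_ldl"),
                                 ("clipped_mass", "clipped_mass")):
            ledger[key_dst] += audit.get(key_src, 0.0)
        t += dt_step
        n_steps += 1
        peaks = state.data.max(axis=(0, 1))
        if np.any(peaks > guard):
            bad = [SPECIES[k] for k in np.nonzero(peaks > guard)[0]]
            raise SolverError(
                f"blow-up detected at t = {t / YEAR:.2f} years: "
                f"{', '.join(bad)} exceeded 1e3 x reference "
                f"(peaks {peaks[peaks > guard]})"
            )
        if t >= target * (1.0 - 1e-12):
            times.append(t)
            states.append(state.copy())
            next_cp += 1
        dt = min(dt * opts.dt_growth, opts.dt_max)
    ledger["final_ldl"] = float(state["ldl"].sum()) * mesh.cell_volume
    return InflammationResult(mesh, stimulus, pore, perm, darcy,
                              times, states, ledger, n_steps, horizon)
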