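"""Analytic endothelial wall-shear-stress fixtures.

The inflammation and growth stages of the simulator are driven entirely by the
wall shear stress (WSS) history on the endothelium over one cardiac cycle.
Rather than running a transient CFD computation, this module generates
analytic, exactly periodic WSS time-series fields on a 1D row of endothelial
stations, with a configurable "atheroprone patch" of low time-averaged WSS
(TAWSS) and/or high oscillatory shear index (OSI). Fields can also be imported
from (and exported to) a simple CSV dialect so that externally computed WSS
histories can drive the same pipeline.

The waveform at every station is a biased sinusoid

    tau(t) = m * (1 + gamma * sin(2*pi*t/T)),

whose bias ``m`` and relative amplitude ``gamma`` are solved in closed form so
that the station hits a prescribed (TAWSS, OSI) pair: for ``gamma > 1`` the
traction reverses during part of the cycle and

    mean(|tau|) = |m| * g(gamma),   g = (2/pi) * (theta0 + gamma*cos(theta0)),

with ``theta0 = arcsin(1/gamma)``, while the cycle-mean of the signed traction
stays ``m``, so OSI = (1 - 1/g)/2 follows directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import DomainError, FormatError, InvalidParameterError

__all__ = [
    "BloodProperties",
    "WSSTimeSeriesField",
    "WaveformProfile",
    "AtheropronePatch",
    "poiseuille_wss",
    "synthetic_wss_field",
    "read_wss_table",
    "write_wss_table",
]


@dataclass
class BloodProperties:
    """Bulk blood properties of the pulsatile flow fixture.

    Attributes
    ----------
    rho_b : float
        Blood mass density (kg/m^3).
    mu_b : float
        Blood dynamic viscosity (Pa s).
    period_T : float
        Cardiac cycle duration (s).
    """

    rho_b: float = 1050.0
    mu_b: float = 0.0035
    period_T: float = 0.85

    def __post_init__(self) -> None:
        for name in ("rho_b", "mu_b", "period_T"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"BloodProperties.{name} must be > 0")


@dataclass
class WSSTimeSeriesField:
    """Per-node tangential traction sampled over one cardiac cycle.

    ``tractions`` has shape ``(n_nodes, n_times, 3)`` (Pa); ``times`` spans
    exactly ``[0, period]`` with at least 8 strictly increasing samples.
    """

    node_positions: np.ndarray
    times: np.ndarray
    tractions: np.ndarray
    period: float = 0.85

    def __post_init__(self) -> None:
        self.node_positions = np.asarray(self.node_positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.tractions = np.asarray(self.tractions, dtype=float)
        n, nt = self.node_positions.size, self.times.size
        if self.tractions.shape != (n, nt, 3):
            raise FormatError(
                f"tractions shape {self.tractions.shape} != ({n}, {nt}, 3)"
            )
        if nt < 2:
            raise FormatError("need at least 2 samples per cardiac cycle")
        if np.any(np.diff(self.times) <= 0):
            raise FormatError("times must be strictly increasing")
        if self.times[0] != 0.0 or not np.isclose(self.times[-1], self.period):
            raise FormatError("times must span exactly [0, period]")
        if not np.all(np.isfinite(self.tractions)):
            raise FormatError("tractions must be finite")

    @property
    def n_nodes(self) -> int:
        return self.node_positions.size


@dataclass
class WaveformProfile:
    """Baseline (non-patch) waveform specification.

    ``mean_flow`` (m^3/s) sets the cycle-mean traction through the Poiseuille
    relation at each station's lumen radius; ``pulsatility`` is the relative
    first-harmonic amplitude; a nonzero ``reversal_fraction`` (fraction of the
    cycle spent in reversed flow) overrides the amplitude with the value that
    produces exactly that reversed fraction for a biased sinusoid.
    """

    mean_flow: float = 5.4e-6
    pulsatility: float = 0.6
    reversal_fraction: float = 0.0
    n_samples: int = 64
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.reversal_fraction < 0.5:
            raise InvalidParameterError("reversal_fraction must be in [0, 0.5)")
        if self.n_samples < 8:
            raise InvalidParameterError("n_samples must be >= 8")


@dataclass
class AtheropronePatch:
    """Axial interval where the WSS field is made atheroprone.

    Inside ``[s_start, s_end)`` the waveform is re-solved so that each station
    has TAWSS equal to ``tawss_scale`` (Pa) and OSI equal to ``osi_target``.
    """

    s_start: float = 0.02
    s_end: float = 0.03
    tawss_scale: float = 0.5
    osi_target: float = 0.35

    def __post_init__(self) -> None:
        if self.s_end <= self.s_start:
            raise DomainError("patch interval is empty")
        if not 0 <= self.osi_target <= 0.5:
            raise InvalidParameterError("osi_target must be in [0, 0.5]")
        if self.tawss_scale < 0:
            raise InvalidParameterError("tawss_scale must be >= 0")


def poiseuille_wss(flow_rate: float, radius: float, mu_b: float) -> float:
    """Steady Poiseuille wall shear stress ``4*mu*Q/(pi*R^3)`` (Pa).

    The sign of the axial traction follows the sign of ``flow_rate``.
    """
    if radius <= 0:
        raise InvalidParameterError("radius must be > 0")
    if mu_b <= 0:
        raise InvalidParameterError("viscosity must be > 0")
    return 4.0 * mu_b * flow_rate / (np.pi * radius**3)


def _rectified_mean_factor(gamma: float) -> float:
    """g(gamma) = mean(|1 + gamma*sin|) over one cycle."""
    if gamma <= 1.0:
        return 1.0
    theta0 = np.arcsin(1.0 / gamma)
    return (2.0 / np.pi) * (theta0 + gamma * np.cos(theta0))


def _solve_bias_amplitude(tawss: float, osi: float) -> tuple[float, float]:
    """Bias ``m`` and absolute amplitude ``a`` hitting (TAWSS, OSI) exactly.

    OSI = (1 - 1/g)/2 fixes g = 1/(1-2*OSI); g(gamma) is then inverted for
    gamma. OSI = 0.5 degenerates to a zero-mean sinusoid with mean magnitude
    2a/pi.
    """
    if osi >= 0.5 - 1e-12:
        return 0.0, tawss * np.pi / 2.0
    if osi <= 0.0:
        return tawss, 0.0
    g_target = 1.0 / (1.0 - 2.0 * osi)
    gamma = brentq(lambda g: _rectified_mean_factor(g) - g_target, 1.0, 1e9)
    m = tawss / g_target
    return m, gamma * m


def synthetic_wss_field(
    profile: WaveformProfile,
    patch: AtheropronePatch | None,
    mesh: np.ndarray,
    lumen_radius: float | np.ndarray = 2e-3,
    blood: BloodProperties | None = None,
    seed: int = 0,
) -> WSSTimeSeriesField:
    """Generate a deterministic per-station WSS time-series field.

    Parameters
    ----------
    profile
        Baseline waveform outside the patch.
    patch
        Optional atheroprone interval; must lie within the axial extent.
    mesh
        Axial station coordinates (m), strictly increasing.
    lumen_radius
        Lumen radius (m), scalar or per station.
    blood
        Blood properties (defaults to carotid values).
    seed
        Seed for the optional per-node magnitude jitter (``profile.jitter``);
        the field is bit-reproducible for a fixed seed and configuration.
    """
    blood = blood or BloodProperties()
    s = np.asarray(mesh, dtype=float)
    radius = np.broadcast_to(np.asarray(lumen_radius, dtype=float), s.shape)
    if patch is not None:
        if patch.s_start < s.min() - 1e-12 or patch.s_end > s.max() + 1e-12:
            raise DomainError(
                f"patch [{patch.s_start}, {patch.s_end}] outside axial extent "
                f"[{s.min()}, {s.max()}]"
            )

    times = np.linspace(0.0, blood.period_T, profile.n_samples)
    phase = np.sin(2.0 * np.pi * times / blood.period_T)

    # baseline: Poiseuille mean traction, pulsatile modulation
    tau_mean = np.array(
        [poiseuille_wss(profile.mean_flow, r, blood.mu_b) for r in radius]
    )
    if profile.reversal_fraction > 0:
        amp_rel = 1.0 / np.cos(np.pi * profile.reversal_fraction)
    else:
        amp_rel = profile.pulsatility
    tau_x = tau_mean[:, None] * (1.0 + amp_rel * phase[None, :])

    if patch is not None:
        inside = (s >= patch.s_start) & (s < patch.s_end)
        m, a = _solve_bias_amplitude(patch.tawss_scale, patch.osi_target)
        tau_x[inside, :] = m + a * phase[None, :]

    if profile.jitter > 0:
        rng = np.random.default_rng(seed)
        factor = 1.0 + profile.jitter * rng.standard_normal(s.size)
        tau_x *= np.abs(factor)[:, None]

    tractions = np.zeros((s.size, times.size, 3))
    tractions[:, :, 0] = tau_x
    return WSSTimeSeriesField(s, times, tractions, period=blood.period_T)


_CSV_COLUMNS = ["node_id", "s_axial_m", "t_s", "tau_x_Pa", "tau_y_Pa", "tau_z_Pa"]


def write_wss_table(fld: WSSTimeSeriesField, path) -> None:
    """Write a field to the tabular CSV dialect (bit-exact round trip)."""
    n, nt = fld.n_nodes, fld.times.size
    frame = pd.DataFrame(
        {
            "node_id": np.repeat(np.arange(n), nt),
            "s_axial_m": np.repeat(fld.node_positions, nt),
            "t_s": np.tile(fld.times, n),
            "tau_x_Pa": fld.tractions[:, :, 0].ravel(),
            "tau_y_Pa": fld.tractions[:, :, 1].ravel(),
            "tau_z_Pa": fld.tractions[:, :, 2].ravel(),
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def read_wss_table(path) -> WSSTimeSeriesField:
    """Read a WSS field from the tabular CSV dialect.

    Raises
    ------
    FormatError
        On missing columns or non-monotone per-node time samples, naming the
        offending field.
    """
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read WSS table: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"WSS table missing columns: {', '.join(missing)}")

    node_ids = frame["node_id"].to_numpy()
    unique_ids = pd.unique(node_ids)
    n = unique_ids.size
    nt = len(frame) // n
    if len(frame) != n * nt:
        raise FormatError("node_id: ragged sample counts across nodes")

    positions = np.empty(n)
    tractions = np.empty((n, nt, 3))
    times = None
    for k, nid in enumerate(unique_ids):
        block = frame[node_ids == nid]
        t = block["t_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise FormatError(f"t_s: non-monotone times for node {nid}")
        if times is None:
            times = t
        elif not np.array_equal(times, t):
            raise FormatError("t_s: inconsistent time grid across nodes")
        positions[k] = block["s_axial_m"].iloc[0]
        for j, comp in enumerate(["tau_x_Pa", "tau_y_Pa", "tau_z_Pa"]):
            tractions[k, :, j] = block[comp].to_numpy()
    return WSSTimeSeriesField(positions, times, tractions, period=float(times[-1]))
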