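"""Haemodynamic stimuli on the endothelium.

From a per-node WSS time series over one cardiac cycle this module computes
the two classical stimuli,

    TAWSS = (1/T) * int_0^T |tau(t)| dt
    OSI   = 0.5 * (1 - |(1/T) int_0^T tau(t) dt| / TAWSS),

and maps either (or a combination of both) onto the endothelial cell shape
index SI — a roundness descriptor in (0, 1); rounder cells have wider
intercellular junctions and a leakier endothelium. Three fitted correlations
are available:

    tawss mode:    SI = k1*exp(k2*TAWSS) + k3*exp(k4*TAWSS)
    osi mode:      SI = k5*OSI^2 + k6*OSI + k7
    combined mode: SI = k8*exp(k9*OSI) + k10*exp(k11*TAWSS^2)

Atheroprone regions are flagged by the carotid thresholds TAWSS < 2 Pa and/or
OSI > 0.1910 (strict inequalities). The module also provides the
stimulus-dependent factor entering the endothelial monocyte recruitment flux.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .haemo_fixtures import WSSTimeSeriesField

__all__ = [
    "CorrelationParams",
    "StimulusField",
    "wss_magnitude",
    "compute_tawss",
    "compute_osi",
    "shape_index",
    "atheroprone_mask",
    "monocyte_flux_factor",
    "compute_stimulus",
    "MODES",
]

MODES = ("tawss", "osi", "combined")


@dataclass
class CorrelationParams:
    """Fitted constants of the SI correlations and the atheroprone thresholds.

    ``k1..k4`` belong to the TAWSS correlation, ``k5..k7`` to the OSI
    correlation and ``k8..k11`` to the combined one. ``tawss0`` is the
    reference TAWSS (Pa) of the monocyte-recruitment factor.
    """

    k1: float = 0.6296
    k2: float = -0.8709
    k3: float = 0.2145
    k4: float = 0.03938
    k5: float = 1.53
    k6: float = 0.4688
    k7: float = 0.1631
    k8: float = 0.0264
    k9: float = 5.647
    k10: float = 0.5513
    k11: float = -0.1815
    tawss_threshold: float = 2.0
    osi_threshold: float = 0.1910
    tawss0: float = 1.0


@dataclass
class StimulusField:
    """Per-endothelial-node stimulus summary for one correlation mode."""

    node_positions: np.ndarray
    tawss: np.ndarray
    osi: np.ndarray
    si: np.ndarray
    atheroprone: np.ndarray
    mode: str = "combined"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s_axial_m": self.node_positions,
                "tawss_Pa": self.tawss,
                "osi": self.osi,
                "si": self.si,
                "atheroprone": self.atheroprone.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def wss_magnitude(traction: np.ndarray) -> np.ndarray:
    """Euclidean norm of the tangential stress vector (last axis)."""
    traction = np.asarray(traction, dtype=float)
    if not np.all(np.isfinite(traction)):
        raise InvalidParameterError("traction components must be finite")
    return np.linalg.norm(traction, axis=-1)

def compute_tawss(times: np.ndarray, tractions: np.ndarray) -> np.ndarray:
    """Time-averaged WSS magnitude by composite trapezoid over one cycle.

    ``tractions`` may be a single node ``(nt, 3)`` or stacked ``(n, nt, 3)``.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise InvalidParameterError("need at least 2 samples to average")
    period = times[-1] - times[0]
    mag = wss_magnitude(tractions)
    return np.trapezoid(mag, times, axis=-1) / period


def compute_osi(times: np.ndarray, tractions: np.ndarray) -> np.ndarray:
    """Oscillatory shear index, clipped to [0, 0.5] against round-off.

    The numerator is the magnitude of the *vector* time-average of the
    traction. Nodes with zero TAWSS are assigned OSI = 0 (with a warning):
    a node that never experiences shear has no oscillation to index.
    """
    times = np.asarray(times, dtype=float)
    tractions = np.asarray(tractions, dtype=float)
    if times.size < 2:
        raise InvalidParameterError("need at least 2 samples to average")
    period = times[-1] - times[0]
    tawss = compute_tawss(times, tractions)
    mean_vec = np.trapezoid(tractions, times, axis=-2) / period
    mean_mag = np.linalg.norm(mean_vec, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        osi = 0.5 * (1.0 - mean_mag / tawss)
    zero = tawss == 0.0
    if np.any(zero):
        warnings.warn("OSI undefined at TAWSS = 0; using OSI = 0", stacklevel=2)
        osi = np.where(zero, 0.0, osi)
    return np.clip(osi, 0.0, 0.5)


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise InvalidParameterError(f"unknown stimulus mode {mode!r}; use one of {MODES}")


def shape_index(
    mode: str,
    tawss: np.ndarray | float,
    osi: np.ndarray | float = 0.0,
    params: CorrelationParams | None = None,
):
    """Endothelial shape index from the fitted correlation for ``mode``."""
    _check_mode(mode)
    p = params or CorrelationParams()
    tawss = np.asarray(tawss, dtype=float)
    osi = np.asarray(osi, dtype=float)
    if np.any(tawss < 0):
        raise InvalidParameterError("tawss must be >= 0")
    if np.any((osi < 0) | (osi > 0.5)):
        raise InvalidParameterError("osi must be in [0, 0.5]")
    if mode == "tawss":
        si = p.k1 * np.exp(p.k2 * tawss) + p.k3 * np.exp(p.k4 * tawss)
    elif mode == "osi":
        si = p.k5 * osi**2 + p.k6 * osi + p.k7
    else:
        si = p.k8 * np.exp(p.k9 * osi) + p.k10 * np.exp(p.k11 * tawss**2)
    return si[()] if si.ndim == 0 else si


def atheroprone_mask(
    tawss: np.ndarray | float,
    osi: np.ndarray | float,
    mode: str = "combined",
    params: CorrelationParams | None = None,
) -> np.ndarray:
    """Boolean atheroprone flag per node (strict threshold comparisons)."""
    _check_mode(mode)
    p = params or CorrelationParams()
    tawss = np.asarray(tawss, dtype=float)
    osi = np.asarray(osi, dtype=float)
    low_tawss = tawss < p.tawss_threshold
    high_osi = osi > p.osi_threshold
    if mode == "tawss":
        return low_tawss
    if mode == "osi":
        return high_osi
    return low_tawss | high_osi


def monocyte_flux_factor(
    mode: str,
    tawss: np.ndarray | float,
    osi: np.ndarray | float = 0.0,
    params: CorrelationParams | None = None,
    tawss_factor_literal: bool = False,
):
    """Dimensionless stimulus factor of the monocyte recruitment flux.

    The factor is ~1 in strongly atheroprone conditions and decays toward ~1/3
    as the stimulus becomes protective. For ``mode='tawss'`` the default is
    the decreasing reciprocal 1/(1 + TAWSS/TAWSS0); ``tawss_factor_literal``
    switches to the increasing printed product (1 + TAWSS/TAWSS0) for
    side-by-side comparison.
    """
    _check_mode(mode)
    p = params or CorrelationParams()
    tawss = np.asarray(tawss, dtype=float)
    osi = np.asarray(osi, dtype=float)
    if mode == "tawss":
        lin = 1.0 + tawss / p.tawss0
        out = lin if tawss_factor_literal else 1.0 / lin
    elif mode == "osi":
        out = 8.503 * osi**2 - 3.741 * osi + 0.7449
    else:
        out = 0.8588 * np.exp(-0.6301 * tawss) + 0.1295 * np.exp(3.963 * osi)
    return out[()] if out.ndim == 0 else out


def compute_stimulus(
    field: WSSTimeSeriesField,
    mode: str = "combined",
    params: CorrelationParams | None = None,
) -> StimulusField:
    """Reduce a WSS time-series field to per-node TAWSS/OSI/SI/mask."""
    _check_mode(mode)
    p = params or CorrelationParams()
    tawss = compute_tawss(field.times, field.tractions)
    osi = compute_osi(field.times, field.tractions)
    si = shape_index(mode, tawss, osi, p)
    mask = atheroprone_mask(tawss, osi, mode, p)
    return StimulusField(field.node_positions.copy(), tawss, osi, si, mask, mode)


def read_stimulus_csv(path, mode: str = "combined") -> StimulusField:
    """Load a per-node stimulus table written by :meth:`StimulusField.to_csv`."""
    frame = pd.read_csv(path)
    return StimulusField(
        frame["s_axial_m"].to_numpy(),
        frame["tawss_Pa"].to_numpy(),
        frame["osi"].to_numpy(),
        frame["si"].to_numpy(),
        frame["atheroprone"].to_numpy().astype(bool),
        mode,
    )
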