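"""Observables: lifetime-based NPQ, pigment totals, and quenching capacity.

The measured quantity NPQ_tau = (tau(0) - tau(t)) / tau(t) is linear in the
concentrations of the active quenchers: in reduced units it is simply the
change, relative to the dark-acclimated start, of the summed quencher
complexes plus ``r_qZ`` times the change in free zeaxanthin,

    NPQ_tau(t) = d[QV] + d[QA] + d[QZ] + r_qZ * d[Z].

The per-channel decomposition (qE via each complex, qZ via the free-Z pool)
therefore sums to the total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .model import KineticParameters, SystemState, Trajectory, rate_equations
from .protocols import LightLevel, LightProtocol

__all__ = [
    "NPQTrace",
    "HPLCSeries",
    "npq_trace",
    "lifetime_from_state",
    "quenching_capacity",
    "total_xanthophylls",
]

PIGMENTS = ("V", "A", "Z")


@dataclass
class NPQTrace:
    """A (possibly noisy) NPQ_tau time series.

    ``channels``, when present, holds the decomposition into the four
    quenching contributions ``qE_V``, ``qE_A``, ``qE_Z`` and ``qZ`` which
    sum to ``npq``.
    """

    times: np.ndarray
    npq: np.ndarray
    se: Optional[np.ndarray] = None
    channels: Optional[Dict[str, np.ndarray]] = None
    label: str = ""
    replicate: int = 0
    protocol: Optional[LightProtocol] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.npq = np.asarray(self.npq, dtype=float)
        if self.times.shape != self.npq.shape:
            raise ValueError("times and npq must have the same shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.times.shape:
                raise ValueError("se must match times in shape")
        if self.channels is not None:
            total = np.zeros_like(self.npq)
            for k, v in self.channels.items():
                self.channels[k] = np.asarray(v, dtype=float)
                total = total + self.channels[k]
            if not np.allclose(total, self.npq, atol=1e-10, rtol=0.0):
                raise ValueError("channel decomposition does not sum to total NPQ")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class HPLCSeries:
    """Pigment-concentration changes relative to t = 0 (mmol / mol Chl a).

    ``delta`` maps pigment name to the time series of
    Delta[X]_tot = Delta([X] + [PX] + [QX]).  ``absolute``, when present,
    additionally stores absolute concentrations (including any inert,
    non-cycling pool).
    """

    times: np.ndarray
    delta: Dict[str, np.ndarray]
    se: Optional[Dict[str, np.ndarray]] = None
    label: str = ""
    protocol: Optional[LightProtocol] = None
    absolute: Optional[Dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for x in PIGMENTS:
            if x not in self.delta:
                raise ValueError(f"missing pigment {x!r} in delta")
            self.delta[x] = np.asarray(self.delta[x], dtype=float)
            if self.delta[x].shape != self.times.shape:
                raise ValueError(f"delta[{x!r}] must match times in shape")


def _require_reference_start(traj: Trajectory, params: KineticParameters) -> None:
    """The NPQ baseline is defined only for dark-acclimated starts."""
    y0 = traj.state_at(0)
    dydt = rate_equations(y0, params, LightLevel.DARK)
    scale = max(1.0, params.X_tot)
    if np.abs(dydt).max() > 1e-6 * scale:
        raise ValueError(
            "trajectory does not start at a dark-acclimated reference state; "
            "NPQ baseline is undefined"
        )


def npq_trace(traj: Trajectory, params: KineticParameters,
              check_reference: bool = True, label: str = "") -> NPQTrace:
    """NPQ_tau time series and channel decomposition for a trajectory.

    The trajectory must start at the dark-acclimated reference state
    (checked by evaluating the dark rate equations at the first point).
    """
    if check_reference:
        _require_reference_start(traj, params)
    dQV = traj.species("QV") - traj.species("QV")[0]
    dQA = traj.species("QA") - traj.species("QA")[0]
    dQZ = traj.species("QZ") - traj.species("QZ")[0]
    dZ = traj.species("Z") - traj.species("Z")[0]
    channels = {
        "qE_V": dQV,
        "qE_A": dQA,
        "qE_Z": dQZ,
        "qZ": params.r_qZ * dZ,
    }
    total = dQV + dQA + dQZ + params.r_qZ * dZ
    return NPQTrace(
        times=traj.times.copy(),
        npq=total,
        channels=channels,
        label=label or str(traj.provenance.get("protocol", "")),
    )


def lifetime_from_state(
    state: SystemState,
    params: KineticParameters,
    tau_F0: float,
    k_qE_abs: float,
    z_ref: float = 0.0,
) -> float:
    """Absolute chlorophyll fluorescence lifetime implied by a state.

    The decay rate is ``1/tau_F0 + k_qE * ([QV]+[QA]+[QZ]) + k_qZ * [Z]``
    with ``k_qZ = r_qZ * k_qE``.  Reduced concentrations are converted to
    absolute ones using the reference-state lifetime (the lifetime when all
    QX are zero and free zeaxanthin equals ``z_ref`` in reduced units), so
    that NPQ_tau computed from lifetimes is independent of the arbitrary
    choice of ``tau_F0`` and ``k_qE_abs`` and agrees with :func:`npq_trace`.

    Absolute lifetimes are illustrative: the data constrain only the reduced
    combination, never ``tau_F0`` or ``k_qE_abs`` individually.
    """
    if tau_F0 <= 0:
        raise ValueError(f"tau_F0 must be positive, got {tau_F0!r}")
    if k_qE_abs <= 0:
        raise ValueError(f"k_qE_abs must be positive, got {k_qE_abs!r}")
    tau_ref = tau_F0 * (1.0 - params.r_qZ * z_ref)
    if tau_ref <= 0:
        raise ValueError("reference quenching too strong for the given tau_F0")
    # Reduced -> absolute: [B] = [~B] / (tau_ref * k_qE_abs)
    conv = 1.0 / (tau_ref * k_qE_abs)
    q_abs = (state.QV + state.QA + state.QZ) * conv
    z_abs = state.Z * conv
    rate = 1.0 / tau_F0 + k_qE_abs * q_abs + params.r_qZ * k_qE_abs * z_abs
    return 1.0 / rate


def quenching_capacity(K_light: float) -> float:
    """Maximum fraction of bound xanthophyll in the quencher state, K/(1+K)."""
    if K_light < 0:
        raise ValueError(f"equilibrium constant must be non-negative, got {K_light!r}")
    return K_light / (1.0 + K_light)


def total_xanthophylls(traj: Trajectory, params: KineticParameters,
                       label: str = "") -> HPLCSeries:
    """Per-pigment total-concentration changes in mmol / mol Chl a.

    For each X, Delta[X]_tot = Delta([X] + [PX] + [QX]) scaled by the
    reduced-to-HPLC conversion factor ``c_hplc``.  The three changes sum to
    zero at all times because the labile pool is closed.
    """
    delta = {}
    for x in PIGMENTS:
        tot = traj.species(x) + traj.species("P" + x) + traj.species("Q" + x)
        delta[x] = params.c_hplc * (tot - tot[0])
    return HPLCSeries(
        times=traj.times.copy(),
        delta=delta,
        label=label or str(traj.provenance.get("protocol", "")),
    )
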