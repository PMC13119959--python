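"""Explicit-Euler time stepping and batch simulation of the coupled system.

The coupled microbial/electrochemical ODE system is integrated with an
explicit Euler scheme (default Δt = 0.01 h, the accurate end of the
0.01–0.05 h range the model is designed for).  A batch run advances in
discharge mode — the electrode oxidizes whatever reduced mediator is
present — until the time horizon, an optional total-phenazine toxicity
threshold, or an optional substrate floor is reached.

State variables are clamped at zero after each step; clamp events are
counted and their largest magnitude recorded so that clamping can be
verified not to mask dynamics.  Cumulative charge (A·h·m⁻²) is accumulated
with the trapezoidal rule on the current density at step boundaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Any

import numpy as np
import pandas as pd

from .electrochem import recharge_flux
from .params import A_M2_TO_MA_CM2, AnolyteState, ElectroParams, MicrobialParams, TerminationSpec

__all__ = [
    "Mode",
    "TerminationReason",
    "SimulationError",
    "Trajectory",
    "SummaryMetrics",
    "euler_step",
    "simulate_batch",
    "summary_metrics",
]

logger = logging.getLogger(__name__)

#: Upper end of the time-step range the explicit Euler scheme is meant for (h).
DT_MAX_RECOMMENDED = 0.05


class Mode(str, Enum):
    """Operating mode of one Euler step."""

    DISCHARGE = "discharge"
    RECHARGE = "recharge"
    OPEN_CIRCUIT = "open_circuit"


class TerminationReason(str, Enum):
    MAX_TIME = "max_time"
    TOXICITY = "toxicity"
    SUBSTRATE_FLOOR = "substrate_floor"
    VOLTAGE_CUTOFF = "voltage_cutoff"
    TIME_LIMIT = "time_limit"


class SimulationError(RuntimeError):
    """Raised when the integration produces a non-finite state."""


@dataclass
class Trajectory:
    """Time series of anolyte states and derived electrical observables.

    Column arrays are aligned on step boundaries; ``cumulative_charge`` is
    the running trapezoidal integral of ``j`` in A·h·m⁻².
    """

    t: np.ndarray
    X: np.ndarray
    S: np.ndarray
    P_red: np.ndarray
    P_ox: np.ndarray
    v_elec: np.ndarray
    j: np.ndarray
    E_an: np.ndarray
    E_oc: np.ndarray
    V_cell: np.ndarray
    cumulative_charge: np.ndarray
    termination_reason: TerminationReason
    n_clamp_events: int = 0
    max_clamp_magnitude: float = 0.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.t) == 0:
            raise ValueError("trajectory must contain at least one state")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def P_tot(self) -> np.ndarray:
        return self.P_red + self.P_ox

    @property
    def duration(self) -> float:
        """Realized run duration in hours."""
        return float(self.t[-1] - self.t[0])

    def final_state(self) -> AnolyteState:
        return AnolyteState(
            t=float(self.t[-1]),
            X=float(self.X[-1]),
            S=float(self.S[-1]),
            P_red=float(self.P_red[-1]),
            P_ox=float(self.P_ox[-1]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with current density in both unit conventions."""
        return pd.DataFrame(
            {
                "t": self.t,
                "X": self.X,
                "S": self.S,
                "P_red": self.P_red,
                "P_ox": self.P_ox,
                "P_tot": self.P_tot,
                "v_elec": self.v_elec,
                "j_A_m2": self.j,
                "j_mA_cm2": self.j * A_M2_TO_MA_CM2,
                "E_an": self.E_an,
                "E_oc": self.E_oc,
                "V_cell": self.V_cell,
                "cumulative_charge": self.cumulative_charge,
            }
        )

    def write_csv(self, path, metadata: dict[str, Any] | None = None) -> None:
        """Write the trajectory CSV plus a JSON metadata sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        meta = {
            "termination_reason": self.termination_reason.value,
            "n_clamp_events": self.n_clamp_events,
            "max_clamp_magnitude": self.max_clamp_magnitude,
            **self.metadata,
            **(metadata or {}),
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2, default=str))


@dataclass(frozen=True)
class SummaryMetrics:
    """Batch-run performance summary.

    ``avg_j`` time-averaged current density over the realized horizon
    (A·m⁻²), ``peak_j`` maximum instantaneous current density (A·m⁻²),
    ``cumulative_charge`` total charge passed (A·h·m⁻²), ``duration``
    realized run length (h).
    """

    avg_j: float
    peak_j: float
    cumulative_charge: float
    duration: float


def _check_dt(dt: float) -> None:
    if dt <= 0:
        raise ValueError(f"dt must be strictly positive, got {dt}")
    if dt > DT_MAX_RECOMMENDED:
        logger.warning(
            "dt = %g h exceeds the recommended explicit-Euler range (0, %g]",
            dt, DT_MAX_RECOMMENDED,
        )


def euler_step(
    state: AnolyteState,
    dt: float,
    mp: MicrobialParams,
    ep: ElectroParams,
    mode: Mode | str = Mode.DISCHARGE,
    j_charge: float = 0.0,
) -> AnolyteState:
    """Advance the anolyte state by one explicit Euler step.

    In ``discharge`` mode the electrode flux is k_elec·P_red and all four
    state equations advance.  In ``open_circuit`` mode the electrode flux
    is zero but the microbial dynamics still run.  In ``recharge`` mode a
    constant charging current ``j_charge`` is imposed in the opposite
    direction while biomass and substrate are held fixed over the short
    recharge interval; only the phenazine pools evolve (reduction of P_ox
    plus degradation), with the imposed flux truncated in any step that
    would drive P_ox negative.  All outputs are clamped at zero.
    """
    _check_dt(dt)
    mode = Mode(mode)

    X, S, P_red, P_ox = state.X, state.S, state.P_red, state.P_ox

    if mode is Mode.RECHARGE:
        v = recharge_flux(j_charge, ep)  # <= 0
        supply = P_ox * (1.0 - dt * mp.k_deg)
        if -v * dt > supply:  # imposed current would empty the oxidized pool
            v = -supply / dt
        new_P_red = P_red + dt * (-v - mp.k_deg * P_red)
        new_P_ox = P_ox + dt * (v - mp.k_deg * P_ox)
        new_X, new_S = X, S
    else:
        v = ep.k_elec * P_red if mode is Mode.DISCHARGE else 0.0
        from .kinetics import microbial_derivatives

        dX, dS, dP_red, dP_ox = microbial_derivatives(state, v, mp)
        new_X = X + dt * dX
        new_S = S + dt * dS
        new_P_red = P_red + dt * dP_red
        new_P_ox = P_ox + dt * dP_ox

    return AnolyteState(
        t=state.t + dt,
        X=max(new_X, 0.0),
        S=max(new_S, 0.0),
        P_red=max(new_P_red, 0.0),
        P_ox=max(new_P_ox, 0.0),
    )


def simulate_batch(
    init: AnolyteState,
    mp: MicrobialParams,
    ep: ElectroParams,
    term: TerminationSpec | None = None,
    dt: float = 0.01,
) -> Trajectory:
    """Integrate a batch run in discharge mode until a termination event.

    Returns the full :class:`Trajectory` on step boundaries.  Termination
    reasons: ``max_time`` (horizon reached), ``toxicity`` (total phenazine
    exceeded ``term.P_tox_stop``), ``substrate_floor`` (substrate fell
    below ``term.S_floor``).  A non-finite state aborts with
    :class:`SimulationError`.
    """
    _check_dt(dt)
    if term is None:
        term = TerminationSpec()

    n_max = max(1, int(math.ceil(term.t_max / dt - 1e-9)))

    # Hoisted parameter locals: the inner loop is pure float arithmetic.
    qS_max, K_S, Y_XS = mp.qS_max, mp.K_S, mp.Y_XS
    alpha_P, beta_P, k_deg = mp.alpha_P, mp.beta_P, mp.k_deg
    K_inh, n_inh = mp.K_inh, mp.n_inh
    k_elec, eps = ep.k_elec, ep.conc_floor
    c_j = ep.flux_to_j
    E0, slope, E_cath, R_ohm = ep.E0_an, ep.nernst_slope, ep.E_cath, ep.R_ohm
    log = math.log

    size = n_max + 1
    arr = {k: np.empty(size) for k in
           ("t", "X", "S", "P_red", "P_ox", "v_elec", "j", "E_an", "E_oc", "V_cell", "q")}
    a_t, a_X, a_S = arr["t"], arr["X"], arr["S"]
    a_Pr, a_Po, a_v, a_j = arr["P_red"], arr["P_ox"], arr["v_elec"], arr["j"]
    a_Ean, a_Eoc, a_V, a_q = arr["E_an"], arr["E_oc"], arr["V_cell"], arr["q"]

    t0 = init.t
    X, S, P_red, P_ox = init.X, init.S, init.P_red, init.P_ox
    n_clamp = 0
    max_clamp = 0.0
    q = 0.0
    j_prev = 0.0
    reason = TerminationReason.MAX_TIME
    n_steps = 0

    for i in range(size):
        # observables at the current state (discharge convention)
        v = k_elec * P_red
        j = c_j * v
        if P_ox < eps and P_red < eps:
            E_an = E0
        else:
            E_an = E0 + slope * log(max(P_ox, eps) / max(P_red, eps))
        E_oc = E_cath - E_an
        if i > 0:
            q += 0.5 * (j_prev + j) * dt
        j_prev = j
        a_t[i] = t0 + i * dt
        a_X[i] = X
        a_S[i] = S
        a_Pr[i] = P_red
        a_Po[i] = P_ox
        a_v[i] = v
        a_j[i] = j
        a_Ean[i] = E_an
        a_Eoc[i] = E_oc
        a_V[i] = E_oc - j * R_ohm
        a_q[i] = q
        n_steps = i

        if term.P_tox_stop is not None and P_red + P_ox > term.P_tox_stop:
            reason = TerminationReason.TOXICITY
            break
        if term.S_floor is not None and S < term.S_floor:
            reason = TerminationReason.SUBSTRATE_FLOOR
            break
        if i == n_max:
            break

        # explicit Euler update from the current state
        qS = qS_max * S / (K_S + S)
        mu = Y_XS * qS / (1.0 + ((P_red + P_ox) / K_inh) ** n_inh)
        r_prod = (alpha_P * mu + beta_P) * X
        X_n = X + dt * mu * X
        S_n = S - dt * qS * X
        Pr_n = P_red + dt * (r_prod - v - k_deg * P_red)
        Po_n = P_ox + dt * (v - k_deg * P_ox)

        for val in (X_n, S_n, Pr_n, Po_n):
            if val < 0.0:
                n_clamp += 1
                if -val > max_clamp:
                    max_clamp = -val
        X = X_n if X_n > 0.0 else 0.0
        S = S_n if S_n > 0.0 else 0.0
        P_red = Pr_n if Pr_n > 0.0 else 0.0
        P_ox = Po_n if Po_n > 0.0 else 0.0

        if not (math.isfinite(X) and math.isfinite(S)
                and math.isfinite(P_red) and math.isfinite(P_ox)):
            raise SimulationError(
                f"non-finite state at t = {t0 + (i + 1) * dt:.4f} h: "
                f"X={X}, S={S}, P_red={P_red}, P_ox={P_ox}"
            )

    end = n_steps + 1
    if n_clamp:
        logger.debug("clamped %d negative excursions (max %.3e)", n_clamp, max_clamp)

    return Trajectory(
        t=arr["t"][:end],
        X=arr["X"][:end],
        S=arr["S"][:end],
        P_red=arr["P_red"][:end],
        P_ox=arr["P_ox"][:end],
        v_elec=arr["v_elec"][:end],
        j=arr["j"][:end],
        E_an=arr["E_an"][:end],
        E_oc=arr["E_oc"][:end],
        V_cell=arr["V_cell"][:end],
        cumulative_charge=arr["q"][:end],
        termination_reason=reason,
        n_clamp_events=n_clamp,
        max_clamp_magnitude=max_clamp,
        metadata={"dt": dt},
    )


def summary_metrics(traj: Trajectory) -> SummaryMetrics:
    """Performance summary of a trajectory over its realized horizon.

    The time-averaged current density is ∫j dt divided by the run duration
    (trapezoidal integration on step boundaries); for a single-point
    trajectory all integral metrics are zero.
    """
    if traj.duration <= 0:
        return SummaryMetrics(avg_j=0.0, peak_j=float(traj.j.max()),
                              cumulative_charge=0.0, duration=0.0)
    total = float(traj.cumulative_charge[-1])
    return SummaryMetrics(
        avg_j=total / traj.duration,
        peak_j=float(traj.j.max()),
        cumulative_charge=total,
        duration=traj.duration,
    )
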