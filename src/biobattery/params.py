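"""Parameter containers and the anolyte state vector.

All quantities are expressed per unit anolyte volume.  Concentrations are
mmol·L⁻¹ except biomass, which follows microbial-kinetics convention and is
reported as grams of cell dry weight per litre (gDW·L⁻¹).  Time is in hours.

The default values correspond to the baseline parameterization of the
bio-battery model: aerobic glucose uptake and yield typical of *E. coli*,
micromolar-scale phenazine toxicity informed by pyocyanin sensitivity of
non-native hosts, and half-cell constants representative of aqueous
phenazine negolytes with porous carbon-felt electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any, Mapping

__all__ = [
    "MicrobialParams",
    "ElectroParams",
    "AnolyteState",
    "TerminationSpec",
    "CyclingParams",
    "A_M2_TO_MA_CM2",
]

#: 1 A·m⁻² expressed in mA·cm⁻².
A_M2_TO_MA_CM2 = 0.1


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _from_mapping(cls, data: Mapping[str, Any]):
    """Build a parameter dataclass from a mapping, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}; "
            f"expected a subset of {sorted(known)}"
        )
    return cls(**data)


@dataclass(frozen=True)
class MicrobialParams:
    """Kinetic and toxicity constants of the microbial module.

    Attributes
    ----------
    qS_max : float
        Maximum specific substrate uptake rate, mmol·gDW⁻¹·h⁻¹.
    K_S : float
        Substrate half-saturation (Monod) constant, mmol·L⁻¹.
    Y_XS : float
        Biomass yield on substrate, gDW·mmol⁻¹ (≈0.5 gDW per g glucose).
    alpha_P : float
        Growth-associated phenazine yield, mmol·gDW⁻¹.
    beta_P : float
        Non-growth-associated phenazine production rate, mmol·gDW⁻¹·h⁻¹.
        Production is primarily growth-associated; the constitutive term
        defaults to zero but is exposed for engineered designs.
    k_deg : float
        First-order phenazine degradation rate constant, h⁻¹.  Applies to
        both redox states.
    K_inh : float
        Total phenazine concentration at half-maximal growth inhibition,
        mmol·L⁻¹ (default 0.01 = 10 µM).
    n_inh : float
        Hill coefficient of growth inhibition (≥ 1).
    """

    qS_max: float = 10.0
    K_S: float = 0.10
    Y_XS: float = 0.09
    alpha_P: float = 0.03
    beta_P: float = 0.0
    k_deg: float = 0.01
    K_inh: float = 0.010
    n_inh: float = 2.0

    def __post_init__(self) -> None:
        for name in ("qS_max", "K_S", "Y_XS", "alpha_P", "k_deg", "K_inh"):
            _require(getattr(self, name) > 0, f"{name} must be strictly positive")
        _require(self.beta_P >= 0, "beta_P must be non-negative")
        _require(self.n_inh >= 1, "n_inh must be >= 1")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "MicrobialParams":
        return _from_mapping(cls, data)

    def replace(self, **kw: Any) -> "MicrobialParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ElectroParams:
    """Half-cell constants of the electrochemical module.

    Attributes
    ----------
    k_elec : float
        Lumped first-order electrode oxidation rate constant, h⁻¹.  Absorbs
        mass-transfer and heterogeneous electron-transfer limitations.
    A : float
        Electrode area per anolyte volume, m²·L⁻¹ (0.1 ≈ 100 m²·m⁻³,
        representative of porous carbon felt).
    n_e : int
        Electrons per phenazine redox event.
    E0_an : float
        Standard (formal) anode potential of the phenazine couple, V vs SHE.
    E_cath : float
        Fixed cathode potential (ideal counter-electrode), V vs SHE.
    R_ohm : float
        Lumped area-specific ohmic resistance, Ω·m².
    T : float
        Temperature, K.
    F : float
        Faraday constant, C·mol⁻¹.
    R_gas : float
        Universal gas constant, J·mol⁻¹·K⁻¹.
    conc_floor : float
        Concentration floor ε (mmol·L⁻¹) applied inside the Nernst log
        ratio so the anode potential stays finite when one redox pool is
        empty.  Must be small enough that the Nernstian potential swing can
        still reach the discharge voltage cut-off (see docs/methods.md).
    """

    k_elec: float = 20.0
    A: float = 0.10
    n_e: int = 2
    E0_an: float = -0.10
    E_cath: float = 0.90
    R_ohm: float = 0.50
    T: float = 298.15
    F: float = 96485.0
    R_gas: float = 8.314
    conc_floor: float = 1e-18

    def __post_init__(self) -> None:
        for name in ("k_elec", "A", "R_ohm", "T", "F", "R_gas", "conc_floor"):
            _require(getattr(self, name) > 0, f"{name} must be strictly positive")
        _require(int(self.n_e) >= 1, "n_e must be an integer >= 1")
        _require(int(self.n_e) == self.n_e, "n_e must be an integer")

    @property
    def flux_to_j(self) -> float:
        """Conversion factor from volumetric flux (mmol·L⁻¹·h⁻¹) to A·m⁻².

        j = n_e·F·v_elec / (A·1000·3600): the molar electron flux per litre
        is divided by 1000 (mmol→mol) and 3600 (h→s) to give A·L⁻¹, then by
        the electrode area per volume to give A·m⁻².
        """
        return self.n_e * self.F / (self.A * 1000.0 * 3600.0)

    @property
    def nernst_slope(self) -> float:
        """RT/(n_e F) in volts."""
        return self.R_gas * self.T / (self.n_e * self.F)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ElectroParams":
        return _from_mapping(cls, data)

    def replace(self, **kw: Any) -> "ElectroParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class AnolyteState:
    """Instantaneous well-mixed anolyte state.

    ``t`` elapsed time (h), ``X`` biomass (gDW·L⁻¹), ``S`` substrate
    (mmol·L⁻¹), ``P_red``/``P_ox`` reduced/oxidized phenazine (mmol·L⁻¹).
    """

    t: float = 0.0
    X: float = 0.05
    S: float = 20.0
    P_red: float = 0.0
    P_ox: float = 0.0

    def __post_init__(self) -> None:
        for name in ("X", "S", "P_red", "P_ox"):
            _require(getattr(self, name) >= 0, f"{name} must be non-negative")

    @property
    def P_tot(self) -> float:
        """Total phenazine, P_tot = P_red + P_ox (mmol·L⁻¹)."""
        return self.P_red + self.P_ox

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "AnolyteState":
        return _from_mapping(cls, data)

    def replace(self, **kw: Any) -> "AnolyteState":
        return replace(self, **kw)


@dataclass(frozen=True)
class TerminationSpec:
    """Stopping conditions for a batch simulation.

    ``t_max`` is always enforced; the toxicity threshold ``P_tox_stop``
    (total phenazine, mmol·L⁻¹) and the substrate floor ``S_floor``
    (mmol·L⁻¹) are optional and disabled when ``None``.
    """

    t_max: float = 200.0
    P_tox_stop: float | None = None
    S_floor: float | None = None

    def __post_init__(self) -> None:
        _require(self.t_max > 0, "t_max must be strictly positive")
        if self.P_tox_stop is not None:
            _require(self.P_tox_stop > 0, "P_tox_stop must be positive when set")
        if self.S_floor is not None:
            _require(self.S_floor > 0, "S_floor must be positive when set")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "TerminationSpec":
        return _from_mapping(cls, data)

    def replace(self, **kw: Any) -> "TerminationSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class CyclingParams:
    """Charge-discharge protocol constants.

    ``V_min`` discharge voltage cut-off (V); ``t_discharge_max`` per-cycle
    discharge time limit (h); ``j_charge`` imposed recharge current density
    (A·m⁻²); ``t_recharge`` recharge duration (h); ``n_cycles`` number of
    discharge/recharge cycles.

    The default recharge interval is short by design: the recharged charge
    (j_charge·t_recharge = 0.005 A·h·m⁻²) is small relative to the
    charge-equivalent mediator inventory a baseline batch accumulates
    (~0.011 A·h·m⁻²), so steady cycling is recharge-limited and the
    per-cycle capacity plateaus instead of tracking the slowly degrading
    inventory.  The default discharge window is shorter than the microbial
    growth phase (~5-6 h at baseline), so early cycles capture successive
    slices of the production transient and capacity builds up over the
    first cycles before the plateau.
    """

    V_min: float = 0.60
    t_discharge_max: float = 2.0
    j_charge: float = 0.02
    t_recharge: float = 0.25
    n_cycles: int = 12

    def __post_init__(self) -> None:
        _require(self.V_min > 0, "V_min must be strictly positive")
        _require(self.t_discharge_max > 0, "t_discharge_max must be positive")
        _require(self.j_charge >= 0, "j_charge must be non-negative")
        _require(self.t_recharge > 0, "t_recharge must be positive")
        _require(int(self.n_cycles) >= 1, "n_cycles must be >= 1")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "CyclingParams":
        return _from_mapping(cls, data)

    def replace(self, **kw: Any) -> "CyclingParams":
        return replace(self, **kw)
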