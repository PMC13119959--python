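"""Half-cell electrochemistry: electrode flux, Nernst potential, ohmic loss.

The anolyte is treated as a well-mixed compartment whose reduced phenazine
is oxidized at the anode with a lumped first-order rate constant,
``v_elec = k_elec·[P_red]``.  The anode potential follows the Nernst
equation for a one-step redox couple, the cathode is an ideal
counter-electrode at fixed potential, and the only loss term is a lumped
area-specific ohmic resistance:

    E_an   = E°_an + (R·T/(n·F))·ln([P_ox]/[P_red])
    E_oc   = E_cath − E_an
    V_cell = E_oc − j·R_ohm

Unit conversions between volumetric mediator flux (mmol·L⁻¹·h⁻¹) and
current density (A·m⁻²) use the electrode area per anolyte volume A
(m²·L⁻¹):  j = n·F·v_elec/(A·1000·3600), and its exact inverse for the
imposed recharge current.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .params import A_M2_TO_MA_CM2, ElectroParams

__all__ = [
    "ElectricalObservables",
    "electrode_flux",
    "current_density",
    "anode_potential",
    "cell_voltage",
    "recharge_flux",
    "observe",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ElectricalObservables:
    """Electrical quantities derived from one anolyte state.

    ``v_elec`` volumetric electrode flux (mmol·L⁻¹·h⁻¹), ``j`` current
    density (A·m⁻²), ``E_an`` anode potential (V vs SHE), ``E_oc``
    open-circuit cell voltage (V), ``V_cell`` terminal cell voltage (V).
    """

    v_elec: float
    j: float
    E_an: float
    E_oc: float
    V_cell: float

    @property
    def j_mA_cm2(self) -> float:
        """Current density in mA·cm⁻² (1 A·m⁻² = 0.1 mA·cm⁻²)."""
        return self.j * A_M2_TO_MA_CM2


def electrode_flux(P_red: float, e: ElectroParams) -> float:
    """Anodic oxidation flux v_elec = k_elec·P_red (mmol·L⁻¹·h⁻¹)."""
    if P_red < 0:
        raise ValueError(f"P_red must be >= 0, got {P_red}")
    return e.k_elec * P_red


def current_density(v_elec: float, e: ElectroParams) -> float:
    """Current density j (A·m⁻²) from the volumetric flux.

    j = n_e·F·v_elec/(A·1000·3600); the sign follows v_elec.
    """
    if not math.isfinite(v_elec):
        raise ValueError(f"v_elec must be finite, got {v_elec}")
    return e.flux_to_j * v_elec


def recharge_flux(j_charge: float, e: ElectroParams) -> float:
    """Volumetric mediator flux imposed by a charging current (mmol·L⁻¹·h⁻¹).

    Returns −j_charge·A·1000·3600/(n_e·F); the negative sign indicates
    reduction of P_ox back to P_red.  Exact inverse of
    :func:`current_density` up to sign.
    """
    if j_charge < 0:
        raise ValueError(f"j_charge must be >= 0, got {j_charge}")
    return -j_charge / e.flux_to_j


def anode_potential(P_ox: float, P_red: float, e: ElectroParams) -> float:
    """Nernstian anode potential E_an (V vs SHE).

    E_an = E°_an + (R·T/(n_e·F))·ln(max(P_ox, ε)/max(P_red, ε)) with the
    concentration floor ε = ``e.conc_floor`` keeping the log finite when a
    pool is empty.  With both pools below ε the redox state is undefined
    and E°_an is returned with a logged warning.
    """
    if P_ox < 0 or P_red < 0:
        raise ValueError(f"phenazine pools must be >= 0, got P_ox={P_ox}, P_red={P_red}")
    eps = e.conc_floor
    if P_ox < eps and P_red < eps:
        logger.warning(
            "both phenazine pools below the concentration floor (%.1e); "
            "redox state undefined, returning E0_an", eps,
        )
        return e.E0_an
    return e.E0_an + e.nernst_slope * math.log(max(P_ox, eps) / max(P_red, eps))


def cell_voltage(E_an: float, j: float, e: ElectroParams) -> tuple[float, float]:
    """Open-circuit and terminal cell voltage (V).

    E_oc = E_cath − E_an;  V_cell = E_oc − j·R_ohm.
    """
    E_oc = e.E_cath - E_an
    return E_oc, E_oc - j * e.R_ohm


def observe(P_red: float, P_ox: float, e: ElectroParams, v_elec: float | None = None) -> ElectricalObservables:
    """Bundle the electrical observables for one anolyte composition.

    ``v_elec`` defaults to the discharge flux k_elec·P_red; pass the imposed
    recharge flux explicitly to evaluate the cell under charging current.
    """
    if v_elec is None:
        v_elec = electrode_flux(P_red, e)
    j = current_density(v_elec, e)
    E_an = anode_potential(P_ox, P_red, e)
    E_oc, V_cell = cell_voltage(E_an, j, e)
    return ElectricalObservables(v_elec=v_elec, j=j, E_an=E_an, E_oc=E_oc, V_cell=V_cell)
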