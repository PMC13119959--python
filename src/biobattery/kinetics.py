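"""Microbial rate laws: Monod uptake, Hill toxicity, Luedeking-Piret production.

The microbial module is a coarse-grained description of an engineered
*E. coli* chassis secreting a soluble phenazine mediator:

* substrate uptake follows Monod kinetics, ``qS = qS_max·S/(K_S + S)``;
* the base growth rate ``μ_base = Y_XS·qS`` is scaled by a Hill-type
  toxicity factor ``1/(1 + (P_tot/K_inh)^n_inh)`` of total phenazine;
* phenazine production is Luedeking-Piret, ``r_prod = (α_P·μ + β_P)·X``,
  primarily growth-associated (β_P defaults to 0);
* both phenazine pools decay with first-order rate constant ``k_deg``.

Toxicity acts only through the growth rate (and hence through
growth-associated production); uptake, degradation and electrode flux are
unaffected.  There is no death or maintenance term, so biomass is
non-decreasing — a model property, not a bug.
"""

from __future__ import annotations

from .params import AnolyteState, MicrobialParams

__all__ = [
    "specific_uptake",
    "toxicity_factor",
    "growth_rate",
    "production_rate",
    "microbial_derivatives",
]


def specific_uptake(S: float, p: MicrobialParams) -> float:
    """Monod-type specific substrate uptake rate qS (mmol·gDW⁻¹·h⁻¹).

    qS = qS_max·S/(K_S + S); bounded by qS_max and monotone in S.
    """
    if S < 0:
        raise ValueError(f"substrate concentration must be >= 0, got {S}")
    return p.qS_max * S / (p.K_S + S)


def toxicity_factor(P_tot: float, p: MicrobialParams) -> float:
    """Hill-type growth inhibition factor in (0, 1].

    Returns 1/(1 + (P_tot/K_inh)^n_inh): 1 with no phenazine, 0.5 at
    P_tot = K_inh, approaching 0 at high mediator burden.
    """
    if P_tot < 0:
        raise ValueError(f"total phenazine must be >= 0, got {P_tot}")
    return 1.0 / (1.0 + (P_tot / p.K_inh) ** p.n_inh)


def growth_rate(state: AnolyteState, p: MicrobialParams) -> float:
    """Effective specific growth rate μ (h⁻¹), toxicity-scaled.

    μ = Y_XS·qS(S) · 1/(1 + (P_tot/K_inh)^n_inh), bounded by Y_XS·qS_max.
    """
    return p.Y_XS * specific_uptake(state.S, p) * toxicity_factor(state.P_tot, p)


def production_rate(mu: float, X: float, p: MicrobialParams) -> float:
    """Luedeking-Piret phenazine production rate (mmol·L⁻¹·h⁻¹).

    r_prod = (α_P·μ + β_P)·X.  Production feeds the reduced pool.
    """
    if mu < 0:
        raise ValueError(f"growth rate must be >= 0, got {mu}")
    if X < 0:
        raise ValueError(f"biomass must be >= 0, got {X}")
    return (p.alpha_P * mu + p.beta_P) * X


def microbial_derivatives(
    state: AnolyteState, v_elec: float, p: MicrobialParams
) -> tuple[float, float, float, float]:
    """Time derivatives (dX/dt, dS/dt, dP_red/dt, dP_ox/dt).

    ``v_elec`` is the electrode flux (mmol·L⁻¹·h⁻¹); it is positive during
    discharge (anodic oxidation of P_red to P_ox) and negative during
    recharge.  The flux moves mediator between the pools without changing
    the total, so d(P_red + P_ox)/dt = r_prod − k_deg·P_tot for any v_elec.
    """
    qS = specific_uptake(state.S, p)
    mu = p.Y_XS * qS * toxicity_factor(state.P_tot, p)
    r_prod = production_rate(mu, state.X, p)
    dX = mu * state.X
    dS = -qS * state.X
    dP_red = r_prod - v_elec - p.k_deg * state.P_red
    dP_ox = v_elec - p.k_deg * state.P_ox
    return dX, dS, dP_red, dP_ox
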