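"""SBML Level 2 Version 4 export of the microbial phenazine subsystem.

The exported model contains the four anolyte state variables (biomass,
substrate, reduced and oxidized phenazine) governed by rate rules, the
first-order electrode oxidation flux, and — optionally — a cumulative
capacity parameter whose rate rule equals the instantaneous current
density, so that integrating the document reproduces the continuous batch
operation of the native simulator.  The cycling and voltage cut-off logic
is deliberately not encoded: SBML events would be required and the
exported component is the continuous microbial subsystem intended for
reuse in standard systems-biology software.

Intermediate quantities (Monod uptake, Hill toxicity factor, effective
growth rate, production rate, electrode flux) are exposed as assignment
rules so the document is self-describing.

Unit conventions: time in hours, mediator and substrate concentrations in
mmol·L⁻¹, biomass in g·L⁻¹ (grams of cell dry weight; SBML has no
dry-weight unit, so plain grams are used and annotated), cumulative
capacity in A·h·m⁻².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import libsbml

from .params import AnolyteState, ElectroParams, MicrobialParams

__all__ = ["SbmlModelSpec", "ValidationReport", "export_sbml", "validate_sbml", "read_sbml_values"]

SBML_LEVEL = 2
SBML_VERSION = 4

#: Parameter ids that must be strictly positive for the model to be meaningful.
_POSITIVE_PARAMS = ("qS_max", "K_S", "Y_XS", "k_deg", "K_inh", "n_inh", "k_elec", "A_per_vol", "n_e", "F_const")


class SbmlExportError(ValueError):
    """Raised when the model specification cannot be encoded."""


@dataclass(frozen=True)
class SbmlModelSpec:
    """What to encode: kinetic parameters, half-cell subset, initial state."""

    microbial: MicrobialParams = field(default_factory=MicrobialParams)
    electro: ElectroParams = field(default_factory=ElectroParams)
    initial: AnolyteState = field(default_factory=AnolyteState)
    include_capacity: bool = True
    model_id: str = "phenazine_anolyte"

    def validate(self) -> None:
        bad = []
        for obj, names in ((self.microbial, ("qS_max", "K_S", "Y_XS", "alpha_P", "beta_P", "k_deg", "K_inh", "n_inh")),
                           (self.electro, ("k_elec", "A", "n_e", "F")),
                           (self.initial, ("X", "S", "P_red", "P_ox"))):
            for n in names:
                v = getattr(obj, n)
                if not math.isfinite(v):
                    bad.append(f"{type(obj).__name__}.{n}={v}")
        if bad:
            raise SbmlExportError(f"non-finite fields in model spec: {', '.join(bad)}")


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of the validator pipeline: libsbml consistency checks plus
    domain sanity checks on the known kinetic parameters."""

    errors: tuple[str, ...]
    warnings: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"ValidationReport(errors={len(self.errors)}, warnings={len(self.warnings)})"


def _add_unit(model, uid: str, parts: list[tuple[int, int, float]]) -> None:
    """parts: list of (unit kind, exponent, multiplier)."""
    ud = model.createUnitDefinition()
    ud.setId(uid)
    for kind, exp, mult in parts:
        u = ud.createUnit()
        u.setKind(kind)
        u.setExponent(exp)
        u.setScale(0)
        u.setMultiplier(mult)


def _set_math(rule, formula: str) -> None:
    ast = libsbml.parseL3Formula(formula)
    if ast is None:
        raise SbmlExportError(f"could not parse rate/assignment formula: {formula}")
    rule.setMath(ast)


def export_sbml(spec: SbmlModelSpec | None = None) -> str:
    """Serialize the microbial phenazine subsystem as SBML L2V4 text.

    The document declares four species (X, S, P_red, P_ox) with rate rules,
    assignment rules for the intermediate rates, and (by default) the
    cumulative-capacity parameter ``Q_cap`` whose rate equals the
    instantaneous current density in A·m⁻², so Q_cap accumulates A·h·m⁻²
    with time in hours.
    """
    spec = spec or SbmlModelSpec()
    spec.validate()
    mp, ep, init = spec.microbial, spec.electro, spec.initial

    doc = libsbml.SBMLDocument(SBML_LEVEL, SBML_VERSION)
    model = doc.createModel()
    model.setId(spec.model_id)
    model.setName("Phenazine-producing E. coli anolyte: microbial subsystem")

    # --- units ------------------------------------------------------------
    _add_unit(model, "hour", [(libsbml.UNIT_KIND_SECOND, 1, 3600.0)])
    _add_unit(model, "per_hour", [(libsbml.UNIT_KIND_SECOND, -1, 1.0 / 3600.0)])
    _add_unit(model, "mmol", [(libsbml.UNIT_KIND_MOLE, 1, 1e-3)])
    _add_unit(model, "mmol_per_litre",
              [(libsbml.UNIT_KIND_MOLE, 1, 1e-3), (libsbml.UNIT_KIND_LITRE, -1, 1.0)])
    _add_unit(model, "gDW_per_litre",
              [(libsbml.UNIT_KIND_GRAM, 1, 1.0), (libsbml.UNIT_KIND_LITRE, -1, 1.0)])
    _add_unit(model, "ampere_hour_per_m2",
              [(libsbml.UNIT_KIND_AMPERE, 1, 1.0), (libsbml.UNIT_KIND_SECOND, 1, 3600.0),
               (libsbml.UNIT_KIND_METRE, -2, 1.0)])
    model.setTimeUnits("hour")

    comp = model.createCompartment()
    comp.setId("anolyte")
    comp.setSize(1.0)
    comp.setUnits("litre")
    comp.setConstant(True)

    # --- species (concentrations per litre of anolyte) ---------------------
    species = [
        ("X", init.X, "gram", "biomass concentration, gDW per litre"),
        ("S", init.S, "mmol", "substrate (glucose) concentration"),
        ("P_red", init.P_red, "mmol", "reduced phenazine concentration"),
        ("P_ox", init.P_ox, "mmol", "oxidized phenazine concentration"),
    ]
    for sid, value, sub_units, name in species:
        sp = model.createSpecies()
        sp.setId(sid)
        sp.setName(name)
        sp.setCompartment("anolyte")
        sp.setInitialConcentration(value)
        sp.setSubstanceUnits(sub_units)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    # --- constant parameters ------------------------------------------------
    constants = [
        ("qS_max", mp.qS_max, "maximum specific substrate uptake rate, mmol/gDW/h"),
        ("K_S", mp.K_S, "Monod half-saturation constant, mmol/L"),
        ("Y_XS", mp.Y_XS, "biomass yield on substrate, gDW/mmol"),
        ("alpha_P", mp.alpha_P, "growth-associated phenazine yield, mmol/gDW"),
        ("beta_P", mp.beta_P, "non-growth-associated production, mmol/gDW/h"),
        ("k_deg", mp.k_deg, "first-order phenazine degradation constant, 1/h"),
        ("K_inh", mp.K_inh, "half-inhibition total phenazine, mmol/L"),
        ("n_inh", mp.n_inh, "Hill coefficient of growth inhibition"),
        ("k_elec", ep.k_elec, "lumped electrode oxidation constant, 1/h"),
        ("A_per_vol", ep.A, "electrode area per anolyte volume, m2/L"),
        ("n_e", float(ep.n_e), "electrons per phenazine redox event"),
        ("F_const", ep.F, "Faraday constant, C/mol"),
    ]
    for pid, value, name in constants:
        par = model.createParameter()
        par.setId(pid)
        par.setName(name)
        par.setValue(value)
        par.setConstant(True)

    # --- derived quantities (assignment rules) ------------------------------
    derived = [
        ("qS", "qS_max * S / (K_S + S)"),
        ("tox", "1 / (1 + ((P_red + P_ox) / K_inh)^n_inh)"),
        ("mu", "Y_XS * qS * tox"),
        ("v_elec", "k_elec * P_red"),
        ("r_prod", "(alpha_P * mu + beta_P) * X"),
    ]
    for pid, formula in derived:
        par = model.createParameter()
        par.setId(pid)
        par.setConstant(False)
        par.setValue(0.0)
        rule = model.createAssignmentRule()
        rule.setVariable(pid)
        _set_math(rule, formula)

    # --- dynamics (rate rules) ----------------------------------------------
    rates = [
        ("X", "mu * X"),
        ("S", "-qS * X"),
        ("P_red", "r_prod - v_elec - k_deg * P_red"),
        ("P_ox", "v_elec - k_deg * P_ox"),
    ]
    if spec.include_capacity:
        par = model.createParameter()
        par.setId("Q_cap")
        par.setName("cumulative discharge capacity, A·h/m2")
        par.setUnits("ampere_hour_per_m2")
        par.setConstant(False)
        par.setValue(0.0)
        rates.append(("Q_cap", "n_e * F_const * v_elec / (A_per_vol * 1000 * 3600)"))
    for var, formula in rates:
        rule = model.createRateRule()
        rule.setVariable(var)
        _set_math(rule, formula)

    return libsbml.writeSBMLToString(doc)


def validate_sbml(document: str) -> ValidationReport:
    """Check an SBML document: parse, libsbml consistency, domain sanity.

    Unit-consistency diagnostics are reported as warnings; structural and
    schema problems as errors.  Known kinetic parameters with non-positive
    values are flagged as warnings (legal SBML, meaningless kinetics).
    """
    if not document or not document.strip():
        return ValidationReport(errors=("empty document",), warnings=())
    doc = libsbml.readSBMLFromString(document)
    errors: list[str] = []
    warnings: list[str] = []

    def harvest(d) -> None:
        for i in range(d.getNumErrors()):
            e = d.getError(i)
            msg = f"line {e.getLine()}: {e.getMessage().strip()}"
            if e.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                errors.append(msg)
            else:
                warnings.append(msg)

    harvest(doc)
    if doc.getModel() is None:
        errors.append("document contains no model")
        return ValidationReport(errors=tuple(errors), warnings=tuple(warnings))

    # full consistency check, demoting unit diagnostics to warnings
    doc.setConsistencyChecks(libsbml.LIBSBML_CAT_UNITS_CONSISTENCY, False)
    doc.checkConsistency()
    harvest(doc)

    model = doc.getModel()
    for pid in _POSITIVE_PARAMS:
        par = model.getParameter(pid)
        if par is not None and par.isSetValue() and par.getValue() <= 0:
            warnings.append(f"parameter {pid} = {par.getValue()} is not strictly positive")
    return ValidationReport(errors=tuple(errors), warnings=tuple(warnings))


def read_sbml_values(document: str) -> dict[str, float]:
    """Parameter values and species initial concentrations of a document.

    Round-trip helper: ``read_sbml_values(export_sbml(spec))`` recovers the
    numbers that were encoded, keyed by SBML id.
    """
    doc = libsbml.readSBMLFromString(document)
    if doc.getNumErrors() > 0 and doc.getModel() is None:
        raise ValueError("unparseable SBML document")
    model = doc.getModel()
    out: dict[str, float] = {}
    for i in range(model.getNumParameters()):
        par = model.getParameter(i)
        if par.getConstant():
            out[par.getId()] = par.getValue()
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        out[sp.getId()] = sp.getInitialConcentration()
    return out
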