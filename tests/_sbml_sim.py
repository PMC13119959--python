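"""A small generic SBML integrator used as an independent cross-check.

Reads any SBML document whose dynamics are expressed as rate rules (with
optional assignment rules for intermediate quantities), and integrates it
with an explicit Euler scheme.  It interprets only the parsed SBML math —
it knows nothing about the model that produced the document — so agreement
with the native simulator genuinely tests the export.
"""

from __future__ import annotations

import libsbml
import numpy as np


def _compile(math_ast) -> object:
    formula = libsbml.formulaToL3String(math_ast)
    return compile(formula.replace("^", "**"), "<sbml>", "eval")


def simulate_sbml(document: str, t_end: float, dt: float) -> dict[str, np.ndarray]:
    """Euler-integrate an SBML document's rate rules.

    Returns arrays keyed by SBML id (species, rate-rule parameters) plus
    ``"time"``.
    """
    doc = libsbml.readSBMLFromString(document)
    if doc.getModel() is None:
        raise ValueError("unparseable SBML document")
    model = doc.getModel()

    env: dict[str, float] = {}
    for i in range(model.getNumCompartments()):
        c = model.getCompartment(i)
        env[c.getId()] = c.getSize()
    for i in range(model.getNumParameters()):
        p = model.getParameter(i)
        env[p.getId()] = p.getValue() if p.isSetValue() else 0.0
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        env[s.getId()] = s.getInitialConcentration()

    assignments: list[tuple[str, object]] = []
    rates: list[tuple[str, object]] = []
    for i in range(model.getNumRules()):
        rule = model.getRule(i)
        code = _compile(rule.getMath())
        if rule.isAssignment():
            assignments.append((rule.getVariable(), code))
        elif rule.isRate():
            rates.append((rule.getVariable(), code))

    n = int(round(t_end / dt))
    track = ["time"] + [v for v, _ in rates]
    out = {k: np.empty(n + 1) for k in track}

    for step in range(n + 1):
        for var, code in assignments:
            env[var] = eval(code, {"__builtins__": {}}, env)
        out["time"][step] = step * dt
        for var, _ in rates:
            out[var][step] = env[var]
        if step == n:
            break
        derivs = {var: eval(code, {"__builtins__": {}}, env) for var, code in rates}
        for var, d in derivs.items():
            env[var] = max(env[var] + dt * d, 0.0)
    return out
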