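# biobattery

A zero-dimensional mechanistic simulator of a **phenazine-producing
*E. coli* bio-battery anolyte**: a living culture that synthesizes its own
redox mediator inside the negative half-cell of a redox flow battery.
The package is aimed at bioelectrochemistry and synthetic-biology modelers
who want to screen designs — how strongly should the strain produce
mediator, how much biomass to load, how tolerant must the host be, how
stable must the mediator stay — before committing to bench experiments.

## Model

A well-mixed anolyte with four states (biomass `X` in gDW·L⁻¹; substrate
`S`, reduced and oxidized phenazine `P_red`, `P_ox` in mmol·L⁻¹) couples
microbial kinetics to a Nernstian half-cell:

```
qS  = qS_max·S/(K_S+S)                         Monod uptake
μ   = Y_XS·qS / (1 + (P_tot/K_inh)^n_inh)      Hill-type toxicity on growth
dX/dt = μX          dS/dt = −qS·X
r_prod = (α_P·μ + β_P)·X                       Luedeking-Piret production
dP_red/dt = r_prod − v_elec − k_deg·P_red
dP_ox/dt  = v_elec − k_deg·P_ox

v_elec = k_elec·P_red                          first-order anode oxidation
j      = n·F·v_elec/(A·1000·3600)              current density, A·m⁻²
E_an   = E°_an + (RT/nF)·ln(P_ox/P_red)
V_cell = (E_cath − E_an) − j·R_ohm
```

On top of the batch simulator (explicit Euler, Δt = 0.01 h default) the
package provides explicit charge–discharge cycling with a voltage cut-off,
an α_P × X₀ design-space sweep, K_inh/k_deg sensitivity curves, redox
speciation analysis, and SBML Level 2 Version 4 export of the microbial
subsystem. Everything is deterministic. See `docs/methods.md` for
assumptions, parameter provenance, and numerical choices.

## Worked example

```python
import numpy as np
import biobattery as bb

traj = bb.simulate_batch(bb.AnolyteState(), bb.MicrobialParams(),
                         bb.ElectroParams(), bb.TerminationSpec(t_max=200.0),
                         dt=0.01)
m = bb.summary_metrics(traj)
print(f"peak j : {m.peak_j * bb.A_M2_TO_MA_CM2:.3e} mA/cm^2 "
      f"at t = {traj.t[np.argmax(traj.j)]:.2f} h")
print(f"charge : {m.cumulative_charge:.4f} A h/m^2 over {m.duration:.0f} h")
print(f"final  : X = {traj.X[-1]:.3f} gDW/L, P_tot = {traj.P_tot[-1]:.4f} mmol/L")

recs = bb.run_cycling(bb.AnolyteState(), bb.moderate_design(),
                      bb.ElectroParams(), bb.CyclingParams(), dt=0.01)
print("cycle capacities:", ", ".join(f"{r.Q_k:.4f}" for r in recs))
```

prints

```
peak j : 2.804e-04 mA/cm^2 at t = 2.53 h
charge : 0.0116 A h/m^2 over 200 h
final  : X = 0.770 gDW/L, P_tot = 0.0030 mmol/L
cycle capacities: 0.0032, 0.0082, 0.0075, 0.0045, 0.0045, 0.0045, 0.0045,
0.0045, 0.0045, 0.0045, 0.0045, 0.0045
```

Reading this: the baseline culture grows until its own phenazine burden and
substrate depletion shut production down — the current density peaks near
2.8×10⁻⁴ mA·cm⁻² a couple of hours in, declines through the ~2.4×10⁻⁴
range, and collapses once substrate is gone. Under cycling, per-cycle
capacity first builds as the culture grows (0.0032 → 0.0082 A·h·m⁻²), then
settles on a recharge-limited plateau of 0.0045 A·h·m⁻² that a ten-fold
more aggressive producer converges to as well: production strength buys an
initial transient, not steady-state capacity.

## Command line

```bash
biobattery batch --config examples/baseline.yaml --out batch.csv
biobattery cycle --out cycles.csv
biobattery sweep --out sweep.csv --heatmap sweep.png
biobattery sensitivity --out sensitivity.csv
biobattery export-sbml --out model.xml
```

Each command writes a tidy CSV (or the SBML XML) plus a `.meta.json`
sidecar containing the complete resolved parameter set; identical
configurations produce bit-identical outputs.

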