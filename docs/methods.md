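# Methods

## Model

`biobattery` simulates a well-mixed ("zero-dimensional") anolyte in which an
engineered *E. coli* strain secretes a soluble phenazine mediator that a
flow-battery half-cell oxidizes at the anode. Four state variables are
tracked per unit anolyte volume: biomass `X` (gDW·L⁻¹), substrate `S`
(mmol·L⁻¹), and the reduced/oxidized mediator pools `P_red`, `P_ox`
(mmol·L⁻¹), with total phenazine `P_tot = P_red + P_ox`. Time is in hours.

Microbial module:

    qS  = qS_max · S/(K_S + S)                         (Monod uptake)
    μ   = Y_XS · qS · 1/(1 + (P_tot/K_inh)^n_inh)      (toxicity-scaled growth)
    dX/dt = μ·X
    dS/dt = −qS·X
    r_prod = (α_P·μ + β_P)·X                           (Luedeking-Piret)
    dP_red/dt = r_prod − v_elec − k_deg·P_red
    dP_ox/dt  = v_elec − k_deg·P_ox

Assumptions worth stating explicitly:

* **No death or maintenance term**: `X` is non-decreasing by construction.
* **Toxicity acts only on growth** (and hence on growth-associated
  production). Substrate uptake is *not* toxicity-scaled, so a
  growth-arrested culture still consumes substrate at the Monod rate; the
  effective biomass yield collapses under mediator burden. This follows
  directly from the governing equations and has visible consequences (see
  "Sweep metric" below).
* Production feeds the reduced pool only; degradation (`k_deg`) removes
  both redox states at first order and is the only irreversible loss.

Electrochemical module (discharge):

    v_elec = k_elec · P_red                            (lumped first-order anode)
    j      = n_e·F·v_elec / (A·1000·3600)              (A·m⁻²)
    E_an   = E°_an + (R·T/(n_e·F))·ln(P_ox/P_red)      (Nernst)
    E_oc   = E_cath − E_an
    V_cell = E_oc − j·R_ohm

The cathode is an ideal counter-electrode at fixed potential and the only
loss term is the lumped area-specific resistance; there is no
activation/Butler-Volmer overpotential, membrane crossover, or catholyte
dynamics. The unit conversion divides the volumetric electron flux
(mmol·L⁻¹·h⁻¹ → mol·L⁻¹·s⁻¹ → A·L⁻¹) by the electrode area per anolyte
volume `A` (m²·L⁻¹); the recharge conversion is its exact inverse, which
round-trip property tests pin down.

During recharge a constant current density `j_charge` is imposed in the
reducing direction; biomass and substrate are held fixed over the short
recharge interval and only the mediator pools evolve.

## Parameters

| symbol | default | units | meaning / why this value |
|---|---|---|---|
| qS_max | 10 | mmol·gDW⁻¹·h⁻¹ | aerobic glucose uptake ceiling for *E. coli* |
| K_S | 0.10 | mmol·L⁻¹ | high-affinity uptake regime |
| Y_XS | 0.09 | gDW·mmol⁻¹ | ≈0.5 gDW per g glucose, aerobic yield |
| α_P | 0.03 | mmol·gDW⁻¹ | growth-associated phenazine yield (design variable) |
| β_P | 0 | mmol·gDW⁻¹·h⁻¹ | production is primarily growth-associated; the constitutive term is exposed but off by default |
| k_deg | 0.01 | h⁻¹ | first-order mediator loss (decay, adsorption, side reactions) |
| K_inh | 0.010 | mmol·L⁻¹ | 10 µM half-inhibition, the order of pyocyanin sensitivity of non-native hosts |
| n_inh | 2 | – | sigmoidal (cooperative) growth suppression |
| k_elec | 20 | h⁻¹ | lumped electrode oxidation constant |
| A | 0.10 | m²·L⁻¹ | ≈100 m²·m⁻³, porous carbon felt |
| n_e | 2 | – | two-electron phenazine redox chemistry |
| E°_an | −0.10 | V vs SHE | aqueous phenazine negolyte range |
| E_cath | 0.90 | V vs SHE | representative aqueous catholyte |
| R_ohm | 0.50 | Ω·m² | lumped ionic/electronic resistance |
| V_min | 0.60 | V | discharge cut-off |
| j_charge | 0.02 | A·m⁻² | gentle recharge current |

Initial conditions default to `X₀ = 0.05 gDW·L⁻¹`, `S₀ = 20 mmol·L⁻¹`,
`P_red₀ = P_ox₀ = 0`: a dilute inoculum in fresh medium with no mediator.
These are package choices (X₀ doubles as a sweep variable); every run's
metadata sidecar records them.

## Numerical scheme

The coupled system is integrated with an explicit Euler scheme, default
Δt = 0.01 h (the accurate end of the 0.01–0.05 h range the model targets;
the fastest rate, `k_elec` = 20 h⁻¹, gives Δt·k = 0.2). Convergence is
checked two ways in the test suite: Δt = 0.01 vs 0.001 agrees within 1% at
t = 50 h on the baseline run, and halving Δt changes the terminal state by
< 0.5%.

* **Negative excursions** are clamped to zero after each step; clamp events
  are counted and the largest magnitude recorded in the trajectory (zero at
  baseline settings).
* **Nernst floor**: the log ratio uses `max(pool, ε)` with ε = 10⁻¹⁸
  mmol·L⁻¹. The floor must be far smaller than the commonly used 10⁻⁹:
  reaching the 0.6 V cut-off from the default potentials requires
  P_ox/P_red ≈ 3×10¹³, so a 10⁻⁹ floor would cap the Nernstian swing ≈0.23 V
  short of the cut-off and the voltage terminator could never fire. With
  both pools below ε the redox state is undefined and E°_an is returned with
  a logged warning.
* **Charge bookkeeping** integrates `j` trapezoidally on step boundaries;
  cut-off detection happens at step boundaries without interpolating the
  crossing, so the per-cycle capacity error is bounded by one step's charge.
* **Recharge flux limiting**: in any recharge step that would drive `P_ox`
  negative, the imposed flux is truncated for that step — the
  constant-current assumption yields to mediator availability.

## Study protocols and open design choices

**Batch baseline** runs 200 h with no other stopping rule; the current
density rises with the production transient, passes ~0.24×10⁻³ mA·cm⁻²
during its decline, and collapses when substrate depletes.

**Toxicity-limited protocol** (sweeps and sensitivity): each run stops at
200 h or when `P_tot` exceeds **2·K_inh** (growth 80% suppressed at Hill
n = 2). The multiplier is a package choice; it is set where the stop
actually terminates aggressive designs (120/225 default grid points),
because the shutdown is what shapes the design map. At 5·K_inh the
substrate budget caps `P_tot` below the threshold almost everywhere and the
stop would be inoperative.

**Sweep metric**: `time_averaged_j` is the charge passed divided by the
*protocol horizon* `t_max`, not by the realized (possibly truncated) run
time. Dividing by the realized horizon would paradoxically score an
aggressive design that collapses within the first hour as the best design
on the grid, because it is briefly fast; normalizing by the operating
window makes early toxicity-driven shutdown show up as lost performance.
`summary_metrics` still reports the realized-horizon average for single
trajectories. The design map then shows performance rising along α_P to a
maximum at intermediate production strength (the default grid's argmax sits
at the baseline α_P = 0.03) and falling beyond it, while the X₀ axis is
nearly flat: with a 200 h window every inoculum size has time to complete
the same substrate-limited growth course, so X₀ mostly sets *when*, not
*how much*.

**Cycling protocol** defaults (V_min and j_charge are the half-cell
constants above; the
durations are package choices): `t_discharge_max = 2 h`,
`t_recharge = 0.25 h`, `n_cycles = 12`. The recharge interval is chosen so
the recharged charge (0.005 A·h·m⁻²) is small relative to the
charge-equivalent mediator inventory a baseline batch accumulates
(~0.011 A·h·m⁻²); steady cycling is then recharge-limited and the capacity
plateaus (0.004492 A·h·m⁻² for both the moderate- and high-production
designs) instead of tracking the slowly degrading inventory. The discharge
window is shorter than the ~5–6 h growth phase so early cycles capture
successive slices of the production transient: moderate-design capacity
builds over the first cycles (0.0032 → 0.0082 A·h·m⁻²) before settling,
while the high-production design starts above its plateau and fades onto
it. With a 2 h recharge (0.04 A·h·m⁻² demand) every recharge would be
inventory-limited and capacity would fade monotonically at ≈k_deg per
cycle-hour — no plateau and no cross-design convergence.

**Sensitivity metrics**: besides the protocol-window average current
density, the curves report the cumulative extracted charge and the *stored*
charge — the charge-equivalent mediator inventory at the end of the run and
(after first-order decay of the remainder, production having ceased at the
stop) at the end of the protocol window. Faster degradation raises the
average current modestly — it keeps `P_tot` lower, delaying toxicity, so
microbial activity persists longer — while stored charge falls strictly.
Cumulative *extracted* charge also rises with `k_deg` in this model (the
toxicity relief converts more substrate into mediator overall), which is
why the stored-charge metric, not the extracted one, is the right reading
of "degradation costs capacity".

**Design labels**: the *moderate-production* design is the baseline
α_P = 0.03; the *high-production* design is the α_P on the default grid
maximizing peak instantaneous current density (the aggressive end,
α_P = 0.3, located by a coarse Δt = 0.05 scan).

## SBML export

The microbial subsystem (four species with rate rules, assignment rules
for the intermediate rates, the electrode oxidation flux, and a
cumulative-capacity parameter whose rate rule is the current-density
expression) is exported as SBML Level 2 Version 4. Concentrations are
declared in mmol·L⁻¹-equivalent units; biomass uses grams per litre (SBML
has no dry-weight unit — the species name records that grams mean gDW).
Cycling and the voltage cut-off are deliberately *not* encoded (they would
require SBML events; the export is the continuous batch subsystem). The
test suite cross-simulates the document with a small generic rate-rule
integrator that interprets only the parsed SBML math and requires 1%
agreement with the native simulator at t = 50 h, plus a bit-exact
round-trip of all encoded values.

## What the tests do and do not show

The model is deterministic — there is no synthetic-noise generator; the
"study conditions" are the parameter defaults above. Passing tests show
that the implementation integrates the stated equations correctly
(conservation to machine precision, dt-convergence, cross-simulator
agreement), that the analytic limits hold exactly, and that the documented
qualitative regimes (interior performance ridge in α_P, capacity plateau
and cross-design convergence, oxidized-skewed speciation, sensitivity
directions) emerge at the default settings. They do not validate the model
against a real bioelectrochemical system: spatial gradients, biofilms,
mass-transfer films, oxygen/pH dynamics, catholyte behavior, and
genome-scale metabolism are all outside the model, and several protocol
constants (initial conditions, toxicity-stop multiplier, cycling windows)
are documented package choices rather than measured quantities.

## Known limitations

* Growth-arrested cultures consume substrate at full Monod rate (no
  maintenance partitioning), which strongly discounts the effective yield
  under toxicity — a direct consequence of the governing equations.
* Explicit Euler with zero-clamping can (in extreme parameter corners)
  overshoot fast transients; peak-current readings at the aggressive end of
  the design grid carry a few-percent step-size bias (4.67 vs 4.38 ×10⁻³
  mA·cm⁻² between Δt = 0.01 and Δt = 10⁻⁴ at the grid corner).
* The voltage cut-off depends on the Nernst floor being far below the
  physical pool sizes; configurations that raise ε above ~10⁻¹⁵ mmol·L⁻¹
  silently disable the cut-off (a warning is logged when the floor binds).
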