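# Baseline bio-battery configuration.
#
# Every block is optional; omitted values resolve to the baseline parameter
# set hard-coded in the package (aerobic E. coli uptake/yield, pyocyanin-like
# toxicity, aqueous phenazine half-cell).  Shown here in full as a template.
defaults: baseline

microbial:
  qS_max: 10.0     # mmol/gDW/h
  K_S: 0.10        # mmol/L
  Y_XS: 0.09       # gDW/mmol
  alpha_P: 0.03    # mmol/gDW, growth-associated phenazine yield
  beta_P: 0.0      # mmol/gDW/h, constitutive production (off by default)
  k_deg: 0.01      # 1/h
  K_inh: 0.010     # mmol/L (10 uM)
  n_inh: 2.0

electro:
  k_elec: 20.0     # 1/h
  A: 0.10          # m2/L
  n_e: 2
  E0_an: -0.10     # V vs SHE
  E_cath: 0.90     # V vs SHE
  R_ohm: 0.50      # Ohm m2
  T: 298.15        # K

initial:
  X: 0.05          # gDW/L
  S: 20.0          # mmol/L
  P_red: 0.0
  P_ox: 0.0

termination:
  t_max: 200.0     # h

cycling:
  V_min: 0.60            # V
  t_discharge_max: 2.0   # h
  j_charge: 0.02         # A/m2
  t_recharge: 0.25       # h
  n_cycles: 12

dt: 0.01           # h, explicit Euler step
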