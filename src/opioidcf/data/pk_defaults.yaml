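# Default pharmacokinetic parameter sets and MME conversion factors.
#
# The PK values are population three-compartment bolus parameters of the kind
# reported for adult IV fentanyl (Scott & Stanski-style disposition with a
# plasma/effect-site equilibration half-time of ~5 min) and for IV
# hydromorphone (slower effect-site equilibration). They are reasonable
# literature-style defaults for simulation and demonstration, not a clinical
# reference: the code treats everything in this file as opaque configuration,
# and per-study parameterizations (including demographic adjustment) should
# be supplied via --pk / per-patient overrides.
#
# Units: V1 in litres, all rate constants in 1/min. Doses are in ug, so
# concentrations come out in ug/L = ng/mL.
pk_parameters:
  fentanyl:
    V1: 12.7
    k10: 0.0562
    k12: 0.2803
    k21: 0.1407
    k13: 0.1346
    k31: 0.0035
    ke0: 0.147
    n_compartments: 3
  hydromorphone:
    V1: 14.0
    k10: 0.0660
    k12: 0.1930
    k21: 0.0780
    k13: 0.0360
    k31: 0.0113
    ke0: 0.0290
    n_compartments: 3

# MME per microgram administered (IV equianalgesic convention:
# 100 ug IV fentanyl ~ 10 mg oral morphine; hydromorphone mg x 4 = MME).
mme_per_ug:
  fentanyl: 0.1
  hydromorphone: 0.004
  morphine: 0.001
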