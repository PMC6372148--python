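# M4 — incoherent feedforward loop hub.
# The signal both activates X into Xa (reaction A) and, through the feedforward
# branch, activates an inhibitor (Y -> Ya, reaction FFA).  Xa is removed by a
# basal first-order deactivation (D) and by an inhibitor-mediated deactivation
# (DS, Michaelis-Menten in Xa with Ya as the catalytic modifier).  Ya reverts
# by first-order decay (FFR).  Both pools are conserved.
#
# Provenance: the structure {A, D, DS, FFA, FFR} and parameter names (k1, km1,
# k2a, k2b, km2, k3, km3, k4) follow the published hub-motif family (the
# feedforward model is the one whose inhibitor-mediated deactivation pairs k2b
# with km2); numeric reference values are RECONSTRUCTED so that a sustained
# unit stimulus produces the incoherent-feedforward signature: an early peak
# (Xa ~ 600 near t = 20 min) adapting down far below it as Ya accumulates.
id: M4
name: incoherent feedforward loop
species: [X, Xa, Y, Ya]
output: Xa
pools:
  - total: 1000.0        # reconstructed: conserved pool X + Xa
    members: [X, Xa]
    eliminate: X
  - total: 1000.0        # reconstructed: conserved pool Y + Ya
    members: [Y, Ya]
    eliminate: Y
initial:
  X: 1000.0
  Xa: 0.0
  Y: 1000.0
  Ya: 0.0
reactions:
  - label: A
    rate_law: michaelis_menten
    k: k1
    km: km1
    substrate: X
    signal: true
    stoich: {X: -1, Xa: 1}
  - label: D             # basal deactivation
    rate_law: mass_action
    k: k2a
    substrate: Xa
    stoich: {Xa: -1, X: 1}
  - label: DS            # inhibitor-mediated deactivation (Ya catalyses)
    rate_law: michaelis_menten
    k: k2b
    km: km2
    substrate: Xa
    modifier: Ya
    stoich: {Xa: -1, X: 1}
  - label: FFA           # feedforward activation of the inhibitor by s
    rate_law: michaelis_menten
    k: k3
    km: km3
    substrate: Y
    signal: true
    stoich: {Y: -1, Ya: 1}
  - label: FFR           # inhibitor reversion
    rate_law: mass_action
    k: k4
    substrate: Ya
    stoich: {Ya: -1, Y: 1}
reference_params:
  k1: 50.0               # reconstructed, amount/min at s = 1
  km1: 100.0             # reconstructed, amount
  k2a: 0.05              # reconstructed, 1/min
  k2b: 0.15              # reconstructed, 1/min per unit Ya (Vmax = k2b*Ya)
  km2: 100.0             # reconstructed, amount
  k3: 20.0               # reconstructed, amount/min at s = 1 (Vmax of FFA)
  km3: 100.0             # reconstructed, amount
  k4: 0.02               # reconstructed, 1/min
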