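# M3 — negative feedback loop hub.
# The signal activates X into Xa; Xa activates a feedback inhibitor (Y -> Ya,
# reaction FBA); active inhibitor Ya mediates the deactivation of Xa (reaction
# D, second-order mass action in Xa and Ya); Ya reverts by first-order decay
# (reaction FBR).  Both X+Xa and Y+Ya pools are conserved.
#
# Provenance: the feedback structure with reactions {A, D, FBA, FBR} and the
# parameter names (k1, km1, k2b, k3, km3, k4) follow the published hub-motif
# family (the feedback model is the one whose deactivation carries k2b and
# whose feedback arm carries k3/km3 and k4); numeric reference values are
# RECONSTRUCTED so that a sustained unit stimulus produces an overshoot
# (Xa ~ 700) relaxing to an adapted plateau (Xa ~ 500) as the inhibitor builds.
id: M3
name: negative feedback loop
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
  - label: D             # inhibitor-mediated deactivation, mass action in Xa*Ya
    rate_law: mass_action
    k: k2b
    substrate: Xa
    modifier: Ya
    stoich: {Xa: -1, X: 1}
  - label: FBA           # feedback activation of the inhibitor by Xa
    rate_law: michaelis_menten
    k: k3
    km: km3
    substrate: Y
    modifier: Xa
    stoich: {Y: -1, Ya: 1}
  - label: FBR           # inhibitor reversion
    rate_law: mass_action
    k: k4
    substrate: Ya
    stoich: {Ya: -1, Y: 1}
reference_params:
  k1: 50.0               # reconstructed, amount/min at s = 1
  km1: 100.0             # reconstructed, amount
  k2b: 5.0e-4            # reconstructed, 1/(amount*min)
  k3: 0.04               # reconstructed, 1/min per unit Xa (Vmax = k3*Xa)
  km3: 100.0             # reconstructed, amount
  k4: 0.1                # reconstructed, 1/min
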