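# M1 — reversible reaction hub.
# A single activation/deactivation pair: the input signal s drives activation of
# X into Xa ("X*", the output), and Xa reverts to X by first-order deactivation.
#
# Provenance: the motif structure (reaction set {A, D}), the rate-law mix
# (Michaelis-Menten activation, mass-action deactivation) and the parameter
# names (k1, km1, k2a) follow the published hub-motif family; the numeric
# reference values below are RECONSTRUCTED defaults chosen once to give a
# responsive mid-range output (half of the pool activated within ~20 min of a
# sustained unit stimulus) on the 0-300 min horizon.  Units: time in minutes,
# amounts in arbitrary molecule-count units.
id: M1
name: reversible reaction
species: [X, Xa]
output: Xa
pools:
  - total: 1000.0        # reconstructed: conserved pool X + Xa
    members: [X, Xa]
    eliminate: X
initial:
  X: 1000.0              # everything inactive at t = 0
  Xa: 0.0
reactions:
  - label: A             # activation: s-driven, saturating in X
    rate_law: michaelis_menten
    k: k1
    km: km1
    substrate: X
    signal: true
    stoich: {X: -1, Xa: 1}
  - label: D             # deactivation: first-order in Xa
    rate_law: mass_action
    k: k2a
    substrate: Xa
    stoich: {Xa: -1, X: 1}
reference_params:
  k1: 50.0               # reconstructed, amount/min at s = 1 (Vmax of A)
  km1: 100.0             # reconstructed, amount
  k2a: 0.05              # reconstructed, 1/min
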