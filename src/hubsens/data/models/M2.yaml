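# M2 — cycle reaction hub.
# Extends M1 with a refractory state: activated Xa deactivates into Y, which is
# recycled back to the activatable form X by the cycle reaction R.  The pool
# X + Xa + Y is conserved.
#
# Provenance: structure {A, D, R} and parameter names (k1, km1, k2a, k3, km3)
# follow the published hub-motif family; numeric reference values are
# RECONSTRUCTED (see M1.yaml for conventions).  The recycle Vmax k3 is set so
# the refractory pool turns over on a ~10-30 min time scale.
id: M2
name: cycle reaction
species: [X, Xa, Y]
output: Xa
pools:
  - total: 1000.0        # reconstructed: conserved pool X + Xa + Y
    members: [X, Xa, Y]
    eliminate: X
initial:
  X: 1000.0
  Xa: 0.0
  Y: 0.0
reactions:
  - label: A
    rate_law: michaelis_menten
    k: k1
    km: km1
    substrate: X
    signal: true
    stoich: {X: -1, Xa: 1}
  - label: D             # deactivation into the refractory state
    rate_law: mass_action
    k: k2a
    substrate: Xa
    stoich: {Xa: -1, Y: 1}
  - label: R             # cycle reaction: recycle Y -> X
    rate_law: michaelis_menten
    k: k3
    km: km3
    substrate: Y
    stoich: {Y: -1, X: 1}
reference_params:
  k1: 50.0               # reconstructed, amount/min at s = 1
  km1: 100.0             # reconstructed, amount
  k2a: 0.05              # reconstructed, 1/min
  k3: 30.0               # reconstructed, amount/min (Vmax of R)
  km3: 100.0             # reconstructed, amount
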