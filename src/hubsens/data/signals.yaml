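# Ten input signal patterns S1-S10: combinations of "fast" and "slow"
# initiation and decay phases on the 0-300 min horizon.
#
# Functional template (form: rise_decay):
#   s(t) = 1 - exp(-kon * t)                         for t <= t_switch
#   s(t) = s(t_switch) * exp(-koff * (t - t_switch)) for t >  t_switch
# koff = 0 marks a sustained stimulus (no decay phase).
#
# Provenance: the published pattern set defines ten fast/slow
# initiation-by-decay combinations; the exact published equations and rate
# constants are not transcribable from the available material, so the values
# below are RECONSTRUCTED to realise the qualitative combinations: "fast"
# initiation kon = 0.5 /min (tau = 2 min), "slow" kon = 0.02 /min
# (tau = 50 min); "fast" decay koff = 0.2 /min, "slow" koff = 0.01 /min;
# switch times span short pulses to late-decaying stimuli.
patterns:
  - {id: S1,  form: rise_decay, kon: 0.5,  koff: 0.0,  t_switch: 300.0}  # fast init, sustained
  - {id: S2,  form: rise_decay, kon: 0.02, koff: 0.0,  t_switch: 300.0}  # slow init, sustained
  - {id: S3,  form: rise_decay, kon: 0.5,  koff: 0.2,  t_switch: 60.0}   # fast init, fast decay
  - {id: S4,  form: rise_decay, kon: 0.5,  koff: 0.01, t_switch: 60.0}   # fast init, slow decay
  - {id: S5,  form: rise_decay, kon: 0.02, koff: 0.2,  t_switch: 150.0}  # slow init, fast decay
  - {id: S6,  form: rise_decay, kon: 0.02, koff: 0.01, t_switch: 150.0}  # slow init, slow decay
  - {id: S7,  form: rise_decay, kon: 0.5,  koff: 0.2,  t_switch: 15.0}   # short pulse, fast decay
  - {id: S8,  form: rise_decay, kon: 0.5,  koff: 0.01, t_switch: 15.0}   # short pulse, slow decay
  - {id: S9,  form: rise_decay, kon: 0.02, koff: 0.2,  t_switch: 60.0}   # slow init, fast decay, early switch
  - {id: S10, form: rise_decay, kon: 0.02, koff: 0.01, t_switch: 60.0}   # slow init, slow decay, early switch
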