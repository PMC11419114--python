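# Default semi-Markov kinetics for the synthetic behavior generator.
#
# `base` gives the per-period jump distribution shared by both groups
# (baseline behavior: mostly rearing, food-cup and port visits, little
# freezing or locomotion). `delta` gives the group-specific, zero-sum
# perturbation applied during cue / post / shock periods; the effect-size
# setting scales delta (none = 0, moderate = 1, strong = 1.75), after which
# distributions are clipped at zero and renormalized. Dwell means are in
# frames (200 ms each); freeze dwell >= 3 frames honors the >= 600 ms
# scoring definition of a freezing bout.
dwell:
  freeze: 4.0
  stretch: 2.0
  rear: 3.0
  light_rear: 3.0
  scale: 3.0
  light_scale: 3.0
  jump: 1.5
  locomote: 2.0
  backpedal: 1.5
  cup: 3.0
  port: 3.0
  groom: 3.0
  background: 2.0
base:
  baseline: &base_dist
    freeze: 0.02
    stretch: 0.02
    rear: 0.18
    light_rear: 0.03
    scale: 0.05
    light_scale: 0.02
    jump: 0.01
    locomote: 0.05
    backpedal: 0.01
    cup: 0.22
    port: 0.20
    groom: 0.05
    background: 0.14
  cue: *base_dist
  post: *base_dist
  shock: *base_dist
delta:
  paired:
    cue:
      freeze: 0.10
      locomote: 0.08
      cup: -0.08
      port: -0.05
      rear: -0.05
    post:
      locomote: 0.10
      backpedal: 0.04
      jump: 0.03
      freeze: 0.03
      cup: -0.08
      port: -0.06
      rear: -0.06
    shock:
      locomote: 0.25
      jump: 0.19
      backpedal: 0.19
      freeze: 0.03
      background: 0.01
      cup: -0.20
      port: -0.18
      rear: -0.16
      groom: -0.05
      scale: -0.04
      stretch: -0.02
      light_rear: -0.02
  unpaired:
    # unpaired rats do not fear the cue: reward seeking is preserved and the
    # divergence is light-directed rearing/scaling at the expense of plain
    # rearing and background
    cue:
      light_rear: 0.08
      light_scale: 0.06
      scale: 0.04
      rear: -0.09
      background: -0.05
      groom: -0.02
      port: -0.02
    post:
      light_rear: 0.06
      light_scale: 0.04
      scale: 0.04
      rear: -0.07
      background: -0.04
      groom: -0.015
      port: -0.015
    shock: {}
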