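# Example configuration for mhcc-sim.
# Any omitted key keeps its library default; `setting` applies the named
# preset (standard | heavy) before the remaining scenario overrides.

scenario:
  setting: heavy
  horizon_s: 14400.0        # 4-hour shift
  n_agents: 4
  base_rate_per_h: 10.0
  p_mobile: 0.6
  patience_desktop_s: 402.0 # device-segment mean waits anchoring patience
  patience_mobile_s: 266.0
  patience_scale: 4.0       # censoring correction: patience >> observed wait
  sigma_d: 250.0            # duration inaccuracy-error s.d. (seconds)
  sigma_q: 0.4              # feedback inaccuracy-error s.d. (Likert units)
  duration_floor_s: 60.0

predictors:
  duration: oracle          # oracle | naive (naive = population average)
  quality: oracle
  patience: oracle
  remaining: oracle
  k_min: 3.0                # "chat ends within k minutes" horizon

mcts:
  n_rollouts: 300
  uct_c: 1.4142135623730951
  rollout_policy: cmt
  horizon_s: null           # null = plan to the end of the shift
  prune_dominated: true
  null_margin: 0.002
  match_margin: 0.005
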