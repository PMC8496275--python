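# Example neutrality-test scenario configuration.
#
# Each scenario simulates a null distribution of the observed statistic
# under one demographic model, with independent uniform priors on theta
# (per site) and on every demographic parameter.  Times are in coalescent
# units of 2*N0 generations; sizes are relative to the present size N0.
#
# The theta prior below (0.006-0.009 per site) is a typical range for an
# African D. melanogaster X-linked locus; the growth and bottleneck
# parameters are illustrative values in the range inferred for African
# populations and should be replaced by the user's own estimates.
scenarios:
  - name: standard_neutral
    model: equilibrium
    n: 20
    L: 1500
    R: 152.0
    replicates: 10000
    priors:
      theta_per_site: [0.006, 0.009]
  - name: exponential_growth
    model: exponential_growth
    n: 20
    L: 1500
    R: 152.0
    replicates: 10000
    priors:
      theta_per_site: [0.006, 0.009]
      growth_rate: [20.0, 60.0]
  - name: three_epoch_bottleneck
    model: three_epoch_bottleneck
    n: 20
    L: 1500
    R: 152.0
    replicates: 10000
    priors:
      theta_per_site: [0.006, 0.009]
      t1: [0.01, 0.05]     # time the bottleneck ended (backward)
      s1: [0.02, 0.2]      # relative size during the bottleneck
      t2: [0.05, 0.2]      # time the bottleneck began
      s2: [0.5, 1.5]       # ancestral relative size
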