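# Reference model configuration for the Kerman free-roaming dog study area.
params:
  Q: 1.0        # litters per female per year
  Np: 2.3       # pups per litter (mean of the Uniform(1, 3.6) prior)
  M: 0.23       # finite annual mortality
  fm: 0.3125    # female proportion parameter ("F/M")
  Du1: 1.0      # years from puppy/young to adult
distributions:
  Q: {normal: [1.0, 0.01]}    # mean, standard deviation
  Np: {uniform: [1.0, 3.6]}
  M: {normal: [0.23, 0.01]}
initial:
  puppy_young: 1547
  adult: 5234
K: [16592, 24200, 55000]
spay_rates: [0.0, 0.1, 0.3, 0.5, 0.6, 0.7]
horizons: [5, 10]
dt: 1.0
schedule: constant
monte_carlo:
  n: 10000
  seed: 42
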