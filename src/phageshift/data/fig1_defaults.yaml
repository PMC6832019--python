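# Bistable reference parameter set (two bacteria, one phage, one nutrient).
# Growth: lambda1 > lambda2; susceptibility: lambda1/eta1 < lambda2/eta2;
# phage stoichiometry: Y2*beta2 >> Y1*beta1 -> bistable window 0.2267 < phi < 0.7.
params:
  lambda1: 1.0
  lambda2: 0.8
  Y1: 1.0
  Y2: 1.0
  eta1: 0.2
  eta2: 0.15
  beta1: 2.0
  beta2: 40.0
  deltaC: 0.2
  deltaB: 0.2
  deltaP: 0.2
  phi: 0.66
seed: 0
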