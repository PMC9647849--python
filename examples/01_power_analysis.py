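"""Sample-size analysis for the TMT study design.

Solves for the per-group n at which a two-sided two-sample t-test detects
a 1.5-fold protein change (delta = log2 1.5 = 0.585) given a residual SD
of 0.208 on the log2 scale, at significance 1e-4 and power 0.8.
"""

import math

from tmtde import PowerSpec, effect_size, sample_size

spec = PowerSpec(alpha=1e-4, power=0.8, sigma=0.208, delta=math.log2(1.5))
res = sample_size(spec)

print(f"Cohen's d           : {effect_size(spec.delta, spec.sigma):.4f}")
print(f"n per group         : {res.n:.2f}  (round up to {res.n_ceil})")
print(f"power at solution   : {res.achieved_power:.6f}")
# n ~ 9.4 means 10 subjects per group suffice; a 15-per-group design has
# headroom for dropout and for proteins noisier than the planning sigma.
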