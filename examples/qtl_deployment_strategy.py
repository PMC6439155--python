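"""Assess a QTL's worth and pick a deployment strategy.

A salinity-tolerance QTL explains 20% of the variance of leaf sodium
content — a proxy correlated 0.65 with the visual injury the breeder
actually selects on — and is absent from the elite program.
"""

from masplan import (
    absolute_effect_from_pve,
    class_mean_effect,
    deployment_strategy,
    indirect_selection_attenuation,
)

attenuated = indirect_selection_attenuation(0.20, 0.65)
print(f"Expected improvement on the target trait: {attenuated:.0%} "
      "(PVE on the proxy x proxy-target correlation)")

effect = absolute_effect_from_pve(0.20, 10.0)
print(f"Absolute-effect proxy at population variance 10: {effect} units^2")

diff = class_mean_effect([6.1, 5.8, 6.4], [4.0, 4.3, 3.9])
print(f"Genotypic class mean difference: {diff:.2f} trait units")

for freq, effect_pct in [(0.01, 45), (0.5, 45), (0.9, 45), (0.9, 10)]:
    strategies = deployment_strategy(freq, effect_pct)
    print(f"frequency {freq:.0%}, effect {effect_pct}% -> "
          + "; ".join(strategies))
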