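"""Inspect one BME posterior density and the kriging-reduction property.

Builds the max-entropy (Gaussian) prior over a target, its hard neighbors and
soft neighbors, conditions on the data, and prints the posterior summaries —
then shows that dropping the soft data recovers simple kriging exactly.
"""

import numpy as np

import soilbme as sb

world = sb.WorldConfig()
temp, flux = sb.simulate_world(world, seed=7)
pts = sb.sample_scheme(world.flux_grid, 49)
hard = sb.hard_samples_from_field(flux, pts)
temps_at_hard = [temp.value_at(x, y) for x, y in pts]
fit = sb.fit_arrhenius(temps_at_hard, hard.values)
soft = sb.make_soft_data(fit, temp, exclude=pts)

model = sb.fit_variogram_model(sb.empirical_variogram(hard, 5.0), "gaussian")
gk = sb.GeneralKnowledge(float(np.mean(hard.values)), model)

target = np.array([[12.0, 23.0]])
est, sd = sb.bme_points(hard, soft, gk, target)
est0, sd0 = sb.bme_points(hard, [], gk, target, n_soft_neighbors=0)
i = np.argmin(np.sum((temp.spec.node_coordinates() - target[0]) ** 2, axis=1))
truth = flux.flat_values()[i]

print(f"target ({target[0][0]:.1f}, {target[0][1]:.1f}), simulated truth {truth:.3f}")
print(f"BME with soft data:    estimate {est[0]:.3f}, posterior SD {sd[0]:.4f}")
print(f"BME without soft data: estimate {est0[0]:.3f}, posterior SD {sd0[0]:.4f}")
print(
    "The no-soft posterior is exactly the Gaussian conditional given the hard "
    "data (simple kriging) — kriging is the special case of the entropy-based "
    "framework with no uncertain knowledge.  Adding the temperature-derived "
    "densities shifts the estimate toward what the local temperature implies "
    "and tightens the posterior."
)
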