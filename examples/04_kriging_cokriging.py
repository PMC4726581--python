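"""Ordinary kriging and cokriging of the flux field at unsampled locations.

Fits the plot's variogram structures, then estimates flux at a few targets
with OK (flux data only) and with Co-OK (temperature as a secondary,
cross-correlated attribute).
"""

import numpy as np

import soilbme as sb
from soilbme.validation import ComparisonConfig, fit_plot_models, _temperature_samples

world = sb.WorldConfig()
temp, flux = sb.simulate_world(world, seed=7)
hard = sb.hard_samples_from_field(flux, sb.sample_scheme(world.flux_grid, 49))

flux_model, coreg = fit_plot_models(hard, temp, ComparisonConfig())
targets = [[10.0, 10.0], [17.5, 22.5], [30.0, 5.0]]

ok = sb.ordinary_kriging(hard, flux_model, targets, n_neighbors=16)
cok = sb.cokriging(hard, _temperature_samples(temp, 200), coreg, targets, 16, 16)

print("target          truth    OK est (var)      Co-OK est")
for t, ro, rc in zip(targets, ok, cok):
    # nearest dense node carries the simulated truth
    i = np.argmin(np.sum((temp.spec.node_coordinates() - t) ** 2, axis=1))
    truth = flux.flat_values()[i]
    print(
        f"({t[0]:5.1f},{t[1]:5.1f}) {truth:7.2f} {ro.estimate:8.2f} "
        f"({ro.kriging_variance:.3f}) {rc.estimate:10.2f}"
    )
    assert abs(ro.weights.sum() - 1) < 1e-10  # unbiasedness constraint

print(
    "OK weights sum to 1 (unbiasedness); Co-OK adds temperature data with "
    "secondary weights summing to 0, typically nudging estimates toward what "
    "the local temperatures imply."
)
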