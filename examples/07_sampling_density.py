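"""Shrinking-design experiment: how many flux samples does each method need?

For a few replicate plots, estimates the whole field from nested designs of
9 and 37 sampling points with OK (hard data only) and BME (hard data + dense
temperature soft data), scoring against the simulated truth at the
non-sampled dense-grid nodes.  A full run uses 30 seeds and schemes
(9, 21, 37, 49); this narrative run keeps 3 seeds for speed.
"""

import warnings

import soilbme as sb

warnings.simplefilter("ignore")

table = sb.sampling_density_experiment(schemes=(9, 37), seeds=range(3))
print(sb.summarize_experiment(table).to_string(index=False))
print(
    "BME's mean RMSE sits below OK's at the same design size: the dense "
    "temperature soft data supply information the sparse flux samples lack, "
    "which is most valuable when very few flux points are available."
)
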