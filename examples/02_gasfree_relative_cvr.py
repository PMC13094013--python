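"""Gas-free relative CVR from intermittent breath modulation.

No CO2 inhalation: brief paced-breathing epochs modulate EtCO2, and the
regressor is the whole-brain mean BOLD signal, detrended and low-pass
filtered at 0.1164 Hz. Each voxel's percent coefficient is normalized by the
whole-brain mean, giving a relative map (r.u., mask mean 1). ChP voxels come
out negative at an elasticity-sensitive echo time.
"""

import numpy as np

import chp_elastic as ce

acq = ce.AcquisitionParams(tr=1500.0, te_list=(60.0,), flip_angle=52.0, n_volumes=270)
trace = ce.simulate_etco2_breathmod(duration=acq.scan_duration + 20, seed=1)
spec = ce.default_phantom_spec(seed=1)
series, truth = ce.build_phantom(spec, trace, acq)

result = ce.run_subject(series, trace=None)  # gas-free path: no capnograph needed
rel = result.maps[0]

chp = truth.mask("chp")
gray = truth.mask("gray")
print(f"map units                  : {rel.units}")
print(f"whole-brain mean (by def.) : {rel.values[rel.mask].mean():.3f}")
print(f"gray-matter relative CVR   : {np.median(rel.values[gray]):+.2f} r.u.")
print(f"ChP relative CVR (mean)    : {rel.values[chp].mean():+.2f} r.u.")
print()
print("Relative units express each voxel's response as a multiple of the brain")
print("average; the ChP strip sits below zero because its partial-volume")
print("mechanism opposes the global BOLD response.")
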