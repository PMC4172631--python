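"""The conditional-variance contract of the dose-reduction simulator.

At a fixed attenuation the detector signal at dose a*mAs has mean a*lambda
and variance a*lambda + sigma_e^2 (Poisson photons + electronic noise).  The
simulator must hit both moments when fed a *noisy* high-dose scan — without
assuming the input is noiseless.  This script checks that by Monte Carlo on
10^5 detector bins, and repeats from a doubled source dose to show the
result does not depend on the source noise level.
"""

import numpy as np

from lodosim.ct_forward import (
    CalibrationModel,
    ElectronicNoisePool,
    Geometry,
    LineIntegralSinogram,
    acquire_counts,
)
from lodosim.lowdose_sim import DoseReductionPlan, simulate_low_dose

n = 100_000
geom = Geometry(n_angles=1, n_bins=n, bin_spacing_mm=1e9 / n)
flat = LineIntegralSinogram(p=np.zeros((1, n)), geometry=geom)
pool = ElectronicNoisePool.synthetic(seed=0, sigma_e=20.0)
calib = CalibrationModel(n0_per_mas=100.0, electronic_pool=pool)  # lambda = 1e4 at 100 mAs

direct = acquire_counts(flat, 10.0, calib, rng_seed=3)
print("target: 10 mAs, lambda = 1000 counts, sigma_e = 20 counts")
print(f"theory          : mean 1000.0   variance {1000 + 400:.0f}")
print(f"direct 10 mAs   : mean {direct.counts.mean():6.1f}   variance {direct.counts.var():6.0f}")
for source in (100.0, 200.0):
    x = acquire_counts(flat, source, calib, rng_seed=int(source))
    y = simulate_low_dose(x, DoseReductionPlan(source, 10.0, rng_seed=int(source) + 1))
    print(
        f"simulated {source:3.0f}->10: mean {y.counts.mean():6.1f}   variance {y.counts.var():6.0f}"
    )
print("\nBoth simulated rows match the direct acquisition within Monte-Carlo")
print("error, from either source dose: the variance already present in the")
print("input is accounted for exactly, never double-counted.")
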