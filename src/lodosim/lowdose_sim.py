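"""Dose reduction in the count domain via the conditional-variance identity.

Given a high-dose count sinogram X acquired at ``mas_source`` the simulator
produces Y at ``mas_target = a * mas_source`` (0 < a <= 1) with the first and
second moments of a genuine acquisition at the target dose:

    E[Y] = a * lambda_0           Var(Y) = a * lambda_0 + sigma_e^2

where lambda_0 is the source photon mean and sigma_e the electronic-noise
standard deviation.  Crucially the construction conditions on the *noisy*
input X — by the law of total variance the variance X already carries is
scaled by a^2 and only the missing variance is injected, so the result does
not depend on the noise level of the source scan and no "noiseless input"
approximation is made.  Per bin:

    Y = a*X + sqrt(a*(1-a)*max(X, 0)) * g + sqrt(1 - a^2) * e

with g a zero-mean unit-variance photonic increment and e resampled from the
electronic-noise pool.  The sqrt(1-a^2) coefficient makes the total
electronic variance exactly sigma_e^2 after adding to the a^2-scaled
electronic noise already inside X.  For low-count bins (X below a
configurable threshold) the Gaussian increment is replaced by binomial
thinning of the counts, which realizes the same conditional moments without
assuming a normal photon distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ct_forward import CalibrationModel, CountSinogram, ElectronicNoisePool

#: below this many counts the Gaussian photonic increment gives way to
#: binomial thinning (Gaussian approximation is adequate for lambda >~ 20)
DEFAULT_THINNING_THRESHOLD = 20.0


@dataclass
class DoseReductionPlan:
    """Target of one dose-reduction run: source/target mAs, pool, seed."""

    mas_source: float
    mas_target: float
    electronic_pool: ElectronicNoisePool | None = None
    rng_seed: int = 0
    thinning_threshold: float = DEFAULT_THINNING_THRESHOLD

    def __post_init__(self) -> None:
        if self.mas_source <= 0 or self.mas_target <= 0:
            raise ValueError("mAs values must be positive")
        if not (0 < self.a <= 1):
            raise ValueError("dose fraction must satisfy 0 < a <= 1 (cannot simulate a higher dose)")

    @property
    def a(self) -> float:
        """Dose fraction mas_target / mas_source."""
        return self.mas_target / self.mas_source


def draw_electronic_noise(pool: ElectronicNoisePool, n: int, rng_seed: int = 0) -> np.ndarray:
    """Resample ``n`` electronic-noise values with replacement from the pool."""
    if pool is None or pool.samples.size == 0:
        raise ValueError("electronic pool is empty")
    if n == 0:
        return np.empty(0)
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    return rng.choice(pool.samples, size=n, replace=True)


def simulate_low_dose(x: CountSinogram, plan: DoseReductionPlan) -> CountSinogram:
    """Transform a high-dose count sinogram into one at a lower dose.

    The plan's pool must describe the same detector as the acquisition's
    calibration (identical sigma_e within 1%), otherwise the injected
    electronic variance would not complete a^2 * sigma_e^2 to sigma_e^2.

    Seed stream order: child 0 drives the photonic increment (both the
    Gaussian draw and the binomial thinning), child 1 the electronic
    resampling.  ``a = 1`` returns the input counts bit-exactly.
    """
    if not np.isclose(plan.mas_source, x.mas):
        raise ValueError(f"plan source dose {plan.mas_source} mAs does not match sinogram ({x.mas} mAs)")
    pool = plan.electronic_pool if plan.electronic_pool is not None else x.calib.electronic_pool
    calib_pool = x.calib.electronic_pool
    if abs(pool.sigma_e - calib_pool.sigma_e) > 0.01 * calib_pool.sigma_e:
        raise ValueError("electronic pool does not match the acquisition calibration")

    a = plan.a
    if a == 1.0:
        counts = x.counts.copy()
    else:
        photon_ss, elec_ss = np.random.SeedSequence(plan.rng_seed).spawn(2)
        photon_rng = np.random.default_rng(photon_ss)
        elec_rng = np.random.default_rng(elec_ss)

        X = x.counts
        Xpos = np.maximum(X, 0.0)

        gaussian = a * X + np.sqrt(a * (1.0 - a) * Xpos) * photon_rng.standard_normal(X.shape)
        # low-flux branch: binomial thinning of the clamped integer counts; the
        # clipped remainder (electronic dips below zero, rounding) is restored
        # scaled by a so that E[Y_photonic | X] = a * X exactly in both branches
        Xint = np.rint(Xpos).astype(np.int64)
        thinned = photon_rng.binomial(Xint, a).astype(float) - a * (Xint - X)
        photonic = np.where(X >= plan.thinning_threshold, gaussian, thinned)

        e = elec_rng.choice(pool.samples, size=X.shape, replace=True)
        counts = photonic + np.sqrt(1.0 - a * a) * e

    return CountSinogram(
        counts=counts,
        mas=plan.mas_target,
        calib=x.calib,
        geometry=x.geometry,
        provenance="simulated",
    )


def simulate_series(
    x: CountSinogram,
    targets: list[float],
    calib: CalibrationModel | None = None,
    seed: int = 0,
) -> list[CountSinogram]:
    """Simulate one scan per target mAs, each from an independent seed stream.

    Mirrors the study design of a single high-dose parent scan feeding the
    whole dose ladder; all targets must be strictly below the source dose.
    """
    for t in targets:
        if t >= x.mas:
            raise ValueError(f"target {t} mAs is not below the source dose {x.mas} mAs")
    if not targets:
        return []
    pool = (calib or x.calib).electronic_pool
    streams = np.random.SeedSequence(seed).spawn(len(targets))
    out = []
    for t, ss in zip(targets, streams):
        plan = DoseReductionPlan(
            mas_source=x.mas,
            mas_target=t,
            electronic_pool=pool,
            rng_seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        out.append(simulate_low_dose(x, plan))
    return out
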