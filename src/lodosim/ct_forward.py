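"""Parallel-beam forward model producing count-domain sinograms.

The acquisition chain is Beer-Lambert: a ray with line integral p (unitless,
mu in 1/mm integrated over mm) transmits a mean photon signal
``lambda = n0_per_mas * mAs * exp(-p)`` counts per detector bin.  Detected
counts are a Poisson draw around that mean plus one additive electronic-noise
sample per bin.  Electronic noise is signal-independent, zero-mean and — as
on real energy-integrating detectors — non-Gaussian, so it is represented by
a pool of samples (synthetic by default, loadable from measured data) rather
than a parametric distribution.

Geometry is desk-scale 2D parallel-beam: rays ``x cos(theta) + y sin(theta) = t``
over theta in [0, 180) with detector offsets t centered on the rotation axis.
Projection uses a Joseph-style interpolating ray driver (bilinear sampling at
half-pixel steps).

Randomness: every stochastic operation takes one integer seed which fans out
to independent child streams via ``numpy.random.SeedSequence.spawn``; stream
order is documented per operation (acquire_counts: photon draw first, then
electronic draw).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.ndimage import map_coordinates

from .phantom import MU_WATER_MM, PhantomImage

#: counts clipped to this floor before the log transform (bins with <= 0 counts)
LOG_CLIP_EPSILON = 0.1

#: Poisson expectations above this are rejected as unphysical/overflowing
MAX_EXPECTED_COUNTS = 1e12


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam sampling: projection angles over 180 deg and detector bins."""

    n_angles: int = 180
    n_bins: int = 384
    bin_spacing_mm: float = 1.4

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.n_bins < 1:
            raise ValueError("n_angles and n_bins must be >= 1")
        if self.bin_spacing_mm <= 0:
            raise ValueError("bin_spacing_mm must be positive")

    @classmethod
    def for_fov(cls, matrix: int, fov_mm: float, n_angles: int = 180) -> "Geometry":
        """Default detector: 1.5x the matrix in bins, spanning the FOV diagonal."""
        n_bins = int(round(1.5 * matrix))
        return cls(n_angles=n_angles, n_bins=n_bins, bin_spacing_mm=fov_mm * np.sqrt(2.0) / n_bins)

    @property
    def span_mm(self) -> float:
        return self.n_bins * self.bin_spacing_mm

    @property
    def angles_rad(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def bin_centers_mm(self) -> np.ndarray:
        return (np.arange(self.n_bins) - (self.n_bins - 1) / 2.0) * self.bin_spacing_mm


@dataclass
class ElectronicNoisePool:
    """Zero-mean additive detector noise represented by real-valued samples.

    ``sigma_e`` is the pool's standard deviation in counts.  The default
    synthetic pool is a right-skewed Gaussian/shifted-exponential mixture,
    deliberately non-Gaussian; measured scanner samples can be loaded from a
    one-column CSV or an HDF5 dataset instead.
    """

    samples: np.ndarray
    sigma_e: float = field(init=False)

    MIN_SIZE = 10_000

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < self.MIN_SIZE:
            raise ValueError(f"electronic pool needs >= {self.MIN_SIZE} samples")
        self.sigma_e = float(self.samples.std())
        if self.sigma_e <= 0:
            raise ValueError("electronic pool has zero variance")
        if abs(self.samples.mean()) >= 0.01 * self.sigma_e:
            raise ValueError("electronic pool is not zero-mean")

    @classmethod
    def synthetic(cls, seed: int = 0, sigma_e: float = 15.0, size: int = 100_000) -> "ElectronicNoisePool":
        """Non-Gaussian mixture pool: 0.9 N(0, s) + 0.1 (Exp(2s) - 2s), rescaled
        to mean exactly 0 and standard deviation exactly ``sigma_e`` counts."""
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        s = sigma_e / np.sqrt(1.3)  # mixture variance 0.9 s^2 + 0.1 (2s)^2 = 1.3 s^2
        comp = rng.random(size) < 0.9
        raw = np.where(comp, rng.normal(0.0, s, size), rng.exponential(2.0 * s, size) - 2.0 * s)
        raw = raw - raw.mean()
        return cls(samples=raw * (sigma_e / raw.std()))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ElectronicNoisePool":
        return cls(samples=np.loadtxt(path, ndmin=1))

    @classmethod
    def from_hdf5(cls, path: str | Path, dataset: str = "electronic_pool") -> "ElectronicNoisePool":
        with h5py.File(path, "r") as f:
            return cls(samples=f[dataset][()])

    def to_hdf5(self, path: str | Path, dataset: str = "electronic_pool") -> None:
        with h5py.File(path, "a") as f:
            if dataset in f:
                del f[dataset]
            f.create_dataset(dataset, data=self.samples)


@dataclass
class CalibrationModel:
    """Scanner calibration: incident counts per bin per mAs and the noise pool.

    At tube setting mAs the unattenuated flux per bin is ``n0_per_mas * mAs``;
    the default 2000 counts/mAs gives 2e5 counts at the 100 mAs source dose.
    Tube voltage is a fixed 100 kV label (monoenergetic effective beam).
    """

    n0_per_mas: float = 2000.0
    electronic_pool: ElectronicNoisePool | None = None
    kv: int = 100

    def __post_init__(self) -> None:
        if self.n0_per_mas <= 0:
            raise ValueError("n0_per_mas must be positive")
        if self.electronic_pool is None:
            self.electronic_pool = ElectronicNoisePool.synthetic()

    def flux(self, mas: float) -> float:
        return self.n0_per_mas * mas


@dataclass
class LineIntegralSinogram:
    """Log-domain attenuation line integrals p = -ln(I/I0), angle x bin."""

    p: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.geometry.n_angles, self.geometry.n_bins):
            raise ValueError("sinogram shape does not match geometry")
        if not np.all(np.isfinite(self.p)):
            raise ValueError("line integrals must be finite")


@dataclass
class CountSinogram:
    """Detector counts per (angle, bin) with acquisition metadata."""

    counts: np.ndarray
    mas: float
    calib: CalibrationModel
    geometry: Geometry
    provenance: str = "acquired"  # {"acquired", "simulated"}

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.geometry.n_angles, self.geometry.n_bins):
            raise ValueError("counts shape does not match geometry")
        if self.mas <= 0:
            raise ValueError("mas must be positive")
        if self.provenance not in ("acquired", "simulated"):
            raise ValueError("provenance must be 'acquired' or 'simulated'")

    @property
    def flux(self) -> float:
        return self.calib.flux(self.mas)


def radon_project(
    phantom: PhantomImage,
    geometry: Geometry,
    mu_water: float = MU_WATER_MM,
    step_fraction: float = 0.5,
) -> LineIntegralSinogram:
    """Forward-project the phantom's attenuation map along parallel rays.

    Each sinogram entry is the discretized line integral of mu (1/mm) sampled
    bilinearly at ``step_fraction`` of a pixel along the ray, times the step
    length in mm — hence unitless.  The detector span must cover the FOV
    diagonal so that no attenuating mass falls off the detector at any angle.
    """
    mu = phantom.mu_grid(mu_water)
    return project_mu(mu, phantom.pixel_size_mm, geometry, step_fraction=step_fraction)


def project_mu(
    mu: np.ndarray,
    pixel_size_mm: float,
    geometry: Geometry,
    step_fraction: float = 0.5,
) -> LineIntegralSinogram:
    mu = np.asarray(mu, dtype=float)
    if mu.ndim != 2:
        raise ValueError("mu grid must be 2D")
    if np.any(mu < 0):
        raise ValueError("mu grid must be nonnegative")
    n = mu.shape[0]
    fov = n * pixel_size_mm
    diag = fov * np.sqrt(2.0)
    if geometry.span_mm < diag - 1e-9:
        raise ValueError(
            f"detector span {geometry.span_mm:.1f} mm does not cover the FOV diagonal {diag:.1f} mm"
        )

    ds = step_fraction * pixel_size_mm
    n_steps = int(np.ceil(diag / ds)) + 1
    s = (np.arange(n_steps) - (n_steps - 1) / 2.0) * ds
    t = geometry.bin_centers_mm

    p = np.empty((geometry.n_angles, geometry.n_bins))
    half = fov / 2.0
    for k, theta in enumerate(geometry.angles_rad):
        ct, st = np.cos(theta), np.sin(theta)
        x = t[:, None] * ct - s[None, :] * st
        y = t[:, None] * st + s[None, :] * ct
        rows = (y + half) / pixel_size_mm - 0.5
        cols = (x + half) / pixel_size_mm - 0.5
        vals = map_coordinates(mu, [rows.ravel(), cols.ravel()], order=1, mode="constant", cval=0.0)
        p[k] = vals.reshape(geometry.n_bins, n_steps).sum(axis=1) * ds
    return LineIntegralSinogram(p=p, geometry=geometry)


def acquire_counts(
    p: LineIntegralSinogram,
    mas: float,
    calib: CalibrationModel,
    rng_seed: int = 0,
    noiseless: bool = False,
) -> CountSinogram:
    """Acquire a count sinogram at the given mAs.

    counts = Poisson(n0_per_mas * mAs * exp(-p)) + one electronic sample per
    bin; with ``noiseless`` the expectation is returned exactly (electronic
    noise is zero-mean, so it contributes nothing to the expectation).

    Seed stream order: child 0 drives the Poisson draw, child 1 the
    electronic-pool resampling.
    """
    if mas <= 0:
        raise ValueError("mas must be positive")
    lam = calib.flux(mas) * np.exp(-p.p)
    if not np.all(np.isfinite(lam)) or lam.max() > MAX_EXPECTED_COUNTS:
        raise ValueError("expected counts overflow")
    if noiseless:
        counts = lam
    else:
        photon_ss, elec_ss = np.random.SeedSequence(rng_seed).spawn(2)
        photon = np.random.default_rng(photon_ss).poisson(lam).astype(float)
        pool = calib.electronic_pool
        elec = np.random.default_rng(elec_ss).choice(pool.samples, size=lam.shape, replace=True)
        counts = photon + elec
    return CountSinogram(counts=counts, mas=mas, calib=calib, geometry=p.geometry, provenance="acquired")


def counts_to_line_integrals(c: CountSinogram) -> LineIntegralSinogram:
    """Log transform back to the line-integral domain.

    p_hat = -ln(max(counts, eps) / flux) with eps = 0.1 counts, so bins that
    measured zero or negative counts map to a large but finite attenuation.
    """
    if c.calib is None:
        raise ValueError("count sinogram has no calibration attached")
    flux = c.flux
    p_hat = -np.log(np.maximum(c.counts, LOG_CLIP_EPSILON) / flux)
    return LineIntegralSinogram(p=p_hat, geometry=c.geometry)


# ---- HDF5 persistence ----------------------------------------------------

def write_sinogram_h5(path: str | Path, sino: CountSinogram | LineIntegralSinogram) -> None:
    with h5py.File(path, "w") as f:
        g = sino.geometry
        f.attrs["n_angles"] = g.n_angles
        f.attrs["n_bins"] = g.n_bins
        f.attrs["bin_spacing_mm"] = g.bin_spacing_mm
        if isinstance(sino, CountSinogram):
            f.create_dataset("counts", data=sino.counts)
            f.attrs["mas"] = sino.mas
            f.attrs["n0_per_mas"] = sino.calib.n0_per_mas
            f.attrs["sigma_e"] = sino.calib.electronic_pool.sigma_e
            f.attrs["provenance"] = sino.provenance
            f.create_dataset("electronic_pool", data=sino.calib.electronic_pool.samples)
        else:
            f.create_dataset("p", data=sino.p)


def read_sinogram_h5(path: str | Path) -> CountSinogram | LineIntegralSinogram:
    with h5py.File(path, "r") as f:
        geom = Geometry(
            n_angles=int(f.attrs["n_angles"]),
            n_bins=int(f.attrs["n_bins"]),
            bin_spacing_mm=float(f.attrs["bin_spacing_mm"]),
        )
        if "counts" in f:
            calib = CalibrationModel(
                n0_per_mas=float(f.attrs["n0_per_mas"]),
                electronic_pool=ElectronicNoisePool(samples=f["electronic_pool"][()]),
            )
            return CountSinogram(
                counts=f["counts"][()],
                mas=float(f.attrs["mas"]),
                calib=calib,
                geometry=geom,
                provenance=str(f.attrs["provenance"]),
            )
        return LineIntegralSinogram(p=f["p"][()], geometry=geom)
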