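"""Validation statistics for simulated-vs-original CT comparisons.

Implements the quantitative end of the validation protocol: ROI mean/noise
measurements (noise = sample standard deviation of a 50 mm^2 ROI), percent
discrepancies between simulated and original arms, Student-t confidence
intervals on paired differences, two-tailed paired t-tests, observer-study
contingency analytics (correct/incorrect detection counts, Cohen's kappa,
exact binomial test against chance), and linear CTDI scaling with mAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .phantom import RoiSpec
from .recon import ReconImage


@dataclass
class RoiMeasurement:
    """Mean HU and HU noise of one ROI at one dose in one arm."""

    tissue_name: str
    dose_mas: float
    provenance: str  # {"original", "simulated"}
    mean_hu: float
    sd_hu: float
    slice_id: int = 0  # which slice realization the ROI was measured on

    def __post_init__(self) -> None:
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be nonnegative")


@dataclass
class DiscrepancyReport:
    """Per-(tissue, dose) discrepancy table for noise and HU plus summaries.

    ``cells`` is a DataFrame with columns tissue, dose_mas, orig_noise,
    sim_noise, orig_hu, sim_hu, noise_pct, hu_pct, noise_ci_low/high,
    hu_ci_low/high (CIs on the per-ROI paired differences, HU).  ``t_p`` maps
    (dose, quantity) to the paired t-test p-value over ROI pairs.
    """

    cells: pd.DataFrame
    mean_noise_pct: float
    range_noise_pct: tuple[float, float]
    mean_hu_pct: float
    range_hu_pct: tuple[float, float]
    t_p: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mean, (lo, hi), what in (
            (self.mean_noise_pct, self.range_noise_pct, "noise"),
            (self.mean_hu_pct, self.range_hu_pct, "HU"),
        ):
            if not np.isnan(mean) and not (lo - 1e-9 <= mean <= hi + 1e-9):
                raise ValueError(f"mean {what} discrepancy outside its own range")


@dataclass(frozen=True)
class ObserverTable:
    """2x2 confusion counts for one observer rating original vs simulated."""

    observer_id: str
    n_orig_rated_orig: int
    n_orig_rated_sim: int
    n_sim_rated_orig: int
    n_sim_rated_sim: int

    def __post_init__(self) -> None:
        for c in (
            self.n_orig_rated_orig,
            self.n_orig_rated_sim,
            self.n_sim_rated_orig,
            self.n_sim_rated_sim,
        ):
            if c < 0:
                raise ValueError("observer counts must be nonnegative")

    @property
    def total(self) -> int:
        return (
            self.n_orig_rated_orig
            + self.n_orig_rated_sim
            + self.n_sim_rated_orig
            + self.n_sim_rated_sim
        )


def roi_stats(image: ReconImage, roi: RoiSpec, slice_id: int = 0) -> RoiMeasurement:
    """Mean and sample (n-1) standard deviation of HU over the ROI mask."""
    mask = roi.mask(image.hu_grid.shape, image.pixel_size_mm)
    vals = image.hu_grid[mask]
    if vals.size == 0:
        raise ValueError("ROI mask is empty")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return RoiMeasurement(
        tissue_name=roi.tissue_name,
        dose_mas=image.source_mas,
        provenance=image.provenance,
        mean_hu=float(vals.mean()),
        sd_hu=sd,
        slice_id=slice_id,
    )


def percent_discrepancy(sim_value: float, orig_value: float) -> float:
    """100 * (sim - orig) / orig; undefined (rejected) for orig = 0."""
    if orig_value == 0:
        raise ValueError("relative discrepancy undefined for a zero reference value")
    return 100.0 * (sim_value - orig_value) / orig_value


def mean_difference_ci(
    paired: list[tuple[float, float]], level: float = 0.95
) -> tuple[float, float, float]:
    """Student-t confidence interval on paired (orig, sim) mean difference."""
    if len(paired) < 2:
        raise ValueError("need at least two pairs")
    d = np.array([s - o for o, s in paired])
    mean = float(d.mean())
    se = float(d.std(ddof=1)) / np.sqrt(len(d))
    if se == 0:
        return mean, mean, mean
    tq = stats.t.ppf(0.5 + level / 2.0, df=len(d) - 1)
    return mean, mean - tq * se, mean + tq * se


def paired_t_test(x: list[float], y: list[float]) -> tuple[float, float]:
    """Two-tailed paired Student t-test; returns (t, p). Zero-variance ties give t=0, p=1."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        return (0.0, 1.0) if np.allclose(d.mean(), 0.0) else (np.inf * np.sign(d.mean()), 0.0)
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def observer_summary(tables: list[ObserverTable]) -> dict:
    """Pooled detection counts and proportions over observers."""
    if not tables:
        raise ValueError("need at least one observer table")
    n_orig_correct = sum(t.n_orig_rated_orig for t in tables)
    n_sim_correct = sum(t.n_sim_rated_sim for t in tables)
    n_sim_rated_orig = sum(t.n_sim_rated_orig for t in tables)
    n_orig_rated_sim = sum(t.n_orig_rated_sim for t in tables)
    n_total = sum(t.total for t in tables)
    n_correct = n_orig_correct + n_sim_correct
    n_incorrect = n_sim_rated_orig + n_orig_rated_sim
    prop = (lambda k: k / n_total) if n_total else (lambda k: float("nan"))
    return {
        "n_total": n_total,
        "n_correct": n_correct,
        "n_incorrect": n_incorrect,
        "n_orig_correct": n_orig_correct,
        "n_sim_correct": n_sim_correct,
        "n_sim_rated_orig": n_sim_rated_orig,
        "n_orig_rated_sim": n_orig_rated_sim,
        "proportions": {
            "correct": prop(n_correct),
            "incorrect": prop(n_incorrect),
            "orig_correct": prop(n_orig_correct),
            "sim_correct": prop(n_sim_correct),
            "sim_rated_orig": prop(n_sim_rated_orig),
            "orig_rated_sim": prop(n_orig_rated_sim),
        },
    }


def cohen_kappa(ratings_a: list[int], ratings_b: list[int]) -> float:
    """Cohen's kappa between two raters; chance agreement from marginal products.

    The degenerate case where both raters are constant and identical
    (p_o = p_e = 1) returns 1 by convention.
    """
    a, b = np.asarray(ratings_a), np.asarray(ratings_b)
    if a.shape != b.shape:
        raise ValueError("rating vectors must have equal length")
    if a.size < 1:
        raise ValueError("need at least one rating")
    cats = np.union1d(a, b)
    p_e = sum((a == c).mean() * (b == c).mean() for c in cats)
    if np.isclose(p_e, 1.0):
        return 1.0 if np.all(a == b) else 0.0
    return float(cohen_kappa_score(a, b))


def chance_level_test(n_correct: int, n_total: int) -> float:
    """Exact two-sided binomial test of the correct-detection count against p = 0.5."""
    if not (0 <= n_correct <= n_total):
        raise ValueError("n_correct must lie in [0, n_total]")
    return float(stats.binomtest(n_correct, n_total, 0.5, alternative="two-sided").pvalue)


def ctdi_scale(ctdi_ref: float, mas_ref: float, mas_target: float) -> float:
    """CTDI (mGy) is linear in mAs at fixed tube voltage."""
    if ctdi_ref <= 0 or mas_ref <= 0 or mas_target <= 0:
        raise ValueError("CTDI scaling requires positive inputs")
    return ctdi_ref * mas_target / mas_ref


def build_discrepancy_report(
    measurements: list[RoiMeasurement],
    ci_level: float = 0.95,
) -> DiscrepancyReport:
    """Aggregate paired ROI measurements into the per-(tissue, dose) report.

    Measurements must come in matched original/simulated sets: for every
    (tissue, dose) the two arms contribute equally many ROIs measured at the
    same sites in the same order.  Cell discrepancies compare the ROI-averaged
    noise and mean HU; confidence intervals and the per-dose paired t-tests
    operate on the ROI-level pairs.
    """
    df = pd.DataFrame([m.__dict__ for m in measurements])
    rows = []
    t_p: dict = {}
    for (tissue, dose), grp in df.groupby(["tissue_name", "dose_mas"], sort=True):
        orig = grp[grp.provenance == "original"]
        sim = grp[grp.provenance == "simulated"]
        if len(orig) != len(sim) or len(orig) == 0:
            raise ValueError(f"unpaired measurements for ({tissue}, {dose})")
        on, sn = orig.sd_hu.to_numpy(), sim.sd_hu.to_numpy()
        oh, sh = orig.mean_hu.to_numpy(), sim.mean_hu.to_numpy()
        noise_ci = mean_difference_ci(list(zip(on, sn)), ci_level) if len(on) >= 2 else (np.nan,) * 3
        hu_ci = mean_difference_ci(list(zip(oh, sh)), ci_level) if len(oh) >= 2 else (np.nan,) * 3
        rows.append(
            {
                "tissue": tissue,
                "dose_mas": dose,
                "orig_noise": on.mean(),
                "sim_noise": sn.mean(),
                "orig_hu": oh.mean(),
                "sim_hu": sh.mean(),
                # relative CT-value discrepancy is unstable for low-|HU| tissues
                # (the reference is comparable to the measurement error); such
                # cells keep their absolute CI but are excluded from hu_pct.
                # Noise discrepancy is undefined when the reference noise is 0
                # (degenerate single-pixel ROIs on very coarse grids).
                "noise_pct": percent_discrepancy(sn.mean(), on.mean()) if on.mean() != 0 else np.nan,
                "hu_pct": percent_discrepancy(sh.mean(), oh.mean()) if abs(oh.mean()) >= 100.0 else np.nan,
                "noise_ci_low": noise_ci[1],
                "noise_ci_high": noise_ci[2],
                "hu_ci_low": hu_ci[1],
                "hu_ci_high": hu_ci[2],
            }
        )
    cells = pd.DataFrame(rows)

    # per-dose paired t-tests on tissue x slice mean values: averaging the ROIs
    # within a (tissue, slice) cell first gives well-behaved, independent pairs
    for dose, grp in df.groupby("dose_mas"):
        cells_ts = grp.groupby(["tissue_name", "slice_id", "provenance"])[["sd_hu", "mean_hu"]].mean()
        orig = cells_ts.xs("original", level="provenance")
        sim = cells_ts.xs("simulated", level="provenance")
        sim = sim.loc[orig.index]
        t_p[(float(dose), "noise")] = paired_t_test(orig.sd_hu.tolist(), sim.sd_hu.tolist())[1]
        t_p[(float(dose), "hu")] = paired_t_test(orig.mean_hu.tolist(), sim.mean_hu.tolist())[1]

    def summarize(col):
        vals = col.dropna().to_numpy()
        if vals.size == 0:
            return np.nan, (np.nan, np.nan)
        return float(vals.mean()), (float(vals.min()), float(vals.max()))

    mean_noise, range_noise = summarize(cells.noise_pct)
    mean_hu, range_hu = summarize(cells.hu_pct)
    return DiscrepancyReport(
        cells=cells,
        mean_noise_pct=mean_noise,
        range_noise_pct=range_noise,
        mean_hu_pct=mean_hu,
        range_hu_pct=range_hu,
        t_p=t_p,
    )
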