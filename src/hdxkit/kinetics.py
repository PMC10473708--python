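"""Plate-reader kinetics utilities.

Two small summarizations that accompany receptor-signaling work:

* apoplastic oxidative (ROS) burst time courses — leaf-disc luminescence
  recorded on a 1-min grid, averaged disc -> plant -> genotype, with the
  burst timing summarized as the time to half-maximal signal from a
  four-parameter logistic fit;
* fluorometric enzyme (GUS/4-MU) quantification — a linear standard
  curve converts fluorescence to product concentration, normalized to
  protein amount and incubation time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import AlignmentError, FitError, InputError

logger = logging.getLogger(__name__)


def average_discs(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average leaf-disc time courses: discs -> plant, plants -> genotype.

    ``df`` is long-format with columns ``disc_id, plant_id, genotype,
    time_min, value``.  Returns ``(plant_means, genotype_stats)``:
    pointwise per-plant means, and per-genotype pointwise mean with the
    SEM across plants (SD/sqrt(n); NaN when a genotype has one plant).

    Raises
    ------
    AlignmentError
        If discs do not share a common time grid.
    """
    required = {"disc_id", "plant_id", "genotype", "time_min", "value"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"missing columns: {sorted(missing)}")
    grids = df.groupby("disc_id")["time_min"].apply(lambda s: tuple(np.sort(s)))
    if grids.nunique() > 1:
        raise AlignmentError("leaf discs do not share a common time grid")
    plant = (
        df.groupby(["genotype", "plant_id", "time_min"], sort=True)["value"]
        .mean()
        .rename("plant_mean")
        .reset_index()
    )
    geno = (
        plant.groupby(["genotype", "time_min"], sort=True)["plant_mean"]
        .agg(
            mean="mean",
            sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
            n_plants="count",
        )
        .reset_index()
    )
    return plant, geno


def _logistic4(t, lower, upper, midpoint, slope):
    return lower + (upper - lower) / (1.0 + np.exp(-slope * (t - midpoint)))


@dataclass(frozen=True)
class BurstSummary:
    """Fitted burst timing for one luminescence series."""

    t_max: float
    t_half: float
    lower: float
    upper: float
    midpoint: float
    slope: float
    r_squared: float


def time_to_half_max(
    times: np.ndarray, values: np.ndarray, *, points_after_max: int = 5
) -> BurstSummary:
    """Time to half-maximal signal from a four-parameter logistic fit.

    The fit window runs from the first point through ``points_after_max``
    points past the argmax (truncated, with a log entry, when the maximum
    sits near the end of the recording).  For the logistic
    ``lower + (upper - lower) / (1 + exp(-slope (t - midpoint)))`` the
    half-maximum time is the midpoint itself, so ``t_half`` is the fitted
    midpoint; it is invariant to rescaling the signal and equivariant
    under time shifts.

    Raises
    ------
    FitError
        On non-convergence or a degenerate fit (upper <= lower, or a
        midpoint far beyond the observed maximum).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise InputError("times and values must be matching 1-D arrays")
    if len(t) < 8:
        raise InputError("need >= 8 points to fit the burst")
    if np.any(np.diff(t) <= 0):
        raise InputError("times must be strictly increasing")
    if not np.all(np.isfinite(y)):
        raise InputError("values must be finite")

    imax = int(np.argmax(y))
    stop = imax + points_after_max + 1
    if stop > len(t):
        logger.info(
            "burst maximum within %d points of the end; fit window truncated",
            points_after_max,
        )
        stop = len(t)
    tw, yw = t[:stop], y[:stop]
    if len(tw) < 4:
        raise FitError("fit window has fewer points than parameters")

    lo0, up0 = float(yw.min()), float(yw.max())
    amp = up0 - lo0
    if amp <= 0:
        raise FitError("flat series: no burst to fit")
    half = lo0 + amp / 2.0
    mid0 = float(tw[np.argmin(np.abs(yw - half))])
    slope0 = 4.0 / max(t[imax] - mid0, (t[1] - t[0]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _logistic4,
                tw,
                yw,
                p0=[lo0, up0, mid0, slope0],
                maxfev=20000,
            )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"logistic fit failed: {exc}") from exc
    lower, upper, midpoint, slope = (float(v) for v in popt)
    if upper <= lower:
        raise FitError(f"degenerate fit: upper {upper:.3g} <= lower {lower:.3g}")
    dt = float(np.median(np.diff(t)))
    if midpoint > t[imax] + points_after_max * dt or midpoint < t[0] - points_after_max * dt:
        raise FitError(f"fitted midpoint {midpoint:.3g} outside plausible window")
    resid = yw - _logistic4(tw, *popt)
    ss_tot = float(((yw - yw.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else np.nan
    return BurstSummary(
        t_max=float(t[imax]),
        t_half=midpoint,
        lower=lower,
        upper=upper,
        midpoint=midpoint,
        slope=slope,
        r_squared=r2,
    )


def burst_summaries(df: pd.DataFrame, *, points_after_max: int = 5) -> pd.DataFrame:
    """Per-disc half-max times, averaged per plant.

    Discs whose fit fails are excluded from the plant average with a log
    entry and reported with ``t_half = NaN`` in the per-disc listing.
    Returns a frame with one row per plant: ``genotype, plant_id,
    t_half_mean, n_discs, n_failed``.
    """
    rows = []
    for (geno, plant, disc), g in df.groupby(["genotype", "plant_id", "disc_id"]):
        g = g.sort_values("time_min")
        try:
            summ = time_to_half_max(
                g["time_min"].to_numpy(),
                g["value"].to_numpy(),
                points_after_max=points_after_max,
            )
            t_half = summ.t_half
        except (FitError, InputError) as exc:
            logger.warning("disc %s (plant %s): fit excluded: %s", disc, plant, exc)
            t_half = np.nan
        rows.append(
            {"genotype": geno, "plant_id": plant, "disc_id": disc, "t_half": t_half}
        )
    per_disc = pd.DataFrame(rows)
    per_plant = (
        per_disc.groupby(["genotype", "plant_id"])["t_half"]
        .agg(
            t_half_mean="mean",
            n_discs="size",
            n_failed=lambda x: int(x.isna().sum()),
        )
        .reset_index()
    )
    return per_plant


@dataclass(frozen=True)
class StandardCurve:
    """Linear fluorescence-vs-concentration calibration."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InputError("standard curve slope must be > 0")


def fit_standard_curve(concentrations, fluorescence) -> StandardCurve:
    """Ordinary least-squares line through the dilution series.

    Requires >= 3 points with non-zero concentration variance (the
    canonical series starts at 10 uM with 2-fold dilutions).
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(fluorescence, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("concentrations and fluorescence must match 1-D")
    if len(x) < 3:
        raise InputError("need >= 3 standard points")
    if np.ptp(x) == 0:
        raise InputError("zero variance in concentrations")
    fit = stats.linregress(x, y)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def gus_activity(
    fluorescence, curve: StandardCurve, protein_mg: float, minutes: float
):
    """Enzyme activity in uM product per mg protein per minute.

    Fluorescence is converted to concentration via the standard curve
    (``(F - intercept) / slope``) and normalized by protein amount and
    incubation time.  Readings below the curve intercept are floored at
    zero activity with a warning.  Accepts scalars or arrays.
    """
    if protein_mg <= 0:
        raise InputError("protein_mg must be > 0")
    if minutes <= 0:
        raise InputError("minutes must be > 0")
    f = np.asarray(fluorescence, dtype=float)
    conc = (f - curve.intercept) / curve.slope
    if np.any(conc < 0):
        logger.warning(
            "%d fluorescence reading(s) below the standard-curve intercept; "
            "activity floored at 0",
            int((conc < 0).sum()),
        )
        conc = np.clip(conc, 0.0, None)
    activity = conc / (protein_mg * minutes)
    if activity.ndim == 0:
        return float(activity)
    return activity
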