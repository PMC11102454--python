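"""Quantitative-microscopy blood-concentration pipeline.

Per well, the pixel intensities of each of (by default) nine images are
summed, a plate background (the mean summed intensity of blood-only
wells) is subtracted, and the corrected per-image sums are averaged.
Standards of known concentration define a linear standard curve
``intensity = slope · concentration + intercept`` which is inverted for
the experimental samples; the resulting per-animal concentration series
is fitted with a one-phase decay ``C(t) = C0·exp(-k·t)`` (plateau
constrained to zero) to report the circulation half-life t½ = ln2/k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .synth import STANDARD_CONCENTRATIONS  # noqa: F401  (shared plate dialect)


class ExtrapolationWarning(UserWarning):
    pass


class DecayFitError(RuntimeError):
    pass


@dataclass
class WellMeasurement:
    well: str
    image_sums: np.ndarray
    background: float

    @property
    def corrected_intensity(self) -> float:
        """Mean per-image summed intensity minus the plate background
        (may be negative; clamp happens at concentration inversion)."""
        return float(np.mean(self.image_sums) - self.background)


def well_intensity(images, background_intensity: float = 0.0, well: str = "") -> WellMeasurement:
    """Sum pixel intensities per image, subtract the background, average."""
    stack = np.asarray(images, dtype=float)
    if stack.size == 0 or stack.ndim < 2:
        raise ValueError("need at least one 2-D image")
    if stack.ndim == 2:
        stack = stack[None]
    if background_intensity < 0:
        raise ValueError("background must be nonnegative")
    sums = stack.reshape(stack.shape[0], -1).sum(axis=1)
    return WellMeasurement(well=well, image_sums=sums, background=background_intensity)


@dataclass(frozen=True)
class StandardCurve:
    """Fluorescence-vs-concentration calibration line."""

    slope: float  # intensity per μg/mL
    intercept: float  # intensity
    conc_range: tuple[float, float]
    r2: float

    def invert(self, intensity: float) -> tuple[float, bool]:
        """Concentration (clamped at 0) and an extrapolation flag."""
        if self.slope <= 0:
            raise ValueError("standard curve slope must be positive")
        conc = (intensity - self.intercept) / self.slope
        tol = 1e-9 * max(self.conc_range[1] - self.conc_range[0], 1.0)
        extrapolated = not (
            self.conc_range[0] - tol <= conc <= self.conc_range[1] + tol
        )
        return max(conc, 0.0), extrapolated


class StandardCurveRegressor(BaseEstimator, RegressorMixin):
    """Ordinary-least-squares standard curve, scikit-learn style.

    ``fit(concentrations, intensities)`` sets ``slope_``, ``intercept_``,
    ``r2_`` and ``curve_``; ``predict`` maps concentration to intensity
    and ``inverse`` maps intensity back to concentration.
    """

    def fit(self, concentrations, intensities) -> "StandardCurveRegressor":
        c = np.asarray(concentrations, dtype=float)
        y = np.asarray(intensities, dtype=float)
        if c.shape != y.shape or c.size < 3:
            raise ValueError("need at least 3 matched standards")
        if np.any(c < 0):
            raise ValueError("standard concentrations must be nonnegative")
        if np.all(c == c[0]):
            raise ValueError("standard concentrations must not all be equal")
        slope, intercept = np.polyfit(c, y, 1)
        resid = y - (slope * c + intercept)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.r2_ = r2
        self.conc_range_ = (float(c.min()), float(c.max()))
        self.curve_ = StandardCurve(
            slope=self.slope_, intercept=self.intercept_,
            conc_range=self.conc_range_, r2=self.r2_,
        )
        return self

    def predict(self, concentrations) -> np.ndarray:
        return self.slope_ * np.asarray(concentrations, dtype=float) + self.intercept_

    def inverse(self, intensity: float) -> tuple[float, bool]:
        return self.curve_.invert(intensity)


def build_standard_curve(concentrations, corrected_intensities) -> StandardCurve:
    """OLS line through (concentration, corrected intensity) standards."""
    return StandardCurveRegressor().fit(concentrations, corrected_intensities).curve_


def concentration_from_intensity(curve: StandardCurve, intensity: float) -> float:
    """Invert the standard curve; emits :class:`ExtrapolationWarning` when
    the intensity falls outside the fitted concentration range."""
    conc, extrapolated = curve.invert(intensity)
    if extrapolated:
        warnings.warn(
            f"intensity {intensity:g} outside the fitted range; extrapolating",
            ExtrapolationWarning,
        )
    return conc


@dataclass(frozen=True)
class DecayFit:
    """One-phase decay fit with plateau constrained to zero."""

    C0: float  # μg/mL
    k: float  # 1/h

    @property
    def t_half(self) -> float:
        return float(np.log(2.0) / self.k)

    def __call__(self, t):
        return self.C0 * np.exp(-self.k * np.asarray(t, dtype=float))


class OnePhaseDecay(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares one-phase decay estimator.

    Initialized from a log-linear regression of the positive
    concentrations; exposes ``C0_``, ``k_`` and ``t_half_`` after
    ``fit(times, concentrations)``.
    """

    def __init__(self, xtol: float = 1e-10):
        self.xtol = xtol

    def fit(self, times, concentrations) -> "OnePhaseDecay":
        t = np.asarray(times, dtype=float)
        c = np.asarray(concentrations, dtype=float)
        if t.shape != c.shape or t.size < 3:
            raise ValueError("need at least 3 (time, concentration) pairs")
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")
        pos = c > 0
        if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
            b, a = np.polyfit(t[pos], np.log(c[pos]), 1)
            p0 = (float(np.exp(a)), float(max(-b, 1e-6)))
        else:
            p0 = (float(max(c.max(), 1e-12)), 1e-2)
        popt, _ = curve_fit(
            lambda tt, C0, k: C0 * np.exp(-k * tt), t, c, p0=p0,
            maxfev=20000, xtol=self.xtol,
        )
        C0, k = float(popt[0]), float(popt[1])
        if k <= 0 or C0 <= 0:
            raise DecayFitError(
                f"non-decaying data: fitted C0={C0:.4g}, k={k:.4g} 1/h"
            )
        self.C0_, self.k_ = C0, k
        self.t_half_ = float(np.log(2.0) / k)
        self.fit_ = DecayFit(C0=C0, k=k)
        return self

    def predict(self, times) -> np.ndarray:
        return self.fit_(times)


def fit_one_phase_decay(times, concentrations) -> DecayFit:
    """C(t) = C0·exp(-kt) fit; reports t½ = ln2/k."""
    return OnePhaseDecay().fit(times, concentrations).fit_


def plate_background(wells: dict[str, np.ndarray], layout: pd.DataFrame) -> float:
    """Mean summed intensity of the blood-only (zero-concentration
    standard) wells on the plate."""
    blanks = layout[(layout.role == "standard") & (layout.concentration == 0)]
    if blanks.empty:
        raise ValueError("plate has no blood-only (0 μg/mL) wells")
    sums = [
        well_intensity(wells[w], 0.0).image_sums.mean() for w in blanks.well
    ]
    return float(np.mean(sums))


def quantify_plate(
    wells: dict[str, np.ndarray], layout: pd.DataFrame
) -> tuple[pd.DataFrame, StandardCurve]:
    """Full chain: background subtraction, standard curve, inversion.

    Returns the per-sample concentrations (well, animal, time,
    concentration) and the fitted curve.
    """
    bg = plate_background(wells, layout)
    standards = layout[layout.role == "standard"]
    conc, intens = [], []
    for row in standards.itertuples():
        conc.append(row.concentration)
        intens.append(well_intensity(wells[row.well], bg).corrected_intensity)
    curve = build_standard_curve(conc, intens)
    samples = layout[layout.role == "sample"]
    rows = []
    for row in samples.itertuples():
        corrected = well_intensity(wells[row.well], bg).corrected_intensity
        value, _ = curve.invert(corrected)
        rows.append((row.well, row.animal, row.time, value))
    return (
        pd.DataFrame(rows, columns=["well", "animal", "time", "concentration"]),
        curve,
    )


def half_life_from_samples(
    samples: pd.DataFrame, per_animal: bool = False
) -> pd.DataFrame:
    """One-phase-decay half-life from quantified samples.

    By default all animals of the group are pooled into one fit (group-
    level reporting); ``per_animal=True`` fits each animal separately.
    """
    groups = samples.groupby("animal") if per_animal else [("pooled", samples)]
    rows = []
    for name, grp in groups:
        fit = fit_one_phase_decay(grp.time.values, grp.concentration.values)
        rows.append((name, fit.C0, fit.k, fit.t_half))
    return pd.DataFrame(rows, columns=["group", "C0", "k", "t_half"])
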