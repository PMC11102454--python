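"""Posterior-predictive validation and endpoint statistics.

A fitted probabilistic model is compared with held-out data condition by
condition with a two-sample Z score,

    Z = (x̄_mod - x̄_exp) / sqrt(σ_mod²/n_mod + σ_exp²/n_exp),

and with the PBPK factor-of-two convention (model mean within 50%–200% of
the experimental mean).  |Z| < 20 is the default acceptance threshold,
the conventional correlate of the factor-of-two rule for this kind of
data.  R²/RMSE summarize overall model-data agreement, and two small
worked-example statistics (pooled-variance t degrees of freedom, one-way
ANOVA F ↔ R² identity) are included for endpoint analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcis import PosteriorPrediction
from .synth import BiodistributionDataset, BloodPKDataset

#: held-out time points (h): blood and organ biodistribution
HOLDOUT_BLOOD_TIMES = (2.0, 10.0)
HOLDOUT_BIODIST_TIMES = (6.0, 24.0)


class ValidationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ZTestResult:
    condition: str
    mean_mod: float
    sd_mod: float
    n_mod: int
    mean_exp: float
    sd_exp: float
    n_exp: int
    Z: float
    threshold: float

    @property
    def passed(self) -> bool:
        return abs(self.Z) < self.threshold


@dataclass(frozen=True)
class FitMetrics:
    r2: float
    rmse: float


def z_score(
    mean_mod: float,
    sd_mod: float,
    n_mod: int,
    mean_exp: float,
    sd_exp: float,
    n_exp: int,
    threshold: float = 20.0,
    condition: str = "",
) -> ZTestResult:
    """Two-sample Z score of a model-produced distribution vs data."""
    if n_mod < 1 or n_exp < 1:
        raise ValueError("sample sizes must be >= 1")
    if sd_mod < 0 or sd_exp < 0:
        raise ValueError("standard deviations must be nonnegative")
    denom = np.sqrt(sd_mod**2 / n_mod + sd_exp**2 / n_exp)
    if denom == 0:
        raise ValueError("both variance terms are zero; Z is undefined")
    return ZTestResult(
        condition=condition,
        mean_mod=mean_mod, sd_mod=sd_mod, n_mod=n_mod,
        mean_exp=mean_exp, sd_exp=sd_exp, n_exp=n_exp,
        Z=float((mean_mod - mean_exp) / denom),
        threshold=threshold,
    )


def factor_of_two(mean_mod: float, mean_exp: float) -> bool:
    """True iff the model mean is within 50%–200% of the experimental mean
    (bounds inclusive)."""
    if mean_exp <= 0:
        raise ValueError("experimental mean must be positive")
    ratio = mean_mod / mean_exp
    return 0.5 <= ratio <= 2.0


def fit_metrics(predicted, observed) -> FitMetrics:
    """R² (about the observed mean) and RMSE of paired predictions."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size < 2:
        raise ValueError("predicted and observed must be equal-length with n >= 2")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values have zero variance; R² is undefined")
    ss_res = float(np.sum((o - p) ** 2))
    return FitMetrics(r2=1.0 - ss_res / ss_tot, rmse=float(np.sqrt(np.mean((o - p) ** 2))))


def anova_r2_from_f(F: float, df_between: int, df_within: int) -> float:
    """R² implied by a one-way ANOVA F statistic:
    R² = df_b·F / (df_b·F + df_w)."""
    if F < 0 or df_between < 1 or df_within < 1:
        raise ValueError("F must be >= 0 and degrees of freedom >= 1")
    return (df_between * F) / (df_between * F + df_within)


def pooled_t_df(n1: int, n2: int) -> int:
    """Degrees of freedom of the pooled-variance two-sample t test."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    return n1 + n2 - 2


@dataclass(frozen=True)
class HoldoutData:
    """Held-out conditions: blood (dose, time, mean, sd, n) and
    biodistribution (organ, time, value, sd, n) relative to liver."""

    blood: pd.DataFrame
    biodist: pd.DataFrame

    @classmethod
    def from_datasets(
        cls,
        blood: BloodPKDataset,
        biodist: BiodistributionDataset,
        dose_mg: float = 0.5,
        blood_times=HOLDOUT_BLOOD_TIMES,
        biodist_times=HOLDOUT_BIODIST_TIMES,
        organs=("lung", "spleen", "kidney", "heart", "bone"),
    ) -> "HoldoutData":
        rows = blood.rows[
            np.isclose(blood.rows.dose, dose_mg)
            & np.isclose(blood.rows.time.values[:, None], blood_times).any(axis=1)
        ]
        g = rows.groupby("time")["concentration"]
        bl = g.agg(mean="mean", sd="std", n="count").reset_index()
        bl.insert(0, "dose", dose_mg)
        if biodist.raw is not None:
            raw = biodist.raw
            mask = raw.organ.isin(organs) & np.isclose(
                raw.time.values[:, None], biodist_times
            ).any(axis=1)
            g = raw[mask].groupby(["organ", "time"])["value"]
            bd = g.agg(value="mean", sd="std", n="count").reset_index()
        else:
            mask = biodist.rows.organ.isin(organs) & np.isclose(
                biodist.rows.time.values[:, None], biodist_times
            ).any(axis=1)
            bd = biodist.rows[mask].copy()
            bd["sd"] = bd["sem"] * np.sqrt(bd["n"])
            bd = bd[["organ", "time", "value", "sd", "n"]]
        return cls(blood=bl, biodist=bd.reset_index(drop=True))


def validate_holdout(
    prediction: PosteriorPrediction,
    holdout: HoldoutData,
    z_threshold: float = 20.0,
) -> tuple[pd.DataFrame, dict]:
    """One Z test and one factor-of-two check per held-out condition.

    The default design yields 12 conditions: blood at 2 and 10 h at the
    fitted dose, plus 5 non-liver organs at 6 and 24 h.
    """
    results = []
    for row in holdout.blood.itertuples():
        if not np.isclose(row.dose, prediction.dose_mg):
            raise ValidationError(
                f"no prediction at dose {row.dose} mg (blood t={row.time} h)"
            )
        if row.time > prediction.t[-1]:
            raise ValidationError(f"no prediction at blood time {row.time} h")
        m, s = prediction.blood_at([row.time])
        zr = z_score(
            float(m[0]), float(s[0]), prediction.n,
            float(row.mean), float(row.sd), int(row.n),
            threshold=z_threshold, condition=f"blood@{row.time:g}h",
        )
        results.append((zr, factor_of_two(zr.mean_mod, zr.mean_exp)))
    for row in holdout.biodist.itertuples():
        if row.organ not in prediction.tissue:
            raise ValidationError(f"no prediction for organ {row.organ!r}")
        if row.time > prediction.t[-1]:
            raise ValidationError(f"no prediction at biodistribution time {row.time} h")
        m, s = prediction.ratio_at(row.organ, [row.time])
        zr = z_score(
            float(m[0]), float(s[0]), prediction.n,
            float(row.value), float(row.sd), int(row.n),
            threshold=z_threshold, condition=f"{row.organ}@{row.time:g}h",
        )
        results.append((zr, factor_of_two(zr.mean_mod, zr.mean_exp)))

    table = pd.DataFrame(
        [
            (
                zr.condition, zr.mean_mod, zr.sd_mod, zr.n_mod,
                zr.mean_exp, zr.sd_exp, zr.n_exp, zr.Z, zr.passed, f2,
            )
            for zr, f2 in results
        ],
        columns=[
            "condition", "mean_mod", "sd_mod", "n_mod",
            "mean_exp", "sd_exp", "n_exp", "Z", "pass_z", "pass_factor2",
        ],
    )
    summary = {
        "n_conditions": len(table),
        "z_threshold": z_threshold,
        "pass_fraction_z": float(table.pass_z.mean()),
        "n_pass_factor2": int(table.pass_factor2.sum()),
        "pass_fraction_factor2": float(table.pass_factor2.mean()),
    }
    return table, summary
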