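"""Probabilistic parameter representations for Monte Carlo importance
sampling: uniform, log-uniform, zero-truncated normal and gamma families,
all restricted to nonnegative support."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FAMILIES = ("uniform", "normal", "gamma", "log-uniform")


@dataclass(frozen=True)
class ParameterDistribution:
    """One kinetic parameter's distribution, in its native units.

    uniform / log-uniform use ``low``/``high`` bounds (log-uniform bounds
    must be positive); normal / gamma use ``mean``/``sd``, with the normal
    truncated below at zero and degenerate (point-mass) when ``sd = 0``.
    """

    name: str
    family: str
    low: float = 0.0
    high: float = 0.0
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family in ("uniform", "log-uniform"):
            if not np.isfinite([self.low, self.high]).all() or self.high < self.low:
                raise ValueError("bounds must be finite with high >= low")
            if self.family == "log-uniform" and self.low <= 0:
                raise ValueError("log-uniform bounds must be positive")
            if self.low < 0:
                raise ValueError("support must be nonnegative")
        else:
            if self.sd < 0 or self.mean < 0:
                raise ValueError("mean and sd must be nonnegative")

    # ------------------------------------------------------------ moments

    def _truncnorm(self):
        a = (0.0 - self.mean) / self.sd
        return stats.truncnorm(a, np.inf, loc=self.mean, scale=self.sd)

    def moments(self) -> tuple[float, float]:
        """(mean, sd) of the distribution itself (after truncation)."""
        if self.family == "uniform":
            return (self.low + self.high) / 2, (self.high - self.low) / np.sqrt(12)
        if self.family == "log-uniform":
            if self.high == self.low:
                return self.low, 0.0
            r = np.log(self.high / self.low)
            m = (self.high - self.low) / r
            m2 = (self.high**2 - self.low**2) / (2 * r)
            return m, float(np.sqrt(max(m2 - m**2, 0.0)))
        if self.family == "normal":
            if self.sd == 0:
                return self.mean, 0.0
            m, v = self._truncnorm().stats(moments="mv")
            return float(m), float(np.sqrt(v))
        # gamma parameterized by mean/sd: shape = (mean/sd)^2, scale = sd^2/mean
        return self.mean, self.sd

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "uniform":
            return rng.uniform(self.low, self.high, n)
        if self.family == "log-uniform":
            if self.high == self.low:
                return np.full(n, self.low)
            return np.exp(rng.uniform(np.log(self.low), np.log(self.high), n))
        if self.family == "normal":
            if self.sd == 0:
                return np.full(n, self.mean)
            return self._truncnorm().rvs(size=n, random_state=rng)
        if self.sd == 0 or self.mean == 0:
            return np.full(n, self.mean)
        shape = (self.mean / self.sd) ** 2
        scale = self.sd**2 / self.mean
        return rng.gamma(shape, scale, n)

    def as_gamma(self) -> "ParameterDistribution":
        """Moment-matched gamma re-expression of this distribution."""
        m, s = self.moments()
        return ParameterDistribution(name=self.name, family="gamma", mean=m, sd=s)


def sample_parameters(
    dists: list[ParameterDistribution], n: int, seed
) -> pd.DataFrame:
    """``n`` independent joint draws, one column per parameter.

    Reproducible for a fixed seed; truncated families never return
    negative values.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({d.name: d.sample(rng, n) for d in dists})


def distributions_to_frame(dists: list[ParameterDistribution]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.name, d.family, d.mean, d.sd, d.low, d.high) for d in dists],
        columns=["parameter", "family", "mean", "sd", "lower", "upper"],
    )


def distributions_from_frame(df: pd.DataFrame) -> list[ParameterDistribution]:
    return [
        ParameterDistribution(
            name=r.parameter,
            family=r.family,
            mean=float(r.mean),
            sd=float(r.sd),
            low=float(r.lower),
            high=float(r.upper),
        )
        for r in df.itertuples()
    ]
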