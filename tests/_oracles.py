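"""Independent numerical oracles used only by the test suite."""

from __future__ import annotations

import numpy as np


def rk4_integrate(rhs, y0, t_end: float, dt: float, t_eval) -> np.ndarray:
    """Classic fixed-step 4th-order Runge–Kutta integration.

    Returns the state at each requested output time (linear interpolation
    between the two bracketing fixed steps).
    """
    n_steps = int(round(t_end / dt))
    t_eval = np.asarray(t_eval, dtype=float)
    out = np.empty((len(t_eval), len(y0)))
    y = np.asarray(y0, dtype=float).copy()
    t = 0.0
    j = 0
    while j < len(t_eval) and t_eval[j] <= 0:
        out[j] = y
        j += 1
    for _ in range(n_steps):
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y_new = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t_new = t + dt
        while j < len(t_eval) and t_eval[j] <= t_new + 1e-12:
            w = (t_eval[j] - t) / dt
            out[j] = (1 - w) * y + w * y_new
            j += 1
        y, t = y_new, t_new
    while j < len(t_eval):
        out[j] = y
        j += 1
    return out


def one_way_anova(groups) -> tuple[float, float]:
    """From-scratch one-way ANOVA: returns (F, R²)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    r2 = ss_between / (ss_between + ss_within)
    return float(F), float(r2)


def truncated_normal_mean(mu: float, sigma: float) -> float:
    """Closed-form mean of a normal truncated below at 0."""
    from scipy.stats import norm

    alpha = (0.0 - mu) / sigma
    return mu + sigma * norm.pdf(alpha) / (1.0 - norm.cdf(alpha))
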