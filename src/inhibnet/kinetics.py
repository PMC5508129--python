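"""Rate laws and nonlinear fitting for the three classical inhibition mechanisms.

Single-substrate initial-rate kinetics with one inhibitor:

* competitive:    v = Vmax*S / (Km*(1 + I/Ki) + S)
* noncompetitive: v = Vmax*S / ((Km + S) * (1 + I/Ki))
* uncompetitive:  v = Vmax*S / (Km + S*(1 + I/Ki))

All three reduce to Michaelis-Menten at I = 0.  ``fit_mechanism`` fits each
candidate law to untransformed rates by least squares (double-reciprocal
linearization supplies starting values only), selects the best model by R^2
with an AIC tie-break, and reports the inhibitory-capacity ratio Ki/Km.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

MECHANISMS = ("competitive", "noncompetitive", "uncompetitive")


@dataclass
class RateDataset:
    data: pd.DataFrame  # columns S_mM, I_mM, rate
    substrate: str = "substrate"
    inhibitor: str = "inhibitor"

    def __post_init__(self):
        required = {"S_mM", "I_mM", "rate"}
        if not required <= set(self.data.columns):
            raise ValueError(f"rate data needs columns {sorted(required)}")
        if (self.data[["S_mM", "I_mM"]] < 0).any().any():
            raise ValueError("concentrations must be >= 0")


@dataclass
class KineticFit:
    mechanism: str
    vmax: float
    km: float
    ki: float
    r_squared: float
    stderr: dict[str, float] = field(default_factory=dict)
    aic: float = float("nan")

    @property
    def ki_over_km(self) -> float:
        return self.ki / self.km


def rate(mechanism: str, S, I, vmax: float, km: float, ki: float):
    """Initial rate under the given mechanism's law (vectorized in S, I)."""
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if min(vmax, km, ki) <= 0:
        raise ValueError("vmax, km, ki must be positive")
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    alpha = 1.0 + I / ki
    if mechanism == "competitive":
        return vmax * S / (km * alpha + S)
    if mechanism == "noncompetitive":
        return vmax * S / ((km + S) * alpha)
    return vmax * S / (km + S * alpha)


def _initial_guess(df: pd.DataFrame) -> tuple[float, float, float]:
    """Starting values from double-reciprocal (Lineweaver-Burk) linearization."""
    base = df[df["I_mM"] == df["I_mM"].min()]
    base = base[base["S_mM"] > 0]
    inv_s = 1.0 / base["S_mM"].to_numpy()
    with np.errstate(divide="ignore"):
        inv_v = 1.0 / base["rate"].to_numpy()
    ok = np.isfinite(inv_v)
    if ok.sum() >= 2 and np.std(inv_s[ok]) > 0:
        slope, intercept, *_ = stats.linregress(inv_s[ok], inv_v[ok])
        if intercept > 0 and slope > 0:
            vmax0 = 1.0 / intercept
            km0 = slope * vmax0
        else:
            vmax0, km0 = float(df["rate"].max()), float(np.median(df["S_mM"]))
    else:
        vmax0, km0 = float(df["rate"].max()), float(np.median(df["S_mM"]))
    i_levels = np.array(sorted(df["I_mM"].unique()))
    ki0 = float(np.median(i_levels[i_levels > 0])) if (i_levels > 0).any() else 1.0
    return max(vmax0, 1e-6), max(km0, 1e-6), max(ki0, 1e-6)


def _fit_single(df: pd.DataFrame, mechanism: str, seed: int = 0) -> KineticFit | None:
    S = df["S_mM"].to_numpy()
    I = df["I_mM"].to_numpy()
    v = df["rate"].to_numpy()
    p0 = np.array(_initial_guess(df))

    def model(X, vmax, km, ki):
        s, i = X
        return rate(mechanism, s, i, vmax, km, ki)

    rng = np.random.default_rng(seed)
    starts = [p0] + [p0 * rng.lognormal(0, 0.5, size=3) for _ in range(5)]
    best = None
    for start in starts:
        try:
            popt, pcov = optimize.curve_fit(
                model, (S, I), v, p0=start,
                bounds=([1e-9] * 3, [np.inf] * 3), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        resid = v - model((S, I), *popt)
        rss = float(np.sum(resid ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
        if rss < 1e-20:
            break
    if best is None:
        return None
    rss, popt, pcov = best
    tss = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    n = len(v)
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * 3
    stderr = {}
    with np.errstate(invalid="ignore"):
        diag = np.sqrt(np.diag(pcov))
    for name, se in zip(("vmax", "km", "ki"), diag):
        stderr[name] = float(se)
    return KineticFit(mechanism=mechanism, vmax=float(popt[0]), km=float(popt[1]),
                      ki=float(popt[2]), r_squared=r2, stderr=stderr, aic=float(aic))


def fit_mechanism(data: RateDataset | pd.DataFrame,
                  candidates=MECHANISMS, seed: int = 0) -> KineticFit:
    """Fit candidate rate laws and select the best-supported mechanism.

    The data must span at least two substrate levels and, for Ki estimation,
    at least two inhibitor levels.  Each candidate is fit by least squares
    on untransformed rates with seeded multi-start; the winner has the
    highest R^2, with lower AIC breaking near-ties.  Raises when no
    candidate converges.
    """
    df = data.data if isinstance(data, RateDataset) else data
    if df["S_mM"].nunique() < 2:
        raise ValueError("need at least two substrate levels")
    if df["I_mM"].nunique() < 2:
        raise ValueError("need at least two inhibitor levels to estimate Ki")
    fits = [f for f in (_fit_single(df, m, seed=seed) for m in candidates) if f is not None]
    if not fits:
        raise RuntimeError(f"no candidate mechanism converged on {len(df)} rates")
    best_r2 = max(f.r_squared for f in fits)
    near = [f for f in fits if f.r_squared >= best_r2 - 1e-6]
    return min(near, key=lambda f: f.aic)


def inhibitory_capacity(fit: KineticFit) -> float:
    """Ki/Km rounded to the reporting precision (1 decimal below 10, integer above)."""
    raw = fit.ki_over_km
    return round(raw, 1) if raw < 10 else float(round(raw))
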