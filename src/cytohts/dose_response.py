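"""Four-parameter logistic dose-response fitting and ICx extraction.

The model is the variable-slope sigmoid used for normalized-viability data:

    y(d) = bottom + (top - bottom) / (1 + 10^((log10 d - log_ic50) * hill))

with viability percent y falling from ``top`` (zero-dose plateau) to
``bottom`` (infinite-dose plateau) as dose d (nM) rises, for hill > 0; the
midpoint (top+bottom)/2 sits at d = 10^log_ic50 with log_ic50 on the log10
molar-equivalent nM scale.  Fits are least squares with multi-start
initialization over the hill slope.

ICx ("Dx") doses are read from the fitted curve.  In ``absolute`` mode
(default) the dose solves fraction-affected fa(d) = 1 - y(d)/100 = x, the
scale the combination index needs so both agents refer to one common effect;
``relative`` mode solves y(d) = top - x*(top - bottom), the span-relative
reading.  A plateau that prevents attaining x yields ``reachable=False``
rather than an error.

``fit_median_effect`` provides the classical median-effect linearization
(log10(fa/(1-fa)) vs log10 dose) as an independent route to Dm and m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

#: default fitting bounds: (bottom, top, log_ic50 pad in decades, hill)
DEFAULT_BOTTOM_BOUNDS = (-10.0, 60.0)
DEFAULT_TOP_BOUNDS = (50.0, 150.0)
DEFAULT_HILL_BOUNDS = (0.05, 10.0)
HILL_STARTS = (0.5, 1.0, 2.0)


class FitError(RuntimeError):
    """The 4PL optimizer failed to converge from every start."""


@dataclass
class Fit4PL:
    """Converged four-parameter logistic fit of viability vs log-dose."""

    bottom: float
    top: float
    log_ic50: float   # log10 of dose in nM
    hill: float
    rss: float
    converged: bool
    n_points: int

    def params(self) -> tuple[float, float, float, float]:
        return (self.bottom, self.top, self.log_ic50, self.hill)


@dataclass
class ICxResult:
    """Dose achieving effect fraction x on a fitted curve."""

    level: float
    dose_nM: float | None
    mode: str
    reachable: bool


def four_pl(dose_nM, bottom, top, log_ic50, hill):
    """Evaluate the 4PL curve at dose (nM)."""
    d = np.asarray(dose_nM, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((np.log10(d) - log_ic50)
                                                     * hill))


def predict_4pl(fit: Fit4PL, dose_nM):
    """Curve evaluation; doses must be strictly positive."""
    d = np.asarray(dose_nM, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dose must be > 0")
    return four_pl(d, *fit.params())


def fit_4pl(doses_nM, responses, constrain_0_100: bool = False,
            bottom_bounds=DEFAULT_BOTTOM_BOUNDS,
            top_bounds=DEFAULT_TOP_BOUNDS,
            hill_bounds=DEFAULT_HILL_BOUNDS) -> Fit4PL:
    """Least-squares 4PL fit with multi-start initialization.

    Replicate points all enter the loss (no pre-averaging).  Starts are
    top = max response, bottom = min response, log_ic50 = median log-dose,
    hill in {0.5, 1, 2}; the best residual sum of squares wins, ties broken
    by the smallest |hill|.  ``constrain_0_100`` pins bottom = 0, top = 100
    for normalized-viability fits.  Raises :class:`FitError` if no start
    converges.
    """
    d = np.asarray(doses_nM, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.shape != y.shape:
        raise ValueError("doses and responses must align")
    if np.any(d <= 0):
        raise ValueError("doses must be strictly positive")
    if np.unique(d).size < 4:
        raise ValueError("need at least 4 distinct doses")
    if np.allclose(y, y[0]):
        raise ValueError("responses are all equal; nothing to fit")
    logd = np.log10(d)
    lo_ic, hi_ic = logd.min() - 3.0, logd.max() + 3.0

    if constrain_0_100:
        def resid(p):
            return four_pl(d, 0.0, 100.0, p[0], p[1]) - y
        lower, upper = [lo_ic, hill_bounds[0]], [hi_ic, hill_bounds[1]]
        def unpack(p):
            return 0.0, 100.0, p[0], p[1]
        def make_start(h):
            return [float(np.median(logd)), h]
    else:
        def resid(p):
            return four_pl(d, p[0], p[1], p[2], p[3]) - y
        lower = [bottom_bounds[0], top_bounds[0], lo_ic, hill_bounds[0]]
        upper = [bottom_bounds[1], top_bounds[1], hi_ic, hill_bounds[1]]
        def unpack(p):
            return tuple(p)
        b0 = float(np.clip(y.min(), *bottom_bounds))
        t0 = float(np.clip(y.max(), *top_bounds))
        def make_start(h):
            return [b0, t0, float(np.median(logd)), h]

    best = None
    for h in HILL_STARTS:
        try:
            sol = optimize.least_squares(resid, make_start(h),
                                         bounds=(lower, upper),
                                         xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if not sol.success:
            continue
        rss = float(np.sum(sol.fun ** 2))
        hill = unpack(sol.x)[3]
        key = (round(rss, 12), abs(hill))
        if best is None or key < best[0]:
            best = (key, sol, rss)
    if best is None:
        raise FitError("4PL fit failed to converge from all starts")
    _, sol, rss = best
    bottom, top, log_ic50, hill = unpack(sol.x)
    return Fit4PL(float(bottom), float(top), float(log_ic50), float(hill),
                  rss=rss, converged=True, n_points=int(y.size))


def icx(fit: Fit4PL, level: float, mode: str = "absolute") -> ICxResult:
    """Invert the fitted curve for the dose achieving effect fraction *level*.

    Closed-form inversion; ``reachable=False`` (with no dose) when the
    requested effect lies outside the curve's plateaus.
    """
    if not fit.converged:
        raise FitError("cannot extract ICx from a non-converged fit")
    if not 0.0 < level < 1.0:
        raise ValueError("effect level must be in (0, 1)")
    if mode == "absolute":
        y_target = 100.0 * (1.0 - level)   # fa = 1 - y/100 = level
    elif mode == "relative":
        y_target = fit.top - level * (fit.top - fit.bottom)
    else:
        raise ValueError(f"unknown ICx mode {mode!r}")
    lo, hi = sorted((fit.bottom, fit.top))
    if not lo < y_target < hi:
        return ICxResult(level, None, mode, reachable=False)
    # y = bottom + span/(1+r), r = 10^((logd - log_ic50)*hill)
    r = (fit.top - y_target) / (y_target - fit.bottom)
    log_dose = fit.log_ic50 + math.log10(r) / fit.hill
    return ICxResult(level, 10.0 ** log_dose, mode, reachable=True)


def icx_table(fit: Fit4PL, levels=(0.5, 0.75, 0.9),
              mode: str = "absolute") -> list[ICxResult]:
    return [icx(fit, x, mode) for x in levels]


def fit_median_effect(doses_nM, fa) -> dict:
    """Median-effect fit: regress log10(fa/(1-fa)) on log10(dose).

    Points with fa outside the open interval (0, 1) are excluded (their
    logit is undefined) and the exclusion count reported.  Returns
    Dm = 10^(-intercept/slope) in nM, the slope m, and the regression r².
    Serves as an independent oracle for 4PL-derived Dx values.
    """
    d = np.asarray(doses_nM, dtype=float)
    f = np.asarray(fa, dtype=float)
    usable = (f > 0.0) & (f < 1.0) & (d > 0.0)
    n_excluded = int(np.sum(~usable))
    d, f = d[usable], f[usable]
    if d.size < 3:
        raise ValueError("need at least 3 points with fa strictly in (0,1)")
    reg = stats.linregress(np.log10(d), np.log10(f / (1.0 - f)))
    m = float(reg.slope)
    dm = 10.0 ** (-reg.intercept / m)
    return {"Dm_nM": float(dm), "m": m, "r2": float(reg.rvalue ** 2),
            "n_used": int(d.size), "n_excluded": n_excluded}
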