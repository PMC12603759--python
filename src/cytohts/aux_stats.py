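"""Small self-contained statistics used around the screen.

* two-sample t-test sample size via the noncentral-t power function
  (the animal-study group-size computation);
* relative expression by the 2^-ddCt method;
* the cell-cycle proliferation ratio (S+G2 over subG1+G1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to the two-sample t-test sample-size computation.

    ``delta`` and ``sd`` share units (mm^3 in the tumor-volume use case);
    ``alpha`` is the two-sided significance level unless ``two_sided`` is
    cleared.
    """

    delta: float
    sd: float
    alpha: float = 0.05
    power: float = 0.80
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.delta == 0:
            raise ValueError("delta must be non-zero")


@dataclass(frozen=True)
class PhaseCounts:
    """DNA-content gating event counts for the four cell-cycle bins."""

    sub_g1: int
    g1: int
    s: int
    g2: int

    def __post_init__(self) -> None:
        if min(self.sub_g1, self.g1, self.s, self.g2) < 0:
            raise ValueError("phase counts must be non-negative")


def t_test_power(n: int, effect_size: float, alpha: float = 0.05,
                 two_sided: bool = True) -> float:
    """Power of an equal-n two-sample t-test (noncentral-t)."""
    if n < 2:
        return 0.0
    df = 2 * n - 2
    ncp = abs(effect_size) * np.sqrt(n / 2.0)
    if two_sided:
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        upper = stats.nct.sf(tcrit, df, ncp)
        lower = stats.nct.cdf(-tcrit, df, ncp)
        # scipy's nct lower tail can underflow to nan for large ncp
        if not np.isfinite(lower):
            lower = 0.0
        return float(upper + lower)
    tcrit = stats.t.ppf(1 - alpha, df)
    return float(stats.nct.sf(tcrit, df, ncp))


def sample_size_two_sample_t(spec: PowerSpec, n_max: int = 100000) -> int:
    """Smallest per-group n whose t-test power reaches the target.

    Iterates the noncentral-t power function upward from n = 2 (the minimum
    fittable group size; a t-test needs at least two observations per arm
    even when power is trivially attained).
    """
    d = abs(spec.delta) / spec.sd
    for n in range(2, n_max + 1):
        if t_test_power(n, d, spec.alpha, spec.two_sided) >= spec.power:
            return n
    raise ValueError(f"no n <= {n_max} attains the requested power")


def simulate_rejection_rate(n: int, delta: float, sd: float,
                            alpha: float = 0.05, n_sim: int = 10000,
                            seed: int = 0) -> float:
    """Monte-Carlo rejection rate of the two-sample t-test at group size n.

    Serves as the simulation cross-check of the analytic power function.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sd, size=(n_sim, n))
    b = rng.normal(delta, sd, size=(n_sim, n))
    _, p = stats.ttest_ind(a, b, axis=1)
    return float(np.mean(p < alpha))


def fold_change_ddct(ct_target_treated: float, ct_ref_treated: float,
                     ct_target_control: float, ct_ref_control: float) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) under treatment minus the same
    difference under control; the fold change is 2^-ddCt (1.0 = no change,
    0.5 = halved expression).
    """
    cts = (ct_target_treated, ct_ref_treated, ct_target_control,
           ct_ref_control)
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = ((ct_target_treated - ct_ref_treated)
            - (ct_target_control - ct_ref_control))
    return float(2.0 ** (-ddct))


def proliferation_ratio(counts: PhaseCounts) -> float:
    """Proliferating (S + G2) over non-proliferating (sub-G1 + G1) cells."""
    denom = counts.sub_g1 + counts.g1
    if denom <= 0:
        raise ValueError("sub_g1 + g1 must be positive")
    return float((counts.s + counts.g2) / denom)
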