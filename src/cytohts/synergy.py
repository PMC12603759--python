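"""Drug-combination interaction analysis.

Two complementary views of combination data are implemented, both operating
on the fraction-affected scale (fa = 1 - viability/100, expressed in
percent):

* **Combination index** (Chou-Talalay): for a fixed-ratio combination
  achieving effect x with component doses (D)1 and (D)2,

      CI = (D)1/(Dx)1 + (D)2/(Dx)2

  where (Dx)i is the dose of agent i alone achieving the same effect.
  CI < 1 indicates synergism, CI ~ 1 additivity, CI > 1 antagonism, refined
  into six interpretation bands (strong synergism below 0.3 up to strong
  antagonism above 1.45).

* **Expected-effect surfaces** over a dose x dose matrix: the Loewe
  additivity null (the effect E solving d1/D1(E) + d2/D2(E) = 1 on the
  fitted single-agent curves) and the highest-single-agent (HSA) null
  (max of the two single-agent effects).  Observed minus expected gives a
  per-cell synergy score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose_response import Fit4PL, FitError, fit_4pl, icx, predict_4pl

CI_LEVELS = (0.5, 0.75, 0.9)

#: (upper edge, right-closed?, label); scanned left to right.
_CI_BANDS = (
    (0.3, False, "strong_synergism"),
    (0.7, False, "synergism"),
    (0.9, False, "moderate_slight_synergism"),
    (1.1, True, "nearly_additive"),
    (1.45, True, "slight_moderate_antagonism"),
    (np.inf, True, "strong_antagonism"),
)

LOEWE_TOL = 1e-8


@dataclass
class CombinationDesign:
    """Fixed-ratio pairing of two drugs' dose ladders."""

    drug1_id: str
    drug2_id: str
    doses1_nM: np.ndarray = field(default=None)
    doses2_nM: np.ndarray = field(default=None)
    fixed_ratio: bool = True

    def __post_init__(self) -> None:
        self.doses1_nM = np.asarray(self.doses1_nM, dtype=float)
        self.doses2_nM = np.asarray(self.doses2_nM, dtype=float)
        if self.doses1_nM.size != self.doses2_nM.size:
            raise ValueError("dose ladders must have equal length")
        if self.fixed_ratio and self.doses1_nM.size:
            r = self.doses2_nM / self.doses1_nM
            if not np.allclose(r, r[0], rtol=1e-9):
                raise ValueError("fixed-ratio design requires constant d2/d1")

    @property
    def ratio(self) -> float:
        """d2/d1, constant under the fixed-ratio flag."""
        return float(self.doses2_nM[0] / self.doses1_nM[0])


@dataclass
class CombinationIndexResult:
    effect_level: float
    D1: float | None
    D2: float | None
    Dx1: float | None
    Dx2: float | None
    ci: float | None
    band: str | None
    reachable: bool


@dataclass
class SynergyMatrix:
    """Observed vs model-expected effect over a dose x dose grid (fa %)."""

    doses1_nM: np.ndarray
    doses2_nM: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    delta: np.ndarray      # observed - expected, elementwise
    model: str
    mean_delta: float
    peak_delta: float
    peak_cell: tuple[int, int]


def ci_value(D1: float, Dx1: float, D2: float, Dx2: float) -> float:
    """Combination index D1/Dx1 + D2/Dx2."""
    if Dx1 <= 0 or Dx2 <= 0:
        raise ValueError("single-agent Dx doses must be positive")
    if D1 < 0 or D2 < 0:
        raise ValueError("combination doses must be non-negative")
    return D1 / Dx1 + D2 / Dx2


def classify_ci(ci: float) -> str:
    """Interpretation band for a combination index.

    The bands partition [0, inf); boundary closure is left-closed at
    0.3/0.7/0.9 and right-closed at 1.1/1.45, so e.g. CI = 0.3 is
    "synergism" and CI = 1.1 is still "nearly_additive".
    """
    if ci < 0:
        raise ValueError("combination index cannot be negative")
    for edge, closed, label in _CI_BANDS:
        if ci < edge or (closed and ci == edge):
            return label
    raise AssertionError("unreachable")  # pragma: no cover


def fraction_affected(fit: Fit4PL, dose_nM: float) -> float:
    """Single-agent effect on the fa percent scale; dose 0 -> zero-dose plateau."""
    if dose_nM < 0:
        raise ValueError("dose must be non-negative")
    if dose_nM == 0:
        y = fit.top
    else:
        y = float(predict_4pl(fit, dose_nM))
    return 100.0 * (1.0 - y / 100.0)


def _require_converged(*fits: Fit4PL) -> None:
    for f in fits:
        if not f.converged:
            raise FitError("synergy models need converged single-agent fits")


def hsa_expected(d1: float, d2: float, fit1: Fit4PL, fit2: Fit4PL) -> float:
    """Highest-single-agent expected effect: max of the two single-agent
    effects at the component doses (fa %)."""
    _require_converged(fit1, fit2)
    return max(fraction_affected(fit1, d1), fraction_affected(fit2, d2))


def _dose_for_effect(fit: Fit4PL, fa_fraction: float) -> float | None:
    """Dose at which the fitted curve attains fa (fraction); None if the
    plateau prevents it."""
    res = icx(fit, fa_fraction, mode="absolute")
    return res.dose_nM if res.reachable else None


def loewe_expected(d1: float, d2: float, fit1: Fit4PL, fit2: Fit4PL,
                   full: bool = False):
    """Loewe-additivity expected effect at dose pair (d1, d2), in fa %.

    Solves d1/D1(E) + d2/D2(E) = 1 for the effect fraction E by bracketed
    bisection, where Di(E) inverts agent i's fitted curve on the
    fraction-affected scale.  When agent i's plateau prevents reaching E its
    reciprocal term is treated as 0 (its dose requirement is infinite).  If
    even the maximum jointly attainable effect leaves the dose sum above 1,
    the expected effect is capped at that maximum and flagged.

    Returns the effect in percent, or ``(effect, capped)`` with ``full=True``.
    """
    _require_converged(fit1, fit2)
    if d1 < 0 or d2 < 0:
        raise ValueError("doses must be non-negative")
    if d1 == 0 and d2 == 0:
        return (0.0, False) if full else 0.0
    if d2 == 0:
        e = fraction_affected(fit1, d1)
        return (e, False) if full else e
    if d1 == 0:
        e = fraction_affected(fit2, d2)
        return (e, False) if full else e

    def dose_sum(e_frac: float) -> float:
        total = 0.0
        for d, fit in ((d1, fit1), (d2, fit2)):
            need = _dose_for_effect(fit, e_frac)
            if need is not None:
                total += d / need
        return total

    # effect of each single agent at its component dose (fraction scale)
    e1 = fraction_affected(fit1, d1) / 100.0
    e2 = fraction_affected(fit2, d2) / 100.0
    # bracket within (0, 1): icx inverts fa only on the open unit interval
    lo = max(e1, e2, 1e-12)
    # maximum fa attainable by either agent (plateau bound)
    hi = min(max(1.0 - fit1.bottom / 100.0, 1.0 - fit2.bottom / 100.0),
             1.0) - 1e-12
    if lo >= hi:
        e = 100.0 * lo
        return (e, True) if full else e
    if dose_sum(hi) >= 1.0:
        # even the joint plateau is "affordable": expected effect capped
        e = 100.0 * hi
        return (e, True) if full else e
    a, b = lo, hi   # dose_sum(a) >= 1 >= dose_sum(b), dose_sum decreasing
    while b - a > LOEWE_TOL:
        mid = 0.5 * (a + b)
        if dose_sum(mid) >= 1.0:
            a = mid
        else:
            b = mid
    e = 100.0 * 0.5 * (a + b)
    return (e, False) if full else e


def combination_ci(design: CombinationDesign, combo_viability,
                   fit1: Fit4PL, fit2: Fit4PL,
                   levels=CI_LEVELS) -> list[CombinationIndexResult]:
    """Chou-Talalay CI of a fixed-ratio combination at the given effect
    levels.

    A 4PL is fitted to the combination's viability along the drug-1 dose
    axis; for each level x the combination dose D1 achieving x is read from
    that fit, D2 = ratio * D1, and the single-agent (Dx)1 and (Dx)2 come
    from the agents' own fits.  A level unreachable on any of the three
    curves yields a per-level unreachable marker rather than a failure.
    """
    if not design.fixed_ratio:
        raise ValueError("CI requires a fixed-ratio design")
    _require_converged(fit1, fit2)
    ratio = design.ratio
    combo_fit = fit_4pl(design.doses1_nM, np.asarray(combo_viability,
                                                    dtype=float))
    out = []
    for x in levels:
        rc = icx(combo_fit, x, mode="absolute")
        r1 = icx(fit1, x, mode="absolute")
        r2 = icx(fit2, x, mode="absolute")
        if not (rc.reachable and r1.reachable and r2.reachable):
            out.append(CombinationIndexResult(x, None, None,
                                              r1.dose_nM, r2.dose_nM,
                                              None, None, reachable=False))
            continue
        D1 = rc.dose_nM
        D2 = ratio * D1
        ci = ci_value(D1, r1.dose_nM, D2, r2.dose_nM)
        out.append(CombinationIndexResult(x, D1, D2, r1.dose_nM, r2.dose_nM,
                                          ci, classify_ci(ci), reachable=True))
    return out


def synergy_matrix(doses1_nM, doses2_nM, observed_effect,
                   fit1: Fit4PL, fit2: Fit4PL, model: str = "loewe",
                   ) -> SynergyMatrix:
    """Per-cell synergy scores over a dose x dose grid.

    ``observed_effect`` is the measured effect (fa %) with shape
    (len(doses1), len(doses2)); the expected surface is computed under the
    chosen null model and delta = observed - expected.  The summary reports
    the mean delta and the peak delta with its cell coordinates
    (deterministic: ties broken by first row-major occurrence).
    """
    if model not in ("loewe", "hsa"):
        raise ValueError(f"unknown synergy model {model!r}")
    _require_converged(fit1, fit2)
    d1 = np.asarray(doses1_nM, dtype=float)
    d2 = np.asarray(doses2_nM, dtype=float)
    obs = np.asarray(observed_effect, dtype=float)
    if obs.shape != (d1.size, d2.size):
        raise ValueError("observed matrix shape must be (len(doses1), "
                         "len(doses2))")
    expected = np.empty_like(obs)
    for i, a in enumerate(d1):
        for j, b in enumerate(d2):
            if model == "loewe":
                expected[i, j] = loewe_expected(a, b, fit1, fit2)
            else:
                expected[i, j] = hsa_expected(a, b, fit1, fit2)
    delta = obs - expected
    peak_flat = int(np.argmax(delta))
    peak_cell = np.unravel_index(peak_flat, delta.shape)
    return SynergyMatrix(d1, d2, obs, expected, delta, model,
                         mean_delta=float(delta.mean()),
                         peak_delta=float(delta[peak_cell]),
                         peak_cell=(int(peak_cell[0]), int(peak_cell[1])))
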