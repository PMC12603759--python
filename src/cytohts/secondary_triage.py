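"""Secondary-screen triage: dose profiles and the three-filter cascade.

Candidates from the primary screen are retested at a four-dose ladder in a
tumor line and a matched control fibroblast line.  Per-dose "cell
suppression" (0% = vehicle behaviour, 100% = complete suppression) is
computed either from the endpoint viability assay (vehicle-relative RLU
loss) or from an imaging metric (control-based normalized effect).  Three
strict filters are applied, all of which must pass:

* selectivity — tumor-minus-control suppression > 40 percentage points at
  two or more doses (not necessarily adjacent);
* efficacy — tumor suppression at the highest dose > 50%;
* off-target safety — control suppression at the highest dose < 50%.

Boundary equality fails every filter (the inequalities are strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .primary_screen import normalize_control_based, robust_mean

SELECK_LADDER_NM = (50.0, 200.0, 650.0, 2000.0)
NIH_LADDER_NM = (125.0, 500.0, 1600.0, 5000.0)

DEFAULT_SELECTIVITY_DELTA = 40.0
DEFAULT_MIN_DOSES = 2
DEFAULT_EFFICACY_CUTOFF = 50.0
DEFAULT_SAFETY_CUTOFF = 50.0


@dataclass
class DoseProfile:
    """Per-dose suppression of one compound in one cell line."""

    compound_id: str
    cell_line: str
    metric_kind: str
    doses_nM: np.ndarray = field(default=None)
    suppression_percent: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.doses_nM = np.asarray(self.doses_nM, dtype=float)
        self.suppression_percent = np.asarray(self.suppression_percent,
                                              dtype=float)
        if self.doses_nM.size != self.suppression_percent.size:
            raise ValueError("dose/suppression length mismatch")
        if np.any(np.diff(self.doses_nM) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(self.suppression_percent > 100.0 + 1e-9):
            raise ValueError("suppression cannot exceed 100%")


def suppression_from_viability(rlu, vehicle_rlu) -> np.ndarray | float:
    """Viability loss vs vehicle: 100 * (1 - rlu / median(vehicle)).

    Values above the vehicle median give negative suppression (growth
    stimulation); a dead well (rlu = 0) gives exactly 100%.
    """
    med = robust_mean(np.asarray(vehicle_rlu, dtype=float))
    if med <= 0:
        raise ValueError("vehicle median RLU must be positive")
    return 100.0 * (1.0 - np.asarray(rlu, dtype=float) / med)


def suppression_from_imaging(values, vehicle_values, positive_values):
    """Control-based normalized effect: vehicle = 0%, positive control = 100%."""
    return normalize_control_based(values, vehicle_values, positive_values)


def _check_matching(tumor: DoseProfile, control: DoseProfile) -> None:
    if tumor.metric_kind != control.metric_kind:
        raise ValueError("metric_kind mismatch between profiles")
    if (tumor.doses_nM.size != control.doses_nM.size
            or not np.allclose(tumor.doses_nM, control.doses_nM)):
        raise ValueError("dose-ladder mismatch between profiles")


def selectivity_filter(tumor: DoseProfile, control: DoseProfile,
                       delta: float = DEFAULT_SELECTIVITY_DELTA,
                       min_doses: int = DEFAULT_MIN_DOSES) -> bool:
    """Tumor-minus-control suppression strictly above *delta* points at
    *min_doses* or more doses."""
    _check_matching(tumor, control)
    diffs = tumor.suppression_percent - control.suppression_percent
    return int(np.sum(diffs > delta)) >= min_doses


def efficacy_filter(tumor: DoseProfile,
                    cutoff: float = DEFAULT_EFFICACY_CUTOFF) -> bool:
    """Tumor suppression at the highest dose strictly above *cutoff*."""
    if tumor.doses_nM.size == 0:
        raise ValueError("empty profile")
    return bool(tumor.suppression_percent[-1] > cutoff)


def safety_filter(control: DoseProfile,
                  cutoff: float = DEFAULT_SAFETY_CUTOFF) -> bool:
    """Control suppression at the highest dose strictly below *cutoff*."""
    if control.doses_nM.size == 0:
        raise ValueError("empty profile")
    return bool(control.suppression_percent[-1] < cutoff)


def triage(profiles: pd.DataFrame, metric_kind: str,
           tumor_line: str, control_line: str,
           delta: float = DEFAULT_SELECTIVITY_DELTA,
           min_doses: int = DEFAULT_MIN_DOSES,
           efficacy_cutoff: float = DEFAULT_EFFICACY_CUTOFF,
           safety_cutoff: float = DEFAULT_SAFETY_CUTOFF) -> pd.DataFrame:
    """Apply the filter cascade to every candidate in a suppression table.

    *profiles* is long format with columns compound_id, cell_line,
    metric_kind, dose_nM, suppression_percent; replicate rows per
    (compound, cell line, dose) are aggregated by median first.  Every
    candidate must have both a tumor and a control profile for the metric.

    Returns one row per compound with the three booleans, the conjunction,
    and the per-dose tumor-minus-control difference vector, ordered by
    compound_id.
    """
    sub = profiles[profiles.metric_kind == metric_kind]
    agg = (sub.groupby(["compound_id", "cell_line", "dose_nM"], as_index=False)
           .agg(suppression_percent=("suppression_percent", "median")))
    rows = []
    for cid in sorted(agg.compound_id.unique()):
        prof = {}
        for line in (tumor_line, control_line):
            g = agg[(agg.compound_id == cid)
                    & (agg.cell_line == line)].sort_values("dose_nM")
            if g.empty:
                raise ValueError(
                    f"missing {line} profile for compound {cid}")
            prof[line] = DoseProfile(cid, line, metric_kind,
                                     g.dose_nM.to_numpy(),
                                     g.suppression_percent.to_numpy())
        t, c = prof[tumor_line], prof[control_line]
        sel = selectivity_filter(t, c, delta, min_doses)
        eff = efficacy_filter(t, efficacy_cutoff)
        saf = safety_filter(c, safety_cutoff)
        rows.append({
            "compound_id": cid, "metric_kind": metric_kind,
            "selectivity_pass": sel, "efficacy_pass": eff,
            "safety_pass": saf, "overall": sel and eff and saf,
            "diff_vector": (t.suppression_percent
                            - c.suppression_percent).round(6).tolist(),
        })
    return pd.DataFrame(rows)
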