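"""Seeded synthetic-data generators with known ground truth.

The generators emulate the geometry and noise structure of a live-cell
dual-dye cytotoxicity screen so that every downstream module can be
exercised against planted truth:

* :func:`simulate_primary_plate` — 384-well plates (controls in the first
  two columns, library elsewhere), timepoints 0/24/48/72 h, 4 imaging
  fields per well.  Per-well death kinetics follow the saturating
  exponential f(t) = f_max * (1 - exp(-k t)); live-stain counts are Poisson
  around exponential cell growth and dead-stain counts Binomial(tracker,
  f(t)).  Planted actives get an f_max elevated by ``effect_sigma``
  null-population standard deviations.
* :func:`simulate_secondary_screen` — per-dose suppression profiles for a
  candidate set in a tumor and a control line, with archetype compounds
  (selective hits, pan-toxic, inactive, weakly selective, off-target-toxic)
  and planted pan-filter passers.
* :func:`simulate_dose_response` / :func:`simulate_combination_matrix` —
  viability series from known 4PL parameters, and combination matrices
  generated exactly under a chosen null model (Loewe, HSA, Bliss) or with a
  planted synergy boost.

All generators are pure functions of their spec including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dose_response import Fit4PL, four_pl
from .screen_data import ScreenDataset
from .synergy import fraction_affected, hsa_expected, loewe_expected

ROWS = "ABCDEFGHIJKLMNOP"
DEFAULT_TIMEPOINTS = (0.0, 24.0, 48.0, 72.0)
#: cells seeded per well in the assay's cell-line presets
CELLS_SEEDED_PRESETS = {"NS-poly": 400, "Lf": 600, "Moffitt-ns": 900}
PRIMARY_DOSE_NM = 5000.0   # single-dose primary screen at 5 uM


@dataclass
class PlateSimSpec:
    """Conditions of a simulated primary screen."""

    n_compounds: int = 2600
    active_fraction: float = 0.05
    effect_sigma: float = 8.0          # planted shift, null-SD units of f_max
    cells_seeded: int = 400
    cell_line: str = "NS-poly"
    timepoints: tuple = DEFAULT_TIMEPOINTS
    fields_per_well: int = 4
    n_vehicle: int = 16                # per plate
    n_positive: int = 16               # per plate
    positive_conc_nM: float = 100.0    # paclitaxel dose; assay parameter
    null_fmax_mean: float = 0.10
    null_fmax_sd: float = 0.02
    null_k: float = 0.06               # 1/h, death-rate constant
    positive_fmax: float = 0.75
    growth_doubling_h: float = 32.0
    with_luminescence: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must be in [0, 1]")
        if self.cells_seeded <= 0:
            raise ValueError("cells_seeded must be positive")


@dataclass
class CurveSimSpec:
    """Known-truth 4PL viability series."""

    bottom: float = 0.0
    top: float = 100.0
    log_ic50: float = 2.0           # log10 nM
    hill: float = 1.0
    doses_nM: tuple = tuple(float(10 ** e) for e in range(0, 8))  # 1 nM..10 mM span
    replicates: int = 4
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.doses_nM):
            raise ValueError("doses must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class MatrixSimSpec:
    """Known-truth combination matrix under a chosen interaction model."""

    model: str = "loewe"            # loewe | hsa | bliss | boosted_synergy
    fit1: Fit4PL = None
    fit2: Fit4PL = None
    doses1_nM: tuple = tuple(float(10 ** e) for e in range(0, 5))
    doses2_nM: tuple = tuple(float(10 ** e) for e in range(0, 5))
    interaction_strength: float | None = None   # effect points, boosted_synergy
    boost_cells: tuple = ((2, 2),)  # grid cells receiving the boost
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("loewe", "hsa", "bliss", "boosted_synergy"):
            raise ValueError(f"unknown interaction model {self.model!r}")
        if self.model == "boosted_synergy" and self.interaction_strength is None:
            raise ValueError("boosted_synergy requires interaction_strength")


def _well_name(i: int) -> str:
    return f"{ROWS[i // 24]}{i % 24 + 1}"


def simulate_primary_plate(spec: PlateSimSpec) -> ScreenDataset:
    """Simulate a multi-plate primary screen with planted actives.

    Controls occupy columns 1 (vehicle) and 2 (positive control, a
    paclitaxel-like strong killer); library compounds fill the remaining
    wells, one compound per well at the fixed screening dose.  Ground-truth
    active labels, per-well kinetic parameters and the spec itself are
    recorded in the dataset metadata.
    """
    rng = np.random.default_rng(spec.seed)
    lib_per_plate = 16 * 24 - spec.n_vehicle - spec.n_positive
    n_plates = int(np.ceil(spec.n_compounds / lib_per_plate))
    n_active = int(round(spec.n_compounds * spec.active_fraction))
    active_ids = set(rng.choice(spec.n_compounds, size=n_active,
                                replace=False).tolist())

    t = np.asarray(spec.timepoints, dtype=float)
    seeded_per_field = spec.cells_seeded / spec.fields_per_well
    growth = 2.0 ** (t / spec.growth_doubling_h)

    ann_rows, img_rows, lum_rows = [], [], []
    truth = {}
    cid = 0
    for p in range(n_plates):
        plate = f"SIM{p + 1}"
        wells = [_well_name(i) for i in range(384)]
        roles = (["vehicle"] * spec.n_vehicle
                 + ["positive_control"] * spec.n_positive
                 + ["library"] * lib_per_plate)
        for well, role in zip(wells, roles):
            compound = np.nan
            conc = np.nan
            if role == "library":
                if cid >= spec.n_compounds:
                    role = "empty"
                else:
                    compound = f"CMPD{cid:04d}"
                    conc = PRIMARY_DOSE_NM
            elif role == "positive_control":
                conc = spec.positive_conc_nM
            ann_rows.append({"plate_id": plate, "well": well, "role": role,
                             "compound_id": compound,
                             "concentration_nM": conc,
                             "cell_line": spec.cell_line})
            if role == "empty":
                continue
            # per-well kinetics
            if role == "positive_control":
                f_max = spec.positive_fmax * rng.normal(1.0, 0.05)
                k = 0.08
            elif role == "library" and cid in active_ids:
                f_max = (spec.null_fmax_mean
                         + spec.effect_sigma * spec.null_fmax_sd
                         + rng.normal(0.0, spec.null_fmax_sd))
                k = spec.null_k * rng.normal(1.0, 0.05)
            else:  # vehicle wells behave like inactive library wells
                f_max = spec.null_fmax_mean + rng.normal(0.0, spec.null_fmax_sd)
                k = spec.null_k * rng.normal(1.0, 0.05)
            f_max = float(np.clip(f_max, 0.005, 0.98))
            if role == "library":
                truth[compound] = {"active": cid in active_ids,
                                   "f_max": f_max, "k": k}
                cid += 1
            f_t = np.clip(f_max * (1.0 - np.exp(-k * t)), 0.0, 1.0)
            for fld in range(1, spec.fields_per_well + 1):
                tracker = rng.poisson(seeded_per_field * growth)
                draq7 = rng.binomial(tracker, f_t)
                for ti, tr, dr in zip(t, tracker, draq7):
                    img_rows.append({"plate_id": plate, "well": well,
                                     "field": fld, "timepoint_h": ti,
                                     "tracker_count": int(tr),
                                     "draq7_count": int(dr)})
            if spec.with_luminescence:
                live72 = spec.cells_seeded * growth[-1] * (1.0 - f_t[-1])
                rlu = max(0.0, 100.0 * live72 * rng.normal(1.0, 0.05))
                lum_rows.append({"plate_id": plate, "well": well, "rlu": rlu})

    ds = ScreenDataset(
        annotations=pd.DataFrame(ann_rows),
        imaging=pd.DataFrame(img_rows),
        luminescence=pd.DataFrame(lum_rows) if spec.with_luminescence else None,
        metadata={"generator": "simulate_primary_plate",
                  "spec": asdict(spec), "seed": spec.seed, "truth": truth},
    )
    return ds


# ------------------------------------------------------------ secondary screen

#: archetype mean suppression profiles (tumor, control), ascending dose.
#: Margins to every filter boundary are >= 8 points so that small
#: measurement noise cannot flip a decision.
_SECONDARY_ARCHETYPES = {
    "planted":   ([65.0, 78.0, 88.0, 95.0], [5.0, 10.0, 15.0, 25.0]),
    "pan_toxic": ([60.0, 75.0, 85.0, 95.0], [50.0, 65.0, 80.0, 90.0]),
    "inactive":  ([0.0, 2.0, 5.0, 10.0], [0.0, 1.0, 3.0, 5.0]),
    "weak_selective": ([15.0, 25.0, 40.0, 58.0], [2.0, 5.0, 12.0, 8.0]),
    "low_efficacy":   ([10.0, 20.0, 30.0, 40.0], [2.0, 4.0, 6.0, 8.0]),
    "off_target":     ([70.0, 80.0, 90.0, 95.0], [10.0, 20.0, 35.0, 58.0]),
}


def simulate_secondary_screen(n_compounds: int = 104, n_planted: int = 3,
                              doses_nM=(50.0, 200.0, 650.0, 2000.0),
                              tumor_line: str = "Moffitt-ns",
                              control_line: str = "Lf",
                              metric_kind: str = "ctg",
                              replicates: int = 2,
                              noise_sd: float = 1.5,
                              seed: int = 0) -> tuple[pd.DataFrame, list[str]]:
    """Simulate a secondary-screen suppression table with planted passers.

    Exactly ``n_planted`` compounds follow the pan-filter-passing archetype
    (selective, efficacious, safe); the rest are drawn from failing
    archetypes whose mean profiles keep a comfortable margin from every
    filter boundary.  Returns the long-format suppression table and the
    sorted list of planted compound ids.
    """
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses_nM, dtype=float)
    failing = [k for k in _SECONDARY_ARCHETYPES if k != "planted"]
    planted_idx = set(rng.choice(n_compounds, size=n_planted,
                                 replace=False).tolist())
    rows = []
    planted_ids = []
    for i in range(n_compounds):
        cid = f"SEC{i:03d}"
        if i in planted_idx:
            arch = "planted"
            planted_ids.append(cid)
        else:
            arch = failing[int(rng.integers(len(failing)))]
        tumor_mu, control_mu = _SECONDARY_ARCHETYPES[arch]
        for line, mus in ((tumor_line, tumor_mu), (control_line, control_mu)):
            for dose, mu in zip(doses, mus):
                for rep in range(replicates):
                    s = min(100.0, mu + rng.normal(0.0, noise_sd))
                    rows.append({"compound_id": cid, "cell_line": line,
                                 "metric_kind": metric_kind,
                                 "dose_nM": float(dose), "replicate": rep,
                                 "suppression_percent": s,
                                 "archetype": arch})
    return pd.DataFrame(rows), sorted(planted_ids)


# ---------------------------------------------------------------- dose response

def simulate_dose_response(spec: CurveSimSpec) -> pd.DataFrame:
    """Viability series from known 4PL truth, Gaussian noise, truncated to
    the instrument-plausible range [-20, 150]."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for rep in range(spec.replicates):
        for d in spec.doses_nM:
            y = four_pl(d, spec.bottom, spec.top, spec.log_ic50, spec.hill)
            y = y + rng.normal(0.0, spec.noise_sd) if spec.noise_sd else float(y)
            rows.append({"dose_nM": float(d), "replicate": rep,
                         "viability_percent": float(np.clip(y, -20.0, 150.0))})
    return pd.DataFrame(rows)


def sham_combination(fit: Fit4PL, doses_nM, ratio: float = 1.0,
                     noise_sd: float = 0.0, replicates: int = 1,
                     seed: int = 0) -> pd.DataFrame:
    """A drug "combined" with itself at a fixed ratio.

    The combination's observed viability at (d1, ratio*d1) is the single
    agent's curve evaluated at the total dose d1*(1+ratio) — the exact
    additivity case, so any correct combination-index implementation must
    return CI = 1 on this design.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        for d1 in np.asarray(doses_nM, dtype=float):
            total = d1 * (1.0 + ratio)
            y = float(four_pl(total, *fit.params()))
            if noise_sd:
                y += rng.normal(0.0, noise_sd)
            rows.append({"dose1_nM": d1, "dose2_nM": ratio * d1,
                         "replicate": rep, "viability_percent": y})
    return pd.DataFrame(rows)


# ----------------------------------------------------------- combination matrix

def _bliss_expected(d1, d2, fit1, fit2) -> float:
    e1 = max(0.0, fraction_affected(fit1, d1)) / 100.0
    e2 = max(0.0, fraction_affected(fit2, d2)) / 100.0
    return 100.0 * (e1 + e2 - e1 * e2)


def simulate_combination_matrix(spec: MatrixSimSpec,
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Observed effect matrix (fa %) generated under the chosen model.

    Returns ``(observed, truth_expected)``; under ``boosted_synergy`` the
    truth surface is Loewe-additive plus ``interaction_strength`` effect
    points added in ``boost_cells``.
    """
    rng = np.random.default_rng(spec.seed)
    d1 = np.asarray(spec.doses1_nM, dtype=float)
    d2 = np.asarray(spec.doses2_nM, dtype=float)
    truth = np.empty((d1.size, d2.size))
    for i, a in enumerate(d1):
        for j, b in enumerate(d2):
            if spec.model == "hsa":
                truth[i, j] = hsa_expected(a, b, spec.fit1, spec.fit2)
            elif spec.model == "bliss":
                truth[i, j] = _bliss_expected(a, b, spec.fit1, spec.fit2)
            else:  # loewe and boosted_synergy share the additive base
                truth[i, j] = loewe_expected(a, b, spec.fit1, spec.fit2)
    if spec.model == "boosted_synergy":
        for (i, j) in spec.boost_cells:
            truth[i, j] += spec.interaction_strength
    observed = truth.copy()
    if spec.noise_sd:
        observed = observed + rng.normal(0.0, spec.noise_sd, size=truth.shape)
    return observed, truth
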