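"""Primary-screen scoring: death-fraction kinetics, AUC, normalization, hits.

The raw response of the dual-dye assay is the dead/dying-cell fraction per
well — dead-stain (DRAQ7) object count over live-stain (cell tracker) count,
with the four imaging fields pooled by summing counts before taking the
ratio.  Three per-well metrics derive from it:

* ``auc`` — trapezoidal area under the death-fraction time course
  (fraction·hours over 0–72 h);
* ``final_timepoint`` — the death fraction at the last timepoint;
* ``ctg`` — endpoint luminescent viability (RLU), when measured.

Compound activity is normalized either to the test population (vehicle
anchored at 0% effect) or to the control window (vehicle = 0%, positive
control = 100%), then hit-called by robust Z-score with the convention that
stronger cell killing is more negative; hits satisfy Z < -3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screen_data import ScreenDataset

DEFAULT_HIT_THRESHOLD = -3.0
#: metrics on which a larger raw value means more killing
DEATH_ORIENTED_METRICS = ("auc", "final_timepoint")


class UndefinedFractionError(ZeroDivisionError):
    """Pooled live-stain count is zero; the death fraction is undefined.

    Carries a QC flag: wells raising this should appear as ``zero_tracker``
    entries in the dataset validation report.
    """


class DegeneratePopulationError(ValueError):
    """Spread estimators (MAD and IQR) are both zero; Z-scores undefined."""


@dataclass
class DeathFractionSeries:
    """Pooled dead/dying fraction of one well at each timepoint."""

    plate_id: str
    well: str
    timepoints: np.ndarray  # hours, strictly increasing
    fractions: np.ndarray   # >= 0; > 1 permitted but QC-worthy

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.fractions < 0):
            raise ValueError("fractions must be non-negative")


def well_death_fraction(draq7_counts, tracker_counts) -> float:
    """Pooled death fraction for one (well, timepoint).

    Counts from all fields are summed before the ratio is taken, so a single
    sparse field cannot produce an infinite per-field ratio.
    """
    d = np.asarray(draq7_counts, dtype=float)
    t = np.asarray(tracker_counts, dtype=float)
    if d.size == 0:
        raise ValueError("no field records supplied")
    pooled_t = t.sum()
    if pooled_t <= 0:
        raise UndefinedFractionError(
            "pooled tracker count is zero (QC flag: zero_tracker)")
    return float(d.sum() / pooled_t)


def death_series(ds: ScreenDataset, plate_id: str, well: str,
                 timepoints=None) -> DeathFractionSeries:
    """Ordered pooled death-fraction series for one well.

    Every configured timepoint must be present; missing timepoints raise
    rather than being interpolated (interpolation would bias the AUC).
    """
    sub = ds.imaging[(ds.imaging.plate_id == plate_id)
                     & (ds.imaging.well == well)]
    if sub.empty:
        raise KeyError(f"no imaging records for ({plate_id}, {well})")
    pooled = (sub.groupby("timepoint_h", as_index=False)
              .agg(draq7=("draq7_count", "sum"),
                   tracker=("tracker_count", "sum"))
              .sort_values("timepoint_h"))
    if timepoints is not None:
        missing = sorted(set(float(t) for t in timepoints)
                         - set(pooled.timepoint_h))
        if missing:
            raise ValueError(
                f"incomplete series for ({plate_id}, {well}): missing {missing}")
    if (pooled.tracker <= 0).any():
        raise UndefinedFractionError(
            f"zero pooled tracker count in ({plate_id}, {well})")
    return DeathFractionSeries(plate_id, well,
                               pooled.timepoint_h.to_numpy(),
                               (pooled.draq7 / pooled.tracker).to_numpy())


def auc_trapezoid(series: DeathFractionSeries) -> float:
    """Trapezoidal integral of the death fraction over hours.

    No baseline subtraction by default; pass a baseline-shifted series if
    t=0 subtraction is wanted.
    """
    if series.timepoints.size < 2:
        raise ValueError("AUC requires at least 2 timepoints")
    return float(np.trapezoid(series.fractions, series.timepoints))


def all_death_series(ds: ScreenDataset, timepoints=None) -> pd.DataFrame:
    """Pooled death fractions for every well, long format."""
    pooled = (ds.imaging.groupby(["plate_id", "well", "timepoint_h"],
                                 as_index=False)
              .agg(draq7=("draq7_count", "sum"),
                   tracker=("tracker_count", "sum")))
    if (pooled.tracker <= 0).any():
        bad = pooled[pooled.tracker <= 0][["plate_id", "well"]]
        raise UndefinedFractionError(
            f"zero pooled tracker counts in wells {bad.values.tolist()[:5]}")
    pooled["fraction"] = pooled.draq7 / pooled.tracker
    return pooled


def well_metrics(ds: ScreenDataset, baseline_subtract: bool = False,
                 ) -> pd.DataFrame:
    """Per-well raw metrics: AUC, final-timepoint fraction and (if
    luminescence was measured) the CTG endpoint RLU.

    Returns a long table with columns plate_id, well, metric_kind, raw_value.
    """
    frames = []
    pooled = all_death_series(ds)
    for (plate, well), grp in pooled.groupby(["plate_id", "well"]):
        grp = grp.sort_values("timepoint_h")
        frac = grp.fraction.to_numpy()
        t = grp.timepoint_h.to_numpy()
        if baseline_subtract:
            frac = frac - frac[0]
        frames.append({"plate_id": plate, "well": well, "metric_kind": "auc",
                       "raw_value": float(np.trapezoid(frac, t))})
        frames.append({"plate_id": plate, "well": well,
                       "metric_kind": "final_timepoint",
                       "raw_value": float(frac[-1])})
    out = pd.DataFrame(frames)
    if ds.luminescence is not None:
        lum = ds.luminescence.rename(columns={"rlu": "raw_value"}).copy()
        lum["metric_kind"] = "ctg"
        out = pd.concat([out, lum[["plate_id", "well", "metric_kind",
                                   "raw_value"]]], ignore_index=True)
    return out


# ---------------------------------------------------------------- robust stats

def robust_mean(x) -> float:
    """Robust location estimate: the median."""
    return float(np.median(np.asarray(x, dtype=float)))


def robust_sd(x) -> float:
    """Robust spread: 1.4826*MAD, falling back to IQR/1.349 when MAD = 0."""
    x = np.asarray(x, dtype=float)
    mad = np.median(np.abs(x - np.median(x)))
    if mad > 0:
        return float(1.4826 * mad)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr > 0:
        return float(iqr / 1.349)
    raise DegeneratePopulationError("MAD and IQR both zero")


def effect_vs_vehicle(x, vehicle_values) -> np.ndarray | float:
    """Activity relative to vehicle: observed minus robust vehicle mean."""
    v = np.asarray(vehicle_values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 vehicle wells")
    return np.asarray(x, dtype=float) - robust_mean(v)


def normalize_control_based(x, vehicle_values, positive_values):
    """Scale activity to the control window: vehicle -> 0%, positive -> 100%."""
    v = robust_mean(np.asarray(vehicle_values, dtype=float))
    p = robust_mean(np.asarray(positive_values, dtype=float))
    if p == v:
        raise ValueError("zero control window: vehicle and positive "
                         "robust means are equal")
    return 100.0 * (np.asarray(x, dtype=float) - v) / (p - v)


def robust_zscores(values, orient_killing_negative: bool = True,
                   death_oriented: bool = True) -> np.ndarray:
    """Robust Z-scores over the library population.

    z_i = (x_i - median(x)) / (1.4826 * MAD(x)).  By default the sign is
    flipped for death-oriented inputs so that stronger killing (larger death
    fraction or AUC) maps to a more negative Z, matching the Z < -3 hit rule
    on a viability-like scale.  Set ``orient_killing_negative=False`` for the
    raw orientation.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 library values for robust Z-scores")
    z = (x - robust_mean(x)) / robust_sd(x)
    if orient_killing_negative and death_oriented:
        z = -z
    return z


def call_hits(zscores: pd.Series | np.ndarray,
              threshold: float = DEFAULT_HIT_THRESHOLD,
              compound_ids=None) -> pd.DataFrame:
    """Strict-inequality hit calls, sorted by Z ascending."""
    z = np.asarray(zscores, dtype=float)
    if compound_ids is None:
        compound_ids = [f"c{i}" for i in range(z.size)]
    out = pd.DataFrame({"compound_id": list(compound_ids), "robust_z": z})
    out["is_hit"] = out.robust_z < threshold
    out["threshold"] = threshold
    return out.sort_values("robust_z", ignore_index=True)


def score_primary_screen(ds: ScreenDataset,
                         metric_kinds=("auc", "final_timepoint"),
                         scheme: str = "test_population",
                         per_plate: bool = True,
                         threshold: float = DEFAULT_HIT_THRESHOLD,
                         orient_killing_negative: bool = True,
                         ) -> pd.DataFrame:
    """End-to-end primary-screen scoring.

    For each metric: compute per-well raw values, normalize library-well
    activity under the chosen scheme (``test_population`` anchors vehicle at
    0% effect; ``control_based`` additionally anchors the positive control at
    100%), compute robust Z-scores over the library population (per plate by
    default, pooled otherwise) on the normalized activities, and call hits at
    the strict Z < threshold rule.

    Returns one row per (compound, metric) with raw value, effect percent,
    robust Z and the hit flag.
    """
    if scheme not in ("test_population", "control_based"):
        raise ValueError(f"unknown scheme {scheme!r}")
    metrics = well_metrics(ds)
    ann = ds.annotations
    merged = metrics.merge(ann, on=["plate_id", "well"], how="left")
    rows = []
    group_keys = ["metric_kind"] + (["plate_id"] if per_plate else [])
    for keys, grp in merged.groupby(group_keys):
        metric = keys[0] if isinstance(keys, tuple) else keys
        if metric not in metric_kinds and metric != "ctg":
            continue
        if metric not in metric_kinds:
            continue
        veh = grp.loc[grp.role == "vehicle", "raw_value"].to_numpy()
        pos = grp.loc[grp.role == "positive_control", "raw_value"].to_numpy()
        lib = grp[grp.role == "library"]
        if veh.size < 2 or lib.empty:
            continue
        x = lib.raw_value.to_numpy()
        if scheme == "control_based":
            if pos.size == 0:
                raise ValueError("control_based scheme needs positive controls")
            effect = normalize_control_based(x, veh, pos)
        else:
            effect = effect_vs_vehicle(x, veh)
        death_metric = metric in DEATH_ORIENTED_METRICS
        # CTG RLU already falls with killing; no flip needed there
        z = robust_zscores(effect,
                           orient_killing_negative=orient_killing_negative,
                           death_oriented=death_metric)
        for cid, raw, eff, zi in zip(lib.compound_id, x, effect, z):
            rows.append({"compound_id": cid, "metric_kind": metric,
                         "plate_id": lib.plate_id.iloc[0] if per_plate else "*",
                         "raw_value": raw, "effect_percent": eff,
                         "robust_z": zi, "is_hit": zi < threshold,
                         "threshold": threshold})
    return pd.DataFrame(rows).sort_values(
        ["metric_kind", "robust_z"], ignore_index=True)
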