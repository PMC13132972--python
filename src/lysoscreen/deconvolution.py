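"""Thermal-shift target deconvolution.

Protein melting is modelled by the standard plateau sigmoid used for
thermal proteome profiling data,

    f(T) = (1 - p) / (1 + exp(b - a/T)) + p,

with T in kelvin, slope parameter a (K), offset b (unitless) and plateau
p in [0, 0.5).  The melting temperature solves f(Tm) = 1/2 in closed form:

    Tm = a / (b - ln(0.5 / (0.5 - p))).

Fold changes are normalised to the lowest temperature.  Curves are fitted
per protein and condition by seeded multi-start nonlinear least squares;
ΔTm = Tm(treated) − Tm(vehicle) and a protein is called stabilized when
ΔTm strictly exceeds the shift threshold (default 2 °C) with both fits
passing the R² quality floor.  The same fitter serves dense (10-point,
37–67 °C) proteome-wide data and sparse (7-point, 37–61 °C) single-protein
thermal shift data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

CELSIUS_TO_KELVIN = 273.15
DEFAULT_SHIFT_THRESHOLD_C = 2.0
DEFAULT_R2_FLOOR = 0.8
#: proteome-wide default grid: 10 aliquots spanning 37-67 °C
DEFAULT_TPP_TEMPS_C = tuple(np.linspace(37.0, 67.0, 10))
#: single-protein assay grid: 7 temperatures, 37-61 °C
DEFAULT_CETSA_TEMPS_C = (37.0, 41.0, 45.0, 49.0, 53.0, 57.0, 61.0)


def melt_model(temps_c: np.ndarray, a: float, b: float, p: float) -> np.ndarray:
    """Plateau sigmoid evaluated at temperatures in °C."""
    t_k = np.asarray(temps_c, dtype=float) + CELSIUS_TO_KELVIN
    return (1.0 - p) / (1.0 + np.exp(b - a / t_k)) + p


def tm_from_params(a: float, b: float, p: float) -> float:
    """Closed-form melting point (°C) of the plateau sigmoid; NaN if undefined."""
    if not (0.0 <= p < 0.5) or a <= 0:
        return float("nan")
    denom = b - np.log(0.5 / (0.5 - p))
    if denom <= 0:
        return float("nan")
    return a / denom - CELSIUS_TO_KELVIN


def params_for_tm(tm_c: float, a: float, p: float) -> float:
    """Offset b that places the melting point at ``tm_c`` given a and p."""
    return a / (tm_c + CELSIUS_TO_KELVIN) + float(np.log(0.5 / (0.5 - p)))


@dataclass(frozen=True)
class MeltCurve:
    """One protein/condition melt curve, normalised to the lowest temperature."""

    protein_id: str
    condition: str  # "vehicle" | "treated"
    temperatures: tuple[float, ...]  # °C, strictly increasing
    fold_changes: tuple[float, ...]

    def __post_init__(self) -> None:
        temps = np.asarray(self.temperatures, dtype=float)
        fc = np.asarray(self.fold_changes, dtype=float)
        if temps.size < 4:
            raise ValueError(
                f"{self.protein_id}/{self.condition}: need >= 4 temperature points, got {temps.size}"
            )
        if temps.size != fc.size:
            raise ValueError(f"{self.protein_id}: temperature/fold-change length mismatch")
        if np.any(np.diff(temps) <= 0):
            raise ValueError(f"{self.protein_id}: temperatures must be strictly increasing")
        if not np.all(np.isfinite(fc)):
            raise ValueError(f"{self.protein_id}/{self.condition}: non-finite fold changes")
        if fc[0] <= 0:
            raise ValueError(f"{self.protein_id}/{self.condition}: non-positive anchor fold change")
        # normalise to the lowest temperature so fc[0] == 1 by construction
        fc = fc / fc[0]
        object.__setattr__(self, "temperatures", tuple(temps))
        object.__setattr__(self, "fold_changes", tuple(fc))


@dataclass(frozen=True)
class MeltFit:
    protein_id: str
    condition: str
    tm: float  # °C; NaN when not converged
    slope_param: float  # a, kelvin
    offset_param: float  # b
    plateau: float  # p
    r_squared: float
    converged: bool


def fit_melt_curve(curve: MeltCurve, n_starts: int = 5, seed: int = 0) -> MeltFit:
    """Fit the plateau sigmoid to one melt curve by multi-start least squares.

    The start grid combines a data-driven guess (plateau from the hottest
    point, Tm from the half-height crossing) with seeded jitters.  The fit
    is flagged unconverged when the optimizer fails on every start, the
    plateau pins at 1/2, Tm falls outside [min T − 10, max T + 10] °C, or
    the data carry no decrease to fit.
    """
    temps = np.asarray(curve.temperatures)
    fc = np.asarray(curve.fold_changes)
    lo, hi = temps.min(), temps.max()

    p0_data = float(np.clip(fc.min(), 0.0, 0.45))
    # half-height crossing estimate for Tm
    half = (1.0 + p0_data) / 2.0
    below = np.nonzero(fc <= half)[0]
    tm0 = float(temps[below[0]]) if below.size else float((lo + hi) / 2)
    rng = np.random.default_rng(seed)
    starts = [(5.0e4, tm0, p0_data)]
    for a0 in (2.5e4, 7.5e4):
        starts.append((a0, tm0, p0_data))
    for _ in range(max(0, n_starts - len(starts))):
        starts.append(
            (
                float(rng.uniform(2e4, 9e4)),
                float(rng.uniform(lo, hi)),
                float(rng.uniform(0.0, 0.3)),
            )
        )

    bounds = ([1e3, 1e-6, 0.0], [5e5, 5e3, 0.499])
    best = None
    for a0, tm_guess, p0 in starts[:n_starts]:
        b0 = params_for_tm(np.clip(tm_guess, lo - 5, hi + 5), a0, max(p0, 1e-3))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    melt_model, temps, fc, p0=[a0, b0, p0],
                    bounds=bounds, maxfev=5000,
                )
        except (RuntimeError, ValueError):
            continue
        resid = fc - melt_model(temps, *popt)
        sse = float(np.sum(resid**2))
        if best is None or sse < best[1]:
            best = (popt, sse)

    if best is None:
        return MeltFit(curve.protein_id, curve.condition, float("nan"),
                       float("nan"), float("nan"), float("nan"), float("nan"), False)
    (a, b, p), sse = best
    sst = float(np.sum((fc - fc.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    tm = tm_from_params(a, b, p)
    converged = bool(
        np.isfinite(tm) and (lo - 10.0) <= tm <= (hi + 10.0) and p < 0.495 and np.isfinite(r2)
    )
    if not converged:
        tm = float("nan")
    return MeltFit(curve.protein_id, curve.condition, tm, float(a), float(b),
                   float(p), float(r2), converged)


def delta_tm(treated: MeltFit, vehicle: MeltFit, r2_floor: float = DEFAULT_R2_FLOOR) -> float:
    """Tm(treated) − Tm(vehicle) in °C; requires both fits converged and above QC."""
    for fit in (treated, vehicle):
        if not fit.converged:
            raise ValueError(f"{fit.protein_id}/{fit.condition}: unconverged melt fit")
        if fit.r_squared < r2_floor:
            raise ValueError(
                f"{fit.protein_id}/{fit.condition}: r2 {fit.r_squared:.3f} below QC floor {r2_floor}"
            )
    return treated.tm - vehicle.tm


def call_stabilized(delta: float, threshold: float = DEFAULT_SHIFT_THRESHOLD_C) -> bool:
    """Stabilized iff the melting-point shift strictly exceeds the threshold."""
    return bool(delta > threshold)


def intersect_targets(stabilized_ids: Iterable[str], predicted_ids: Iterable[str]) -> list[str]:
    """Shared targets: intersection of thermally stabilized and predicted ids, sorted."""
    return sorted(set(stabilized_ids) & set(predicted_ids))


def deconvolve(
    curves: pd.DataFrame,
    predicted_ids: Sequence[str] = (),
    threshold: float = DEFAULT_SHIFT_THRESHOLD_C,
    r2_floor: float = DEFAULT_R2_FLOOR,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit all melt curves and call stabilized / shared targets.

    ``curves`` is tidy with columns protein_id, condition, temperature_c,
    fold_change; both conditions are required per protein.  Proteins whose
    vehicle or treated fit fails convergence or QC get no call
    (stabilized = False, delta_tm = NaN) and are logged.

    Returns one row per protein: tm_vehicle, tm_treated, delta_tm,
    r2_vehicle, r2_treated, callable, stabilized, in_predicted_list,
    shared_target.
    """
    required = {"protein_id", "condition", "temperature_c", "fold_change"}
    if not required.issubset(curves.columns):
        raise ValueError(f"curve table must have columns {sorted(required)}")
    predicted = set(predicted_ids)
    rows = []
    for pid, grp in curves.groupby("protein_id", sort=True):
        fits = {}
        for cond in ("vehicle", "treated"):
            sub = grp.loc[grp["condition"] == cond].sort_values("temperature_c")
            if sub.empty:
                raise ValueError(f"protein {pid!r}: missing condition {cond!r}")
            curve = MeltCurve(str(pid), cond, tuple(sub["temperature_c"]), tuple(sub["fold_change"]))
            fits[cond] = fit_melt_curve(curve, seed=seed)
        ok = all(
            f.converged and f.r_squared >= r2_floor for f in fits.values()
        )
        if ok:
            d = fits["treated"].tm - fits["vehicle"].tm
            stab = call_stabilized(d, threshold)
        else:
            logger.info("protein %s: no ΔTm call (fit failed QC)", pid)
            d, stab = float("nan"), False
        rows.append(
            {
                "protein_id": str(pid),
                "tm_vehicle": fits["vehicle"].tm,
                "tm_treated": fits["treated"].tm,
                "delta_tm": d,
                "r2_vehicle": fits["vehicle"].r_squared,
                "r2_treated": fits["treated"].r_squared,
                "callable": ok,
                "stabilized": stab,
                "in_predicted_list": str(pid) in predicted,
            }
        )
    out = pd.DataFrame(rows)
    out["shared_target"] = out["stabilized"] & out["in_predicted_list"]
    return out
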