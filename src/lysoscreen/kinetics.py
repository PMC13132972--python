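"""Quantitative binding and inhibition mechanism fits.

Three fitters live here:

* **ITC one-site fit** — per-injection heats are modelled by the Wiseman
  single-site isotherm with displacement-mode volume bookkeeping (constant
  cell volume; cell contents diluted by each injection) plus a constant
  dilution-heat offset.  Fitted parameters: K_D (μM), stoichiometry N,
  ΔH (kcal/mol) and the offset (μcal).
* **Inhibition-mode classification** — competitive, noncompetitive and
  uncompetitive Michaelis–Menten rate laws are fitted to untransformed
  rates and compared by small-sample AIC (AICc); the double-reciprocal
  (Lineweaver–Burk) per-inhibitor-level linear fits are reported as a
  diagnostic only, since an ATP-competitive inhibitor shows a common 1/v
  axis intercept (constant Vmax) across inhibitor concentrations.
* **Four-parameter-logistic IC50** — dose–response fit with the bottom
  bounded at 0; the Cheng–Prusoff relation Ki = IC50/(1 + [S]/Km) links
  the potency to the competitive inhibition constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

logger = logging.getLogger(__name__)

KCAL_TO_UCAL = 1.0e9
INHIBITION_MODES = ("competitive", "noncompetitive", "uncompetitive")
#: substrate (ATP) grid, μM
DEFAULT_S_GRID = (25.0, 50.0, 100.0)
#: inhibitor grid for fitting, μM (uninhibited control + two inhibitor doses)
DEFAULT_FIT_I_GRID = (0.0, 10.0, 15.0)
#: ten-point inhibitor dose grid for IC50 determination, μM
DEFAULT_DOSE_GRID = (0.0, 0.1, 1.0, 5.0, 10.0, 15.0, 25.0, 30.0, 100.0, 1000.0)


# --------------------------------------------------------------------------
# ITC
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ITCProtocol:
    """Titration protocol: one small discardable injection then 19 × 2 μL."""

    syringe_conc_um: float = 300.0
    cell_conc_um: float = 15.0
    cell_volume_ul: float = 300.0
    injection_volumes_ul: tuple[float, ...] = (0.2,) + (2.0,) * 19
    temperature_c: float = 25.0
    first_discardable: bool = True

    def __post_init__(self) -> None:
        if self.syringe_conc_um <= 0 or self.cell_conc_um <= 0:
            raise ValueError("concentrations must be positive")
        if self.cell_volume_ul <= 0 or any(v <= 0 for v in self.injection_volumes_ul):
            raise ValueError("volumes must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_ul)


@dataclass(frozen=True)
class BindingFit:
    kd_um: float
    n_sites: float
    dh_kcal_mol: float
    dilution_offset_ucal: float
    fit_rmse_ucal: float
    converged: bool
    identifiable: bool  # False when the isotherm adds nothing over a constant


def _bound_conc(n_sites: float, m_tot: float, x_tot: float, kd: float) -> float:
    """[complex] from the one-site quadratic, concentrations in consistent units."""
    sites = n_sites * m_tot
    s = sites + x_tot + kd
    disc = s * s - 4.0 * sites * x_tot
    return 0.5 * (s - np.sqrt(max(disc, 0.0)))


def itc_isotherm(
    kd_um: float,
    n_sites: float,
    dh_kcal_mol: float,
    protocol: ITCProtocol = ITCProtocol(),
    dilution_offset_ucal: float = 0.0,
) -> np.ndarray:
    """Expected heat (μcal) for each injection of the protocol.

    Displacement convention: the cell volume stays constant and each
    injection of volume v dilutes the current cell contents by (1 − v/V0)
    while delivering titrant at the syringe concentration.  The heat of
    injection i is ΔH·V0·([complex]_i − [complex]_{i−1}·(1 − v/V0)) plus
    the constant dilution offset.
    """
    if kd_um <= 0 or n_sites <= 0:
        raise ValueError("kd and stoichiometry must be positive")
    v0 = protocol.cell_volume_ul * 1e-6  # L
    kd = kd_um * 1e-6  # M
    m = protocol.cell_conc_um * 1e-6
    x = 0.0
    bound_prev = 0.0
    heats = np.empty(protocol.n_injections)
    for i, v_ul in enumerate(protocol.injection_volumes_ul):
        f = (v_ul * 1e-6) / v0
        m = m * (1.0 - f)
        x = x * (1.0 - f) + protocol.syringe_conc_um * 1e-6 * f
        bound = _bound_conc(n_sites, m, x, kd)
        dq_kcal = dh_kcal_mol * v0 * (bound - bound_prev * (1.0 - f))
        heats[i] = dq_kcal * KCAL_TO_UCAL + dilution_offset_ucal
        bound_prev = bound
    return heats


def fit_itc(
    heats_ucal: Sequence[float],
    protocol: ITCProtocol = ITCProtocol(),
    seed: int = 0,
) -> BindingFit:
    """One-site fit of an injection heat series by multi-start least squares.

    The first injection is discarded when the protocol marks it
    discardable.  Residuals are inverse-variance weighted under the
    relative-error noise model (per-injection SD proportional to the
    binding-heat magnitude with a 10%-of-maximum baseline floor, estimated
    from the data before fitting so the weights stay fixed).  Starts span
    a log grid of K_D values; N starts at 1 and ΔH/offset start from
    data-driven guesses.  ``identifiable`` is False when the binding model
    does not beat a constant-offset model on AICc (e.g. a buffer-only
    control titration), in which case K_D is meaningless.
    """
    heats = np.asarray(heats_ucal, dtype=float)
    if heats.size != protocol.n_injections:
        raise ValueError(
            f"expected {protocol.n_injections} heats for the protocol, got {heats.size}"
        )
    use = slice(1, None) if protocol.first_discardable else slice(None)
    y = heats[use]
    if y.size < 10:
        raise ValueError(f"need >= 10 usable injections, got {y.size}")

    offset0 = float(np.median(y[-3:]))
    # early injections bind nearly all delivered titrant
    v2 = protocol.injection_volumes_ul[1] * 1e-6
    moles_per_inj = protocol.syringe_conc_um * 1e-6 * v2
    dh0 = float((y[0] - offset0) / (moles_per_inj * KCAL_TO_UCAL))
    if dh0 == 0.0:
        dh0 = -1.0
    # fixed data-derived weights for the relative-error noise model
    dev = np.abs(y - offset0)
    weights = 1.0 / (dev + 0.1 * float(dev.max()) + 1e-12)

    def resid(theta: np.ndarray) -> np.ndarray:
        log_kd, n, dh, off = theta
        model = itc_isotherm(10.0**log_kd, n, dh, protocol, off)
        return (model[use] - y) * weights

    best = None
    for kd0 in (0.1, 1.0, 3.0, 10.0, 100.0):
        theta0 = np.array([np.log10(kd0), 1.0, dh0, offset0])
        try:
            sol = least_squares(
                resid, theta0,
                bounds=([-4.0, 1e-3, -1e3, -1e3], [4.0, 10.0, 1e3, 1e3]),
                max_nfev=4000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return BindingFit(float("nan"), float("nan"), float("nan"), float("nan"),
                          float("nan"), False, False)
    log_kd, n, dh, off = best.x
    sse_w = float(2.0 * best.cost)
    w2 = weights**2
    y_wmean = float(np.sum(w2 * y) / np.sum(w2))
    sse_const_w = float(np.sum((weights * (y - y_wmean)) ** 2))
    # the isotherm must beat a constant-offset model on AICc to count as
    # a binding signal; a buffer-only control fails this
    identifiable = bool(
        sse_const_w > 0 and _aicc(sse_w, y.size, 4) < _aicc(sse_const_w, y.size, 1) - 2.0
    )
    if not identifiable:
        logger.info("ITC fit: binding signal indistinguishable from constant heat; "
                    "kd unidentifiable")
    model_best = itc_isotherm(10.0**log_kd, n, dh, protocol, off)[use]
    rmse = float(np.sqrt(np.mean((model_best - y) ** 2)))
    return BindingFit(float(10.0**log_kd), float(n), float(dh), float(off),
                      rmse, bool(best.success), identifiable)


# --------------------------------------------------------------------------
# Michaelis–Menten inhibition
# --------------------------------------------------------------------------

def mm_rate(
    s_um: float | np.ndarray,
    i_um: float | np.ndarray,
    km_um: float,
    vmax: float,
    ki_um: float,
    mode: str,
) -> np.ndarray:
    """Michaelis–Menten rate under the selected inhibition mode."""
    s = np.asarray(s_um, dtype=float)
    i = np.asarray(i_um, dtype=float)
    if np.any(s < 0) or np.any(i < 0):
        raise ValueError("concentrations must be non-negative")
    alpha = 1.0 + i / ki_um
    if mode == "competitive":
        return vmax * s / (km_um * alpha + s)
    if mode == "noncompetitive":
        return vmax * s / ((km_um + s) * alpha)
    if mode == "uncompetitive":
        return vmax * s / (km_um + s * alpha)
    raise ValueError(f"unknown inhibition mode {mode!r}; expected one of {INHIBITION_MODES}")


@dataclass(frozen=True)
class InhibitionFit:
    km_um: float
    vmax: float
    ki_um: float
    mode: str
    model_scores: Mapping[str, float]  # AICc per mode; the call is the argmin
    lb_intercepts: Mapping[float, float]  # per-[I] 1/v-axis intercepts
    params_by_mode: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)


def _aicc(sse: float, n: int, k: int) -> float:
    sse = max(sse, 1e-300)
    aic = n * np.log(sse / n) + 2 * k
    corr = 2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.inf
    return float(aic + corr)


def fit_inhibition(rates: pd.DataFrame) -> InhibitionFit:
    """Classify the inhibition mode from an (S, I, rate) table.

    All three rate-law models are fitted to the untransformed rates and
    ranked by AICc; the winning mode's parameters are reported.  Requires
    at least 2 inhibitor levels and 3 substrate levels (default design:
    ATP at 25/50/100 μM with inhibitor at 0/10/15 μM).  Per-inhibitor
    Lineweaver–Burk straight lines are fitted to replicate-mean rates and
    their 1/v-axis intercepts returned as the mechanism diagnostic.
    """
    required = {"S_uM", "I_uM", "rate"}
    if not required.issubset(rates.columns):
        raise ValueError(f"rate table must have columns {sorted(required)}")
    s = rates["S_uM"].to_numpy(float)
    i = rates["I_uM"].to_numpy(float)
    v = rates["rate"].to_numpy(float)
    if len(np.unique(i)) < 2:
        raise ValueError("need >= 2 inhibitor levels")
    if len(np.unique(s)) < 3:
        raise ValueError("need >= 3 substrate levels")

    km0 = float(np.median(np.unique(s)))
    vmax0 = float(1.2 * v.max())
    scores: dict[str, float] = {}
    params: dict[str, tuple[float, float, float]] = {}
    for mode in INHIBITION_MODES:
        def resid(theta, mode=mode):
            km, vmax, ki = theta
            return mm_rate(s, i, km, vmax, ki, mode) - v

        best = None
        for ki0 in (1.0, 10.0, 100.0):
            sol = least_squares(
                resid, np.array([km0, vmax0, ki0]),
                bounds=([1e-6, 1e-9, 1e-6], [1e6, 1e9, 1e6]),
                max_nfev=4000,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        assert best is not None
        params[mode] = tuple(float(x) for x in best.x)  # type: ignore[assignment]
        scores[mode] = _aicc(2.0 * float(best.cost), len(v), 3)

    mode = min(scores, key=scores.get)  # type: ignore[arg-type]
    km, vmax, ki = params[mode]

    # Lineweaver–Burk diagnostic on replicate means, S > 0 only
    mask = s > 0
    means = (
        pd.DataFrame({"S_uM": s[mask], "I_uM": i[mask], "rate": v[mask]})
        .groupby(["I_uM", "S_uM"])["rate"].mean().reset_index()
    )
    intercepts: dict[float, float] = {}
    for lev, grp in means.groupby("I_uM"):
        if len(grp) < 2:
            continue
        slope, intercept = np.polyfit(1.0 / grp["S_uM"], 1.0 / grp["rate"], 1)
        intercepts[float(lev)] = float(intercept)

    return InhibitionFit(km, vmax, ki, mode, scores, intercepts, params)


# --------------------------------------------------------------------------
# Dose–response
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponseFit:
    ic50_um: float
    hill: float
    top: float
    bottom: float
    fit_rmse: float
    converged: bool


def four_parameter_logistic(
    dose_um: np.ndarray, ic50_um: float, hill: float, top: float, bottom: float
) -> np.ndarray:
    """4PL response; dose 0 evaluates exactly to ``top``."""
    dose = np.asarray(dose_um, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / ic50_um) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def fit_ic50(doses_um: Sequence[float], responses: Sequence[float]) -> DoseResponseFit:
    """Four-parameter-logistic IC50 fit (bottom bounded at >= 0).

    Needs at least 5 dose levels spanning the transition; the zero dose and
    the highest dose anchor the top and bottom plateaus.
    """
    doses = np.asarray(doses_um, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if doses.shape != resp.shape:
        raise ValueError("doses and responses must align")
    if len(np.unique(doses)) < 5:
        raise ValueError("need >= 5 dose levels")
    top0 = float(resp[doses == doses.min()].mean())
    bottom0 = float(max(resp[doses == doses.max()].mean(), 0.0))
    mid = (top0 + bottom0) / 2.0
    pos = doses[doses > 0]
    ic50_0 = float(pos[np.argmin(np.abs(resp[doses > 0] - mid))]) if pos.size else 1.0
    try:
        popt, _ = curve_fit(
            four_parameter_logistic, doses, resp,
            p0=[max(ic50_0, 1e-3), 1.0, top0, bottom0],
            bounds=([1e-6, 0.1, -np.inf, 0.0], [1e6, 10.0, np.inf, np.inf]),
            maxfev=10000,
        )
        converged = True
    except RuntimeError:
        return DoseResponseFit(*(float("nan"),) * 5, False)
    pred = four_parameter_logistic(doses, *popt)
    rmse = float(np.sqrt(np.mean((resp - pred) ** 2)))
    ic50, hill, top, bottom = (float(x) for x in popt)
    if top <= bottom:
        converged = False
    return DoseResponseFit(ic50, hill, top, bottom, rmse, converged)


def cheng_prusoff(ic50_um: float, s_um: float, km_um: float) -> float:
    """Competitive-inhibition constant Ki = IC50 / (1 + [S]/Km)."""
    if ic50_um <= 0 or km_um <= 0 or s_um < 0:
        raise ValueError("ic50 and km must be positive, substrate non-negative")
    return ic50_um / (1.0 + s_um / km_um)
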