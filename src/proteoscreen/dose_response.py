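"""Dose–response analysis: viability normalisation, 4PL fits, AUC, QC.

Viability is normalised per plate between the negative (vehicle) and
positive (pan-kinase-inhibitor kill) controls, the symmetric four-parameter
log-logistic (4PL) model

    f(x) = c + (d - c) / (1 + exp(b * (log x - log e)))

is fitted per (drug, cell line), and drug response is summarised as the
standardised area under the viability curve in log-dose space,

    AUC = (1 / (log x_max - log x_min)) * ∫ f(x) d(log x),

which ranges from 1 (no response) to 0 (full response). The natural log is
used inside the 4PL (the model is base-agnostic, b absorbs the base); the
standardisation is likewise base-free because the log range cancels.

Parameters: b = slope (dimensionless, > 0 for viability falling with dose),
c = lower limit, d = upper limit (viability fractions), e = ED50 in µM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .io_formats import ScreenWellRecord

logger = logging.getLogger("proteoscreen")

ED50_FLAT = math.inf  # sentinel for curves with no dose effect


@dataclass
class CurveFit:
    b: float
    c: float
    d: float
    e: float  # ED50, µM
    converged: bool
    rmse: float

    def __post_init__(self) -> None:
        if not self.e > 0:
            raise ValueError(f"ED50 must be positive, got {self.e}")
        if self.c > self.d:
            raise ValueError(f"lower limit c={self.c} exceeds upper limit d={self.d}")

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return four_pl(x, self.b, self.c, self.d, self.e)


@dataclass
class DrugResponseMatrix:
    """Drugs x cell lines summaries of the screen."""

    auc: pd.DataFrame  # standardised AUC in [0, 1]
    ec50: pd.DataFrame  # µM (inf for flat curves)
    max_inhibition: pd.DataFrame  # 1 - min of fitted curve over tested range

    @property
    def drugs(self) -> list[str]:
        return list(self.auc.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.auc.columns)


def four_pl(x, b, c, d, e):
    """Symmetric four-parameter log-logistic viability model."""
    x = np.asarray(x, dtype=float)
    return c + (d - c) / (1.0 + np.exp(b * (np.log(x) - np.log(e))))


def normalize_viability(wells: list[ScreenWellRecord]) -> pd.DataFrame:
    """Normalise one plate's raw signals to viability fractions.

    viability = (signal - mean_pos) / (mean_neg - mean_pos), clipped to
    [0, 1.2]; the fitting input column ``viability`` additionally caps at 1.
    Returns per (drug, cell_line, dose) replicate mean and SD.
    """
    pos = [w.signal for w in wells if w.well_role == "positive_control"]
    neg = [w.signal for w in wells if w.well_role == "negative_control"]
    if not pos or not neg:
        raise ValueError("plate must contain positive and negative controls")
    mean_pos, mean_neg = float(np.mean(pos)), float(np.mean(neg))
    if mean_neg <= mean_pos:
        raise ValueError(
            f"plate failure: negative-control mean {mean_neg:g} <= "
            f"positive-control mean {mean_pos:g}"
        )
    rows = []
    for w in wells:
        if w.well_role != "sample":
            continue
        v = (w.signal - mean_pos) / (mean_neg - mean_pos)
        rows.append((w.drug, w.cell_line, w.dose, min(max(v, 0.0), 1.2)))
    df = pd.DataFrame(rows, columns=["drug", "cell_line", "dose", "viability_raw"])
    out = (
        df.groupby(["drug", "cell_line", "dose"], sort=True)["viability_raw"]
        .agg(viability_mean="mean", viability_sd="std", n="size")
        .reset_index()
    )
    out["viability"] = out["viability_mean"].clip(upper=1.0)
    return out


def empirical_auc(doses: np.ndarray, viability: np.ndarray) -> float:
    """Trapezoid AUC of observed points in log-dose space, standardised."""
    order = np.argsort(doses)
    logx = np.log(np.asarray(doses, float)[order])
    v = np.asarray(viability, float)[order]
    if logx[-1] <= logx[0]:
        raise ValueError("need at least two distinct doses")
    return float(np.clip(np.trapezoid(v, logx) / (logx[-1] - logx[0]), 0.0, 1.0))


def fit_4pl(doses, viability, max_nfev: int = 2000) -> CurveFit:
    """Least-squares 4PL fit of mean viability against dose.

    Initialisation: d = max(v), c = min(v), e = dose nearest half-max,
    b = 1. Bounds: c, d in [-0.2, 1.3]; e in [x_min/100, x_max*100];
    b in (0, 50]. On non-convergence the flag is False and callers should
    fall back to the empirical trapezoid AUC.
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    nonzero = doses > 0
    doses, viability = doses[nonzero], viability[nonzero]
    if len(np.unique(doses)) < 4:
        raise ValueError("need at least 4 distinct nonzero doses")

    d0, c0 = float(viability.max()), float(viability.min())
    half = (d0 + c0) / 2.0
    e0 = float(doses[np.argmin(np.abs(viability - half))])
    x_min, x_max = doses.min(), doses.max()
    lo = [1e-3, -0.2, -0.2, x_min / 100.0]
    hi = [50.0, 1.3, 1.3, x_max * 100.0]
    p0 = [1.0, c0, d0, float(np.clip(e0, lo[3], hi[3]))]

    try:
        popt, _ = optimize.curve_fit(
            four_pl, doses, viability, p0=p0, bounds=(lo, hi), max_nfev=max_nfev
        )
        converged = True
    except (RuntimeError, optimize.OptimizeWarning):
        popt, converged = p0, False
    b, c, d, e = (float(p) for p in popt)
    if c > d:  # enforce the lower<=upper output convention
        c, d = d, c
    resid = four_pl(doses, b, c, d, e) - viability
    return CurveFit(b=b, c=c, d=d, e=e, converged=converged,
                    rmse=float(np.sqrt(np.mean(resid**2))))


def standardized_auc(fit: CurveFit, dose_range: tuple[float, float]) -> float:
    """Standardised AUC of the fitted curve over the tested dose range.

    Adaptive quadrature (tolerance 1e-8) of f in log-dose space divided by
    the log-range, clipped to [0, 1].
    """
    x_min, x_max = dose_range
    if x_min >= x_max:
        raise ValueError(f"empty dose range [{x_min}, {x_max}]")
    if not math.isfinite(fit.e):  # flat curve: constant at its level
        level = (fit.c + fit.d) / 2.0
        return float(np.clip(level, 0.0, 1.0))
    lo, hi = math.log(x_min), math.log(x_max)
    val, _ = integrate.quad(
        lambda u: four_pl(math.exp(u), fit.b, fit.c, fit.d, fit.e),
        lo, hi, epsabs=1e-8, epsrel=1e-8, limit=200,
    )
    return float(np.clip(val / (hi - lo), 0.0, 1.0))


def response_from_curves(
    fits: dict[tuple[str, str], CurveFit], dose_range: tuple[float, float]
) -> DrugResponseMatrix:
    """Summarise per-(drug, line) fits into AUC / EC50 / max-inhibition."""
    drugs = sorted({k[0] for k in fits})
    lines = sorted({k[1] for k in fits})
    auc = pd.DataFrame(np.nan, index=drugs, columns=lines)
    ec50 = pd.DataFrame(np.nan, index=drugs, columns=lines)
    maxinh = pd.DataFrame(np.nan, index=drugs, columns=lines)
    for (drug, line), fit in fits.items():
        auc.loc[drug, line] = standardized_auc(fit, dose_range)
        ec50.loc[drug, line] = fit.e
        if math.isfinite(fit.e):
            curve_min = min(fit.c, float(fit(dose_range[1])))
        else:
            curve_min = (fit.c + fit.d) / 2.0
        maxinh.loc[drug, line] = 1.0 - curve_min
    return DrugResponseMatrix(auc=auc, ec50=ec50, max_inhibition=maxinh)


def fit_screen(
    viability: pd.DataFrame, dose_range: tuple[float, float] | None = None
) -> tuple[DrugResponseMatrix, dict[tuple[str, str], CurveFit]]:
    """Fit every (drug, cell line) group of a normalised viability table."""
    fits: dict[tuple[str, str], CurveFit] = {}
    if dose_range is None:
        doses = viability.loc[viability["dose"] > 0, "dose"]
        dose_range = (float(doses.min()), float(doses.max()))
    for (drug, line), grp in viability.groupby(["drug", "cell_line"], sort=True):
        grp = grp[grp["dose"] > 0]
        fits[(drug, line)] = fit_4pl(grp["dose"].to_numpy(),
                                     grp["viability"].to_numpy())
    return response_from_curves(fits, dose_range), fits


def potency_filter(
    response: DrugResponseMatrix,
    kinase_inhibitors: set[str],
    ec50_max_um: float = 0.1,
    auc_max: float = 0.9,
    min_inhibition: float = 0.5,
) -> pd.Series:
    """Count, per cell line, effective kinase inhibitors.

    A KI counts when EC50 < 100 nM, AUC < 0.9 and relative inhibition
    effect > 50%.
    """
    ki = [d for d in response.drugs if d in kinase_inhibitors]
    eff = (
        (response.ec50.loc[ki] < ec50_max_um)
        & (response.auc.loc[ki] < auc_max)
        & (response.max_inhibition.loc[ki] > min_inhibition)
    )
    return eff.sum(axis=0).rename("n_effective_kinase_inhibitors")


def zprime(pos_signals, neg_signals) -> float:
    """Plate-quality Z'-factor: 1 - 3(σ₊+σ₋)/|μ₊-μ₋| (sample SDs)."""
    pos = np.asarray(pos_signals, dtype=float)
    neg = np.asarray(neg_signals, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least two signals per control group")
    mu_p, mu_n = pos.mean(), neg.mean()
    if mu_p == mu_n:
        raise ValueError("identical control means; Z' undefined")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / abs(mu_p - mu_n))
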