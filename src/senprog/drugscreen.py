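"""Organoid drug-screen statistics: viability, z-scores, growth rates,
median-effect fits and Chou-Talalay combination indices.

A screening plate is a tidy table (columns: well, drug, dose, unit,
replicate, is_control, atp_signal, size_day4, size_day6). Viability is each
well's ATP signal over the mean DMSO-control signal. The per-drug z-score
is (mean drug signal - mean control signal) / control SD (sample SD,
ddof=1). The normalized growth rate is the drug group's day-6/day-4 size
ratio over the control group's.

Dose-response follows the median-effect equation fa/fu = (D/Dm)^m, fitted
by linear regression of log10(fa/(1-fa)) on log10(D). The combination index
at affected fraction fa is CI = d1/Dx1 + d2/Dx2 with Dx_i the single-agent
dose of drug i producing fa (the mutually nonexclusive variant adds
d1*d2/(Dx1*Dx2)); log10 CI < 0 is called synergy, > 0 antagonism, and
values within a tolerance band of 0 additivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "MedianEffectFit",
    "ComboResult",
    "validate_plate",
    "normalize_viability",
    "drug_zscore",
    "growth_rate",
    "viability_to_fa",
    "median_effect_fit",
    "combination_index",
    "tumor_volume",
]

PLATE_COLUMNS = ("well", "drug", "dose", "unit", "replicate", "is_control",
                 "atp_signal", "size_day4", "size_day6")


def validate_plate(plate: pd.DataFrame, min_controls: int = 1) -> pd.DataFrame:
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table lacks columns: {missing}")
    if (plate["dose"] < 0).any():
        raise ValueError("doses must be nonnegative")
    n_ctrl = int(plate["is_control"].sum())
    if n_ctrl < min_controls:
        raise ValueError(f"plate has {n_ctrl} control wells; need >= {min_controls}")
    return plate


def normalize_viability(plate: pd.DataFrame) -> pd.Series:
    """Per-well viability: atp_signal / mean control atp_signal."""
    validate_plate(plate, min_controls=1)
    ctrl_mean = plate.loc[plate["is_control"], "atp_signal"].mean()
    if ctrl_mean == 0:
        raise ValueError("control wells have zero mean ATP signal")
    return plate["atp_signal"] / ctrl_mean


def _drug_rows(plate: pd.DataFrame, drug: str) -> pd.DataFrame:
    if drug == "DMSO" or (plate["is_control"] & (plate["drug"] == drug)).any():
        rows = plate[plate["drug"] == drug]
    else:
        rows = plate[(plate["drug"] == drug) & ~plate["is_control"]]
    if rows.empty:
        raise ValueError(f"no wells for drug {drug!r}")
    return rows


def drug_zscore(plate: pd.DataFrame, drug: str) -> float:
    """(mean drug ATP - mean control ATP) / sample SD of control ATP."""
    validate_plate(plate, min_controls=2)
    ctrl = plate.loc[plate["is_control"], "atp_signal"]
    sd = ctrl.std(ddof=1)
    if sd == 0:
        raise ValueError("control ATP standard deviation is zero")
    rows = _drug_rows(plate, drug)
    return float((rows["atp_signal"].mean() - ctrl.mean()) / sd)


def growth_rate(plate: pd.DataFrame, drug: str) -> float:
    """Drug day6/day4 mean-size ratio, normalized to the control ratio."""
    validate_plate(plate, min_controls=1)
    rows = _drug_rows(plate, drug)
    ctrl = plate[plate["is_control"]]
    for name, grp in (("drug", rows), ("control", ctrl)):
        if grp["size_day4"].mean() == 0:
            raise ValueError(f"{name} group has zero mean day-4 size")
    drug_ratio = rows["size_day6"].mean() / rows["size_day4"].mean()
    ctrl_ratio = ctrl["size_day6"].mean() / ctrl["size_day4"].mean()
    if ctrl_ratio == 0:
        raise ValueError("control group has zero growth ratio")
    return float(drug_ratio / ctrl_ratio)


def viability_to_fa(viability, clip: tuple[float, float] = (0.005, 0.995)):
    """Affected fraction fa = 1 - viability, clipped away from 0 and 1.

    Returns ``(fa, clipped_mask)``; the log-odds transform of the
    median-effect fit is undefined at fa = 0 or 1, so boundary values are
    clipped to ``clip`` and flagged.
    """
    fa = 1.0 - np.asarray(viability, dtype=float)
    lo, hi = clip
    clipped = (fa < lo) | (fa > hi)
    return np.clip(fa, lo, hi), clipped


@dataclass(frozen=True)
class MedianEffectFit:
    """Fitted median-effect model fa/fu = (D/Dm)^m."""

    m: float
    dm: float
    r_squared: float
    dose_range: tuple[float, float]
    n_points: int

    def fa_at(self, dose) -> np.ndarray:
        r = (np.asarray(dose, dtype=float) / self.dm) ** self.m
        return r / (1.0 + r)

    def dose_for_fa(self, fa: float) -> float:
        """Single-agent dose producing affected fraction ``fa`` (Dx)."""
        if not 0.0 < fa < 1.0:
            raise ValueError("fa must lie strictly in (0, 1)")
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)


def median_effect_fit(doses, affected_fractions) -> MedianEffectFit:
    """Fit the median-effect line log10(fa/(1-fa)) = m log10(D) - m log10(Dm).

    Requires at least two distinct positive doses and fa strictly inside
    (0, 1); use :func:`viability_to_fa` to clip boundary values first.
    """
    D = np.asarray(doses, dtype=float)
    fa = np.asarray(affected_fractions, dtype=float)
    if D.shape != fa.shape:
        raise ValueError("doses and affected fractions differ in length")
    if (D <= 0).any():
        raise ValueError("doses must be strictly positive")
    if ((fa <= 0) | (fa >= 1)).any():
        raise ValueError("fa values must lie strictly in (0, 1); clip boundary "
                         "values first (see viability_to_fa)")
    if np.unique(D).size < 2:
        raise ValueError("need at least 2 distinct doses")
    x = np.log10(D)
    y = np.log10(fa / (1.0 - fa))
    res = scipy.stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise ValueError("fitted slope is non-positive; dose-response is not increasing")
    dm = float(10.0 ** (-res.intercept / m))
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 1.0
    return MedianEffectFit(m=m, dm=dm, r_squared=r2,
                           dose_range=(float(D.min()), float(D.max())),
                           n_points=int(D.size))


@dataclass(frozen=True)
class ComboResult:
    """Combination index at one effect level, with its interpretation."""

    fa: float
    ci: float
    log10_ci: float
    call: str
    dx1: float
    dx2: float


def combination_index(fit1: MedianEffectFit, fit2: MedianEffectFit,
                      d1: float, d2: float, fa_combo: float,
                      nonexclusive: bool = False,
                      additivity_tol: float = 0.1) -> ComboResult:
    """Chou-Talalay combination index of a two-drug dose pair.

    ``fa_combo`` is the affected fraction observed for the combination
    (d1, d2). CI = d1/Dx1 + d2/Dx2, where Dx_i is the dose of drug i alone
    producing ``fa_combo`` under its fitted median-effect model;
    ``nonexclusive=True`` adds the d1*d2/(Dx1*Dx2) term. The call is
    "additivity" when |log10 CI| <= ``additivity_tol``, else "synergy"
    (log10 CI < 0) or "antagonism" (> 0); the raw CI is always reported.
    """
    if not 0.0 < fa_combo < 1.0:
        raise ValueError("fa_combo must lie strictly in (0, 1)")
    if d1 < 0 or d2 < 0:
        raise ValueError("doses must be nonnegative")
    dx1 = fit1.dose_for_fa(fa_combo)
    dx2 = fit2.dose_for_fa(fa_combo)
    ci = d1 / dx1 + d2 / dx2
    if nonexclusive:
        ci += (d1 * d2) / (dx1 * dx2)
    if ci <= 0:
        raise ValueError("combination index must be positive; got zero doses?")
    log_ci = float(np.log10(ci))
    if abs(log_ci) <= additivity_tol:
        call = "additivity"
    elif log_ci < 0:
        call = "synergy"
    else:
        call = "antagonism"
    return ComboResult(fa=fa_combo, ci=float(ci), log10_ci=log_ci, call=call,
                       dx1=float(dx1), dx2=float(dx2))


def tumor_volume(length: float, width: float) -> float:
    """Ellipsoid-approximation allograft volume V = 0.5236 * L * W^2."""
    if length < 0 or width < 0:
        raise ValueError("length and width must be nonnegative")
    return 0.5236 * length * width ** 2
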