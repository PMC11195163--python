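"""Scalar NMR-derived observables.

Single-exponential relaxation fits (T1/T2), combined chemical shift
perturbations, secondary chemical shifts against a coil reference, and
heteronuclear NOE ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import InputError, ParameterError

__all__ = [
    "RelaxationSeries",
    "ExponentialDecayModel",
    "DecayResults",
    "GAMMA_RATIO",
    "csp",
    "secondary_shifts",
    "het_noe",
]

#: |γ_X|/γ_H scaling factors for combined shift perturbations
GAMMA_RATIO = {"nitrogen15": 0.10137, "carbon13": 0.2516}


@dataclass(frozen=True)
class RelaxationSeries:
    """Relaxation delays (s) and peak intensities; duplicates allowed."""

    delays: np.ndarray = field(repr=False)
    intensities: np.ndarray = field(repr=False)

    def __post_init__(self):
        d = np.asarray(self.delays, float)
        i = np.asarray(self.intensities, float)
        object.__setattr__(self, "delays", d)
        object.__setattr__(self, "intensities", i)
        if d.shape != i.shape or d.ndim != 1:
            raise InputError("delays and intensities must be 1D and aligned")
        if np.any(d < 0):
            raise InputError("delays must be non-negative")
        if len(np.unique(d)) < 3:
            raise InputError("need at least 3 distinct delays")
        if not np.all(np.isfinite(i)):
            raise InputError("intensities must be finite")


@dataclass(frozen=True)
class DecayResults:
    """Single-exponential fit I = I0·exp(−t/T): estimates, uncertainties, diagnostics."""

    T: float
    I0: float
    T_stderr: float
    I0_stderr: float
    residuals: np.ndarray = field(repr=False, default=None)
    success: bool = True
    message: str = ""

    def summary(self) -> str:
        lines = [
            "Single-exponential relaxation fit",
            "---------------------------------",
            f"  T   = {self.T:.6g} s   (stderr {self.T_stderr:.2g})",
            f"  I0  = {self.I0:.6g}     (stderr {self.I0_stderr:.2g})",
            f"  rms residual = {np.sqrt(np.mean(self.residuals**2)):.3g}"
            if self.residuals is not None else "",
            f"  converged: {self.success}  {self.message}",
        ]
        return "\n".join(x for x in lines if x)


class ExponentialDecayModel:
    """Least-squares model for single-exponential relaxation decays.

    Duplicate delays are averaged before fitting; the spread between
    duplicates enters the reported uncertainty through the residual variance.
    """

    def __init__(self, series: RelaxationSeries):
        self.series = series
        # average duplicates
        d, inv = np.unique(series.delays, return_inverse=True)
        sums = np.bincount(inv, weights=series.intensities)
        counts = np.bincount(inv)
        self.delays = d
        self.intensities = sums / counts

    def fit(self) -> DecayResults:
        t, y = self.delays, self.intensities
        if np.ptp(y) == 0:
            return DecayResults(np.nan, np.nan, np.nan, np.nan,
                                success=False, message="constant intensities")
        # log-linear start where positive; fall back to range-based guesses
        pos = y > 0
        if pos.sum() >= 2 and np.ptp(y[pos]) > 0:
            slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
            p0 = [np.exp(intercept), -1.0 / slope if slope < 0 else np.ptp(t)]
        else:
            p0 = [y[0], np.ptp(t) / 2]
        if p0[1] <= 0:
            return DecayResults(np.nan, np.nan, np.nan, np.nan,
                                success=False, message="non-decaying data")
        try:
            popt, pcov = curve_fit(
                lambda tt, i0, T: i0 * np.exp(-tt / T), t, y, p0=p0, maxfev=10000
            )
        except RuntimeError as e:
            return DecayResults(np.nan, np.nan, np.nan, np.nan,
                                success=False, message=str(e))
        i0, T = popt
        if T <= 0:
            return DecayResults(np.nan, np.nan, np.nan, np.nan,
                                success=False, message="non-decaying data")
        err = np.sqrt(np.diag(pcov))
        resid = y - i0 * np.exp(-t / T)
        return DecayResults(T=float(T), I0=float(i0), T_stderr=float(err[1]),
                            I0_stderr=float(err[0]), residuals=resid)


def csp(delta_h: float, delta_x: float, nucleus_x: str = "nitrogen15",
        gamma_ratio: float | None = None) -> float:
    """Combined chemical shift perturbation (ppm).

    Δδ = sqrt(Δδ_H² + (γ_X/γ_H · Δδ_X)²), with the γ ratio taken from
    ``GAMMA_RATIO`` for ¹⁵N or ¹³C unless given explicitly.
    """
    if gamma_ratio is None:
        if nucleus_x not in GAMMA_RATIO:
            raise ParameterError(
                f"nucleus_x must be one of {sorted(GAMMA_RATIO)}, got {nucleus_x!r}"
            )
        gamma_ratio = GAMMA_RATIO[nucleus_x]
    if not 0 < gamma_ratio < 1:
        raise ParameterError("gamma ratio must lie in (0, 1)")
    return float(np.sqrt(delta_h**2 + (gamma_ratio * delta_x) ** 2))


def secondary_shifts(table: pd.DataFrame, smoothing_window: int = 1) -> pd.DataFrame:
    """Secondary chemical shifts ΔδCα − ΔδCβ against a coil reference.

    ``table`` must carry columns ``residue, ca_obs, cb_obs, ca_coil, cb_coil``
    (ppm); rows lacking a Cβ value (e.g. glycine) use the Cα deviation alone
    and are flagged.  Positive values indicate helical propensity, negative
    values extended structure.  ``smoothing_window`` > 1 applies a centred
    running mean (truncated at the edges).
    """
    required = {"residue", "ca_obs", "cb_obs", "ca_coil", "cb_coil"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"missing columns: {sorted(missing)}")
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ParameterError("smoothing window must be odd and >= 1")
    out = table.copy().reset_index(drop=True)
    d_ca = out["ca_obs"] - out["ca_coil"]
    d_cb = out["cb_obs"] - out["cb_coil"]
    no_cb = d_cb.isna()
    value = d_ca - d_cb.fillna(0.0)
    out["delta_ca"] = d_ca
    out["delta_cb"] = d_cb
    out["secondary_shift"] = value
    out["ca_only"] = no_cb
    if smoothing_window > 1:
        out["secondary_shift"] = (
            out["secondary_shift"]
            .rolling(smoothing_window, center=True, min_periods=1)
            .mean()
        )
    return out


def het_noe(sat_height: float, ref_height: float) -> float:
    """Heteronuclear NOE: peak-height ratio with/without proton saturation."""
    if ref_height == 0:
        raise ZeroDivisionError("reference peak height must be non-zero")
    return sat_height / ref_height
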