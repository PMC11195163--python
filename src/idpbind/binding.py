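"""1:1 binding observable models and their nonlinear fits.

The physical core is the quadratic mass-action isotherm for a labelled
macromolecule M titrated with ligand L:

    F_B = [b − sqrt(b² − 4·L·M)] / (2M),   b = K_D + L + M,

the fraction of M bound.  Fluorescence anisotropy reads out F_B through

    r_obs = [Q·F_B·r_B + r_F·(1−F_B)] / [1 − F_B·(1−Q)],

where Q corrects for intensity differences between free and bound states,
and NMR chemical shift perturbations through Δδ = Δδ_max·F_B.

Fitting follows the statsmodels idiom: build a model from data, call
``fit()``, and read estimates/uncertainties off the results object.
Concentrations are in μM throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import InputError, ModelDomainError, ParameterError

__all__ = [
    "AnisotropyMeasurement",
    "BindingModelParams",
    "TitrationSeries",
    "TitrationResults",
    "AnisotropyTitrationModel",
    "CSPTitrationModel",
    "observed_anisotropy",
    "fraction_bound",
    "anisotropy_model",
    "fit_anisotropy_titration",
    "fit_csp_titration",
    "relative_affinity",
]


@dataclass(frozen=True)
class AnisotropyMeasurement:
    """Raw polarized intensities (arbitrary units) from one anisotropy read."""

    i_vv: float
    i_vh: float
    i_hv: float
    i_hh: float

    def __post_init__(self):
        if min(self.i_vv, self.i_vh, self.i_hv, self.i_hh) <= 0:
            raise InputError("all four polarized intensities must be > 0")


@dataclass(frozen=True)
class BindingModelParams:
    """1:1 binding observable parameters: K_D (μM), r_F, r_B, Q (> 0)."""

    kd: float
    r_f: float = 0.05
    r_b: float = 0.15
    q: float = 1.0

    def __post_init__(self):
        if self.kd <= 0:
            raise ParameterError(f"K_D must be > 0, got {self.kd}")
        if self.q <= 0:
            raise ParameterError(f"Q must be > 0, got {self.q}")

    def with_(self, **kwargs) -> "BindingModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TitrationSeries:
    """Ligand titration of a fixed macromolecule concentration.

    ``ligand_totals`` (μM) must be non-negative and strictly increasing;
    ``observable`` is anisotropy or CSP (ppm) per point.
    """

    ligand_totals: np.ndarray = field(repr=False)
    m_total: float = 0.0
    observable: np.ndarray = field(repr=False, default=None)
    kind: str = "anisotropy"

    def __post_init__(self):
        lig = np.asarray(self.ligand_totals, float)
        obs = np.asarray(self.observable, float)
        object.__setattr__(self, "ligand_totals", lig)
        object.__setattr__(self, "observable", obs)
        if np.any(lig < 0) or np.any(np.diff(lig) <= 0):
            raise InputError("ligand totals must be non-negative and strictly increasing")
        if obs.shape != lig.shape:
            raise InputError("observable must align with the ligand grid")
        if not np.all(np.isfinite(obs)):
            raise InputError("observable must be finite")

    def __len__(self) -> int:
        return len(self.ligand_totals)


def observed_anisotropy(m: AnisotropyMeasurement) -> tuple[float, float]:
    """Instrument G factor and observed anisotropy from polarized intensities.

    G = I_hv/I_hh;  r = (I_vv − G·I_vh)/(I_vv + 2G·I_vh).
    """
    g = m.i_hv / m.i_hh
    r = (m.i_vv - g * m.i_vh) / (m.i_vv + 2.0 * g * m.i_vh)
    return g, r


def fraction_bound(kd, l_total, m_total):
    """Fraction of the macromolecule bound under 1:1 mass action.

    Quadratic solution of L + M ⇌ LM at totals L, M (μM).  ``m_total = 0``
    falls back to the hyperbolic limit L/(K_D + L) (the infinite-dilution
    form).
    """
    kd = float(kd)
    if kd <= 0:
        raise ParameterError("K_D must be > 0")
    l = np.asarray(l_total, dtype=float)
    if np.any(l < 0):
        raise ParameterError("ligand totals must be >= 0")
    if m_total == 0:
        out = l / (kd + l)
        return float(out) if np.isscalar(l_total) else out
    if m_total < 0:
        raise ParameterError("macromolecule total must be >= 0")
    b = kd + l + m_total
    fb = (b - np.sqrt(b**2 - 4.0 * l * m_total)) / (2.0 * m_total)
    fb = np.clip(fb, 0.0, 1.0)
    return float(fb) if np.isscalar(l_total) else fb


def anisotropy_model(f_b, params: BindingModelParams):
    """Observed anisotropy for a given bound fraction under the Q correction."""
    fb = np.asarray(f_b, dtype=float)
    if np.any((fb < 0) | (fb > 1)):
        raise ParameterError("F_B must lie in [0, 1]")
    denom = 1.0 - fb * (1.0 - params.q)
    if np.any(denom <= 0):
        raise ModelDomainError("anisotropy model denominator must be positive")
    out = (params.q * fb * params.r_b + params.r_f * (1.0 - fb)) / denom
    return float(out) if np.isscalar(f_b) else out


@dataclass(frozen=True)
class TitrationResults:
    """Estimates, standard errors and diagnostics of a 1:1 titration fit."""

    params: dict
    bse: dict
    residuals: np.ndarray = field(repr=False, default=None)
    cov: np.ndarray = field(repr=False, default=None)
    kind: str = "anisotropy"
    success: bool = True
    message: str = ""

    @property
    def kd(self) -> float:
        return self.params["kd"]

    def conf_int(self, name: str, z: float = 1.96) -> tuple[float, float]:
        """Normal-approximation confidence interval for one parameter."""
        est, se = self.params[name], self.bse[name]
        return est - z * se, est + z * se

    def summary(self) -> str:
        lines = [f"1:1 {self.kind} titration fit",
                 "-" * 32]
        for k in self.params:
            lines.append(f"  {k:8s} = {self.params[k]:.6g}"
                         f"   (stderr {self.bse[k]:.3g})")
        if self.residuals is not None:
            lines.append(f"  rms residual = "
                         f"{np.sqrt(np.mean(self.residuals**2)):.3g}")
        lines.append(f"  converged: {self.success}  {self.message}")
        return "\n".join(lines)

    def plot(self, model, ax=None):
        """Overlay data and fitted curve; ``model`` is the fitted model object."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = model.series
        ax.plot(s.ligand_totals, s.observable, "o", label="data")
        grid = np.linspace(s.ligand_totals[0], s.ligand_totals[-1], 200)
        ax.plot(grid, model.predict(self.params, grid), "-", label="fit")
        ax.set_xlabel("ligand total (μM)")
        ax.set_ylabel(s.kind)
        ax.legend()
        return ax


class AnisotropyTitrationModel:
    """Nonlinear least-squares model for an anisotropy titration.

    Fits (K_D, Q, r_F, r_B) of ``anisotropy_model ∘ fraction_bound`` to the
    observed series; any subset may be fixed through ``fit(fix=...)``.
    """

    param_names = ("kd", "r_f", "r_b", "q")

    def __init__(self, series: TitrationSeries):
        if len(series) < 6:
            raise InputError("need at least 6 titration points")
        self.series = series

    @classmethod
    def from_arrays(cls, ligand_totals, observable, m_total):
        return cls(TitrationSeries(np.asarray(ligand_totals, float), m_total,
                                   np.asarray(observable, float), "anisotropy"))

    def predict(self, params: dict, ligand_totals=None):
        lig = self.series.ligand_totals if ligand_totals is None else ligand_totals
        fb = fraction_bound(params["kd"], lig, self.series.m_total)
        return anisotropy_model(fb, BindingModelParams(**params))

    def _start(self) -> dict:
        s = self.series
        obs = s.observable
        if np.ptp(obs) == 0:
            raise InputError("degenerate titration: flat observable")
        half = (obs[0] + obs[-1]) / 2.0
        idx = int(np.argmin(np.abs(obs - half)))
        kd0 = max(s.ligand_totals[idx], 1e-6)
        return {"kd": kd0, "r_f": obs[0], "r_b": obs[-1], "q": 1.0}

    def fit(self, fix: dict | None = None) -> TitrationResults:
        fix = dict(fix or {})
        start = self._start()
        free = [p for p in self.param_names if p not in fix]
        if not free:
            raise ParameterError("at least one parameter must be free")
        lo = {"kd": 1e-9, "r_f": -0.5, "r_b": -0.5, "q": 1e-6}
        hi = {"kd": np.inf, "r_f": 1.0, "r_b": 1.0, "q": np.inf}

        def func(lig, *theta):
            params = dict(fix)
            params.update(dict(zip(free, theta)))
            return self.predict(params, lig)

        p0 = [np.clip(start[p], lo[p], min(hi[p], 1e6)) for p in free]
        try:
            popt, pcov = curve_fit(
                func, self.series.ligand_totals, self.series.observable,
                p0=p0, bounds=([lo[p] for p in free], [hi[p] for p in free]),
                maxfev=20000,
            )
        except RuntimeError as e:
            return TitrationResults({}, {}, kind=self.series.kind,
                                    success=False, message=str(e))
        params = dict(fix)
        params.update(dict(zip(free, popt)))
        err = np.sqrt(np.diag(pcov))
        bse = {p: 0.0 for p in fix}
        bse.update(dict(zip(free, err)))
        resid = self.series.observable - self.predict(params)
        return TitrationResults(params={p: float(params[p]) for p in self.param_names},
                                bse={p: float(bse[p]) for p in self.param_names},
                                residuals=resid, cov=pcov, kind=self.series.kind)


class CSPTitrationModel:
    """Nonlinear least-squares model for a CSP titration: Δδ = Δδ_max·F_B."""

    param_names = ("kd", "dd_max")

    def __init__(self, series: TitrationSeries):
        if len(series) < 5:
            raise InputError("need at least 5 titration points")
        self.series = series

    @classmethod
    def from_arrays(cls, ligand_totals, observable, m_total):
        return cls(TitrationSeries(np.asarray(ligand_totals, float), m_total,
                                   np.asarray(observable, float), "csp"))

    def predict(self, params: dict, ligand_totals=None):
        lig = self.series.ligand_totals if ligand_totals is None else ligand_totals
        return params["dd_max"] * fraction_bound(params["kd"], lig,
                                                 self.series.m_total)

    def fit(self) -> TitrationResults:
        s = self.series
        if np.ptp(s.observable) == 0:
            raise InputError("degenerate titration: flat observable")
        ddmax0 = s.observable[-1] if s.observable[-1] != 0 else np.ptp(s.observable)
        half = ddmax0 / 2.0
        idx = int(np.argmin(np.abs(s.observable - half)))
        kd0 = max(s.ligand_totals[idx], 1e-6)
        try:
            popt, pcov = curve_fit(
                lambda lig, kd, dd: dd * fraction_bound(kd, lig, s.m_total),
                s.ligand_totals, s.observable, p0=[kd0, ddmax0],
                bounds=([1e-9, -np.inf], [np.inf, np.inf]), maxfev=20000,
            )
        except RuntimeError as e:
            return TitrationResults({}, {}, kind="csp", success=False,
                                    message=str(e))
        err = np.sqrt(np.diag(pcov))
        params = {"kd": float(popt[0]), "dd_max": float(popt[1])}
        resid = s.observable - self.predict(params)
        return TitrationResults(params=params,
                                bse={"kd": float(err[0]), "dd_max": float(err[1])},
                                residuals=resid, cov=pcov, kind="csp")


def fit_anisotropy_titration(series: TitrationSeries,
                             fix: dict | None = None) -> TitrationResults:
    """Functional wrapper over :class:`AnisotropyTitrationModel`."""
    return AnisotropyTitrationModel(series).fit(fix=fix)


def fit_csp_titration(series: TitrationSeries) -> TitrationResults:
    """Functional wrapper over :class:`CSPTitrationModel`."""
    return CSPTitrationModel(series).fit()


def relative_affinity(kd_a: float, kd_b: float) -> float:
    """Fold by which partner a binds tighter: kd_b / kd_a."""
    if kd_a <= 0 or kd_b <= 0:
        raise ParameterError("dissociation constants must be > 0")
    return kd_b / kd_a
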