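"""Paramagnetic relaxation enhancement (PRE) forward calculation.

A nitroxide spin label attached at one residue bleaches NMR cross peaks of
nearby residues.  The observable is the paramagnetic/diamagnetic intensity
ratio

    I_P/I_D = R2 · exp(−R2sp·t) / (R2 + R2sp),

with the label-induced rate following the r⁻⁶ dipolar form

    R2sp = (K/r⁶) · (4τc + 3τc/(1 + ω²τc²)).

Profiles are forward-calculated either from a conformational ensemble
(distance from the label bead to every residue, ensemble-averaged) or from
the freely rotating chain null model, whose closed-form mean-square
distances stand in for the ensemble.

Two values of the atom-specific constant K are exposed.  ``paper`` mode
returns the constants printed with the experiments reproduced here
(K_H = 1.23e-23, K_C = 7.78e-34 cm⁶ s⁻²); ``computed`` mode evaluates
K = (1/15)·S(S+1)·γ²g²β² in cgs units (K_H = 1.234e-32, K_C = 1.976e-33
cm⁶ s⁻²).  The two disagree and are deliberately not reconciled: the mode
used is recorded on every profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ParameterError
from .geometry import ConformationalEnsemble, NullChainModel, frc_mean_square_distance

__all__ = [
    "PRESettings",
    "PREProfile",
    "pre_constant",
    "pre_rate",
    "intensity_ratio",
    "pre_profile_from_ensemble",
    "pre_null_profile",
    "AVERAGING_MODES",
]

#: electron spin quantum number of the nitroxide radical
ELECTRON_SPIN = 0.5
#: electronic g factor (dimensionless)
G_ELECTRON = -2.002319
#: Bohr magneton in cgs (erg/G)
BOHR_MAGNETON_CGS = 9.274009994e-21
#: nuclear gyromagnetic ratios in cgs (rad s⁻¹ G⁻¹)
GAMMA_CGS = {"proton": 2.6751e4, "carbon": 1.0705e4}
#: default Larmor angular frequencies at 14.1 T (rad/s)
OMEGA_DEFAULT = {"proton": 2 * np.pi * 600e6, "carbon": 2 * np.pi * 150.9e6}
#: printed atom-specific constants (cm⁶ s⁻²)
K_PAPER = {"proton": 1.23e-23, "carbon": 7.78e-34}

AVERAGING_MODES = ("mean_distance", "mean_inverse_sixth", "root_mean_square")


@dataclass(frozen=True)
class PRESettings:
    """Physical constants governing the PRE forward model.

    Parameters
    ----------
    r2 : intrinsic transverse relaxation rate (s⁻¹), default 8.1
    t : total evolution delay (s), default 0.050
    tau_c : rotational correlation time (s), default 1e-9
    nucleus : "proton" or "carbon"; sets γ and the default ω
    omega : Larmor angular frequency (rad/s); default derived from nucleus
    k_mode : "paper" (printed constants) or "computed" (evaluate the dipolar
        prefactor); ``k_value`` overrides both when given (cm⁶ s⁻²)
    """

    r2: float = 8.1
    t: float = 0.050
    tau_c: float = 1e-9
    nucleus: str = "proton"
    omega: float | None = None
    k_mode: str = "paper"
    k_value: float | None = None

    def __post_init__(self):
        if self.nucleus not in GAMMA_CGS:
            raise ParameterError(
                f"nucleus must be one of {sorted(GAMMA_CGS)}, got {self.nucleus!r}"
            )
        if self.omega is None:
            object.__setattr__(self, "omega", OMEGA_DEFAULT[self.nucleus])
        for name in ("r2", "t", "tau_c", "omega"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.k_mode not in ("paper", "computed"):
            raise ParameterError(f"k_mode must be 'paper' or 'computed', got {self.k_mode!r}")

    def with_(self, **kwargs) -> "PRESettings":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PREProfile:
    """Per-residue paramagnetic/diamagnetic intensity ratios for one label site."""

    residues: np.ndarray = field(repr=False)  # 1-based
    ratios: np.ndarray = field(repr=False)
    label_site: int = 0
    averaging: str = ""
    k_mode: str = ""
    nucleus: str = ""

    def to_tsv(self, path) -> None:
        flag = (self.residues == self.label_site).astype(int)
        arr = np.column_stack([self.residues, self.ratios, flag])
        np.savetxt(path, arr, fmt=["%d", "%.6f", "%d"], delimiter="\t",
                   header="residue\tratio\tlabel_site", comments="")


def pre_constant(settings: PRESettings) -> float:
    """Atom-specific constant K in cm⁶ s⁻² for the configured nucleus/mode."""
    if settings.k_value is not None:
        return settings.k_value
    if settings.k_mode == "paper":
        return K_PAPER[settings.nucleus]
    gamma = GAMMA_CGS[settings.nucleus]
    s = ELECTRON_SPIN
    return (s * (s + 1) / 15.0) * gamma**2 * G_ELECTRON**2 * BOHR_MAGNETON_CGS**2


def pre_rate(r_angstrom, settings: PRESettings):
    """Label-induced transverse rate R2sp (s⁻¹) at effective distance r (Å)."""
    r = np.asarray(r_angstrom, dtype=float)
    if np.any(r <= 0):
        raise ParameterError("distance must be > 0")
    k = pre_constant(settings)
    tc, w = settings.tau_c, settings.omega
    spectral = 4.0 * tc + 3.0 * tc / (1.0 + (w * tc) ** 2)
    r_cm = r * 1e-8
    out = k / r_cm**6 * spectral
    return float(out) if np.isscalar(r_angstrom) else out


def intensity_ratio(r2sp, settings: PRESettings):
    """Paramagnetic/diamagnetic intensity ratio for a given R2sp (s⁻¹)."""
    r2sp = np.asarray(r2sp, dtype=float)
    if np.any(r2sp < 0):
        raise ParameterError("R2sp must be >= 0")
    r2, t = settings.r2, settings.t
    with np.errstate(over="ignore"):
        out = r2 * np.exp(-r2sp * t) / (r2 + r2sp)
    return float(out) if out.ndim == 0 else out


def _effective_distance(d: np.ndarray, averaging: str) -> np.ndarray:
    """Collapse per-frame distances (frames × residues) to one per residue."""
    if averaging == "mean_distance":
        return d.mean(axis=0)
    if averaging == "root_mean_square":
        return np.sqrt((d**2).mean(axis=0))
    if averaging == "mean_inverse_sixth":
        return (d**-6).mean(axis=0) ** (-1.0 / 6.0)
    raise ParameterError(f"averaging must be one of {AVERAGING_MODES}, got {averaging!r}")


def pre_profile_from_ensemble(ensemble: ConformationalEnsemble, label_site: int,
                              settings: PRESettings = PRESettings(),
                              averaging: str = "mean_distance") -> PREProfile:
    """PRE profile from per-frame label-to-residue distances.

    ``label_site`` is a 1-based bead index (for single-bead coarse graining
    the bead stands for the labelled residue).  The label residue itself is
    emitted with ratio 0.  The default ``mean_distance`` averaging applies
    r⁻⁶ to the ensemble-mean distance; ``mean_inverse_sixth`` averages r⁻⁶
    itself; ``root_mean_square`` uses sqrt(<r²>), the statistic of the FRC
    null model.
    """
    n = ensemble.n_beads
    if not 1 <= label_site <= n:
        raise IndexError(f"label site {label_site} outside chain of length {n}")
    d = np.linalg.norm(
        ensemble.coords - ensemble.coords[:, label_site - 1:label_site, :], axis=2
    )
    others = np.arange(n) != (label_site - 1)
    r_eff = np.empty(n)
    r_eff[others] = _effective_distance(d[:, others], averaging)
    ratios = np.zeros(n)
    ratios[others] = intensity_ratio(pre_rate(r_eff[others], settings), settings)
    return PREProfile(residues=np.arange(1, n + 1), ratios=ratios,
                      label_site=label_site, averaging=averaging,
                      k_mode=settings.k_mode, nucleus=settings.nucleus)


def pre_null_profile(label_site: int, chain_length: int,
                     model: NullChainModel = NullChainModel(),
                     settings: PRESettings = PRESettings()) -> PREProfile:
    """Closed-form FRC null PRE profile for a label at ``label_site``.

    Residue i is placed at r = sqrt(<r²(|i − site|)>); the label residue
    (separation 0, where the null is degenerate) is emitted with ratio 0.
    """
    if not 1 <= label_site <= chain_length:
        raise IndexError(
            f"label site {label_site} outside chain of length {chain_length}"
        )
    residues = np.arange(1, chain_length + 1)
    sep = np.abs(residues - label_site)
    ratios = np.zeros(chain_length)
    nz = sep > 0
    r = np.sqrt(frc_mean_square_distance(sep[nz], model))
    ratios[nz] = intensity_ratio(pre_rate(r, settings), settings)
    return PREProfile(residues=residues, ratios=ratios, label_site=label_site,
                      averaging="frc_null", k_mode=settings.k_mode,
                      nucleus=settings.nucleus)
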