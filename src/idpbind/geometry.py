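"""Ensemble geometry: R_g, distance maps, random-coil nulls and scattering.

A :class:`ConformationalEnsemble` holds an ordered stack of conformations of
one bead chain (or a molecular pair) in Ångström.  From it the module derives
the global descriptors used to characterise disordered chains: per-frame radii
of gyration, ensemble-mean inter-bead distance maps, and a Debye forward
scattering profile feeding Guinier and dimensionless-Kratky analysis.

Two ideal-chain references are provided as nulls:

* the freely rotating chain (FRC) with bond length ``l`` and bond-angle-
  supplement cosine ``alpha``, whose mean-square inter-monomer distance has
  the closed form

  .. math::

     \\langle r^2(n)\\rangle = n l^2\\left[\\frac{1+\\alpha}{1-\\alpha}
        - \\frac{2\\alpha(1-\\alpha^n)}{n(1-\\alpha)^2}\\right]

* the analytical Flory random coil (AFRC), a sequence-length-only Gaussian
  chain with :math:`\\langle r^2(n)\\rangle = 6 R_0^2 n` and the empirical
  polypeptide prefactor :math:`R_0 = 2.52` Å, used to normalise distance maps
  and as the random-coil R_g expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import InputError, ModelDomainError, ParameterError

__all__ = [
    "ConformationalEnsemble",
    "NullChainModel",
    "AnalyticalFloryCoil",
    "ScatteringProfile",
    "GuinierResult",
    "RgSummary",
    "radius_of_gyration",
    "mean_distance_map",
    "frc_mean_square_distance",
    "afrc_reference",
    "normalized_distance_map",
    "debye_scattering",
    "guinier_fit",
    "dimensionless_kratky",
    "rg_density",
]


@dataclass
class ConformationalEnsemble:
    """Ordered frames of labelled 3D bead coordinates (Å).

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_beads, 3)
    labels : sequence of str, optional
        One label per bead ("<index> <name>" style); defaults to 1..N.
    masses : ndarray, optional
        Per-bead masses, default 1 (bead-level coarse graining).
    """

    coords: np.ndarray
    labels: list[str] | None = None
    masses: np.ndarray | None = None
    name: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[-1] != 3:
            raise InputError(
                f"coords must have shape (n_frames, n_beads, 3), "
                f"got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise InputError("coordinates must be finite")
        n = self.n_beads
        if self.labels is None:
            self.labels = [str(i + 1) for i in range(n)]
        if len(self.labels) != n:
            raise InputError("one label per bead required")
        if self.masses is None:
            self.masses = np.ones(n)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (n,) or np.any(self.masses <= 0):
            raise InputError("masses must be positive, one per bead")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class NullChainModel:
    """Freely rotating chain: bond length ``l`` (Å) and supplement cosine ``alpha``."""

    l: float = 3.8
    alpha: float = 0.8

    def __post_init__(self):
        if self.l <= 0:
            raise ParameterError(f"bond length must be > 0, got {self.l}")
        if not 0.0 <= self.alpha < 1.0:
            raise ParameterError(f"alpha must lie in [0, 1), got {self.alpha}")

    def mean_square_distance(self, n):
        return frc_mean_square_distance(n, self)


@dataclass(frozen=True)
class RgSummary:
    per_frame: np.ndarray = field(repr=False)
    mean: float = 0.0
    sd: float = 0.0


@dataclass(frozen=True)
class ScatteringProfile:
    q: np.ndarray = field(repr=False)
    intensity: np.ndarray = field(repr=False)

    def __post_init__(self):
        q = np.asarray(self.q, float)
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise ParameterError("q grid must be positive and strictly increasing")


@dataclass(frozen=True)
class GuinierResult:
    rg: float
    i0: float
    q_min: float
    q_max: float
    n_points: int
    success: bool
    message: str = ""


def radius_of_gyration(ensemble: ConformationalEnsemble) -> RgSummary:
    """Per-frame mass-weighted radius of gyration with mean/sd summary."""
    if ensemble.n_frames < 1:
        raise InputError("ensemble has no frames")
    m = ensemble.masses
    w = m / m.sum()
    com = np.einsum("fbi,b->fi", ensemble.coords, w)
    d2 = ((ensemble.coords - com[:, None, :]) ** 2).sum(axis=2)
    rg = np.sqrt(np.einsum("fb,b->f", d2, w))
    return RgSummary(per_frame=rg, mean=float(rg.mean()), sd=float(rg.std(ddof=0)))


def mean_distance_map(ensemble: ConformationalEnsemble) -> np.ndarray:
    """Ensemble-mean inter-bead distance matrix (Å), symmetric, zero diagonal."""
    x = ensemble.coords
    diff = x[:, :, None, :] - x[:, None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    return d.mean(axis=0)


def frc_mean_square_distance(n, model: NullChainModel = NullChainModel()):
    """Closed-form FRC mean-square distance (Å²) between monomers ``n`` apart."""
    n_arr = np.asarray(n)
    if np.any(n_arr < 1):
        raise ParameterError("separation n must be >= 1")
    a = model.alpha
    l2 = model.l**2
    bracket = (1 + a) / (1 - a) - 2 * a * (1 - a**n_arr) / (n_arr * (1 - a) ** 2)
    out = n_arr * l2 * bracket
    return float(out) if np.isscalar(n) else out


class AnalyticalFloryCoil:
    """Analytical Flory random coil: sequence-length-only ideal-chain reference.

    Inter-residue separations are Gaussian with
    ``<r²(n)> = 6 R0² n`` (ν = 1/2); ``R0`` is the empirical polypeptide
    radius-of-gyration prefactor (Rg ≈ R0·√N), default 2.52 Å.
    """

    def __init__(self, n_residues: int, r0: float = 2.52):
        if n_residues < 2:
            raise ParameterError(f"n_residues must be >= 2, got {n_residues}")
        if r0 <= 0:
            raise ParameterError("r0 must be positive")
        self.n_residues = int(n_residues)
        self.r0 = float(r0)
        self.b2 = 6.0 * r0**2  # per-residue mean-square segment length

    def mean_square_distance(self, n):
        """<r²> (Å²) at separation n (0 at n=0)."""
        return self.b2 * np.asarray(n, dtype=float)

    def rms_distance(self, n):
        return np.sqrt(self.mean_square_distance(n))

    def mean_distance(self, n):
        """<r> at separation n for the 3D Gaussian separation distribution."""
        return np.sqrt(8.0 * self.mean_square_distance(n) / (3.0 * np.pi))

    def mean_rg(self) -> float:
        """Exact finite-N ideal-chain Rg: Rg² = (1/N²)·Σ_{i<j}<r²(j−i)>."""
        N = self.n_residues
        # Σ_{i<j}(j−i) = N(N²−1)/6
        return float(np.sqrt(self.b2 * (N**2 - 1) / (6.0 * N)))

    def distance_profile(self, kind: str = "rms") -> np.ndarray:
        """Expected distance for every separation 0..N−1."""
        n = np.arange(self.n_residues)
        return self.rms_distance(n) if kind == "rms" else self.mean_distance(n)


def afrc_reference(n_residues: int, r0: float = 2.52) -> AnalyticalFloryCoil:
    """Random-coil reference for an ``n_residues``-long chain (see class docs)."""
    return AnalyticalFloryCoil(n_residues, r0=r0)


def normalized_distance_map(dmap: np.ndarray, null_by_separation: np.ndarray
                            ) -> np.ndarray:
    """Ratio of a mean distance map to a per-separation null expectation.

    ``null_by_separation[k]`` is the expected distance at sequence separation
    k; the diagonal of the result is defined as 1.
    """
    dmap = np.asarray(dmap, float)
    null = np.asarray(null_by_separation, float)
    n = dmap.shape[0]
    if dmap.shape != (n, n):
        raise InputError("distance map must be square")
    if null.shape[0] < n:
        raise InputError("null profile shorter than the map dimension")
    sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    denom = null[sep]
    off = sep > 0
    if np.any(denom[off] <= 0):
        raise ModelDomainError("null expectation must be positive off-diagonal")
    out = np.ones_like(dmap)
    out[off] = dmap[off] / denom[off]
    return out


def debye_scattering(ensemble: ConformationalEnsemble, q: np.ndarray,
                     chunk: int = 256) -> ScatteringProfile:
    """Ensemble-averaged Debye sum with unit form factors.

    I(q) = < Σ_ij sinc(q·r_ij) >_frames, so I(q→0) → N².
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ParameterError("q must be strictly positive")
    x = ensemble.coords
    n_frames, n_beads = x.shape[:2]
    iu = np.triu_indices(n_beads, k=1)
    total = np.zeros_like(q)
    for start in range(0, n_frames, chunk):
        blk = x[start:start + chunk]
        diff = blk[:, :, None, :] - blk[:, None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))[:, iu[0], iu[1]]  # (chunk, n_pairs)
        qd = q[None, None, :] * d[:, :, None]
        total += 2.0 * np.sinc(qd / np.pi).sum(axis=(0, 1))
    intensity = n_beads + total / n_frames
    return ScatteringProfile(q=q, intensity=intensity)


def guinier_fit(profile: ScatteringProfile, qrg_limit: float = 1.1,
                max_iter: int = 100) -> GuinierResult:
    """Guinier analysis: ln I = ln I0 − q²Rg²/3 over a self-consistent range.

    Starting from the full low-q window, the upper q bound is shrunk until
    q_max·Rg ≤ ``qrg_limit``.  Returns a failure-flagged result (not an
    exception) when the slope is non-negative or the range collapses below
    4 points.
    """
    q, i = profile.q, profile.intensity
    if np.any(i <= 0):
        return GuinierResult(np.nan, np.nan, np.nan, np.nan, 0, False,
                             "non-positive intensities")
    n_use = len(q)
    rg = np.nan
    for _ in range(max_iter):
        if n_use < 4:
            return GuinierResult(np.nan, np.nan, np.nan, np.nan, n_use, False,
                                 "fewer than 4 points in the Guinier range")
        slope, intercept = np.polyfit(q[:n_use] ** 2, np.log(i[:n_use]), 1)
        if slope >= 0:
            return GuinierResult(np.nan, np.nan, np.nan, np.nan, n_use, False,
                                 "non-negative Guinier slope")
        rg = float(np.sqrt(-3.0 * slope))
        n_ok = int(np.searchsorted(q, qrg_limit / rg, side="right"))
        if n_ok >= n_use:
            return GuinierResult(rg, float(np.exp(intercept)), float(q[0]),
                                 float(q[n_use - 1]), n_use, True)
        n_use = n_ok
    return GuinierResult(np.nan, np.nan, np.nan, np.nan, n_use, False,
                         "range iteration did not converge")


def dimensionless_kratky(profile: ScatteringProfile, guinier: GuinierResult):
    """(qRg, (qRg)²·I/I0) series on the profile's native q grid."""
    if not guinier.success or guinier.i0 <= 0:
        raise ParameterError("a successful Guinier result with I0 > 0 is required")
    x = profile.q * guinier.rg
    y = x**2 * profile.intensity / guinier.i0
    return x, y


def rg_density(per_frame_rg: np.ndarray, grid: np.ndarray | None = None):
    """Gaussian-KDE (Silverman bandwidth) summary of an Rg distribution."""
    rg = np.asarray(per_frame_rg, float)
    if rg.size < 2:
        raise InputError("need at least two Rg values for a density estimate")
    kde = stats.gaussian_kde(rg, bw_method="silverman")
    if grid is None:
        pad = 0.15 * (rg.max() - rg.min() + 1e-12)
        grid = np.linspace(rg.min() - pad, rg.max() + pad, 256)
    return grid, kde(grid)
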