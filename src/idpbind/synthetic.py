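"""Seeded generators emulating the data every pipeline stage consumes.

These stand in for the instruments and simulation engines: freely rotating
chain ensembles (disordered-chain statistics), two-state bound/unbound COM
distance trajectories in a periodic box (coarse-grained binding runs),
anisotropy/CSP titrations under the 1:1 quadratic model, and
single-exponential relaxation decays.  Every generator is a pure function of
its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding import BindingModelParams, TitrationSeries, anisotropy_model, fraction_bound
from .exceptions import ParameterError
from .geometry import ConformationalEnsemble, NullChainModel
from .nmr import RelaxationSeries
from .simkd import ComDistanceTrajectory, SimulationBox

__all__ = [
    "BindingTrajectoryRecord",
    "BindingTruth",
    "sample_frc_ensemble",
    "simulate_binding_trajectory",
    "generate_anisotropy_titration",
    "generate_csp_titration",
    "generate_decay_series",
]


@dataclass(frozen=True)
class BindingTrajectoryRecord:
    """Ground truth accompanying a simulated trajectory: parameters and the
    per-frame bound/unbound state of the hidden Markov chain."""

    truth: "BindingTruth"
    states: np.ndarray


@dataclass(frozen=True)
class BindingTruth:
    """Ground truth of a two-state binding trajectory.

    Per-frame switching probabilities ``p_on`` (unbound→bound) and ``p_off``
    (bound→unbound) give the stationary bound fraction
    f* = p_on/(p_on + p_off); the implied single-pair mass-action truth is
    K_D = c_box·(1 − f*)²/f*.  Bound frames emit distances from a positive-
    truncated Normal(μ_b, σ_b); unbound frames emit from the r²-weighted
    density on (0, box half-diagonal).
    """

    p_on: float
    p_off: float
    mu_b: float = 30.0
    sigma_b: float = 5.0
    box: SimulationBox = SimulationBox(40.0)

    def __post_init__(self):
        for name in ("p_on", "p_off"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ParameterError(f"{name} must lie in (0, 1), got {p}")
        if self.mu_b <= 0 or self.sigma_b <= 0:
            raise ParameterError("bound-state distance parameters must be > 0")

    @classmethod
    def from_bound_fraction(cls, f_star: float, mean_bound_lifetime: float = 40.0,
                            **kwargs) -> "BindingTruth":
        """Truth with a target stationary fraction and bound-run lifetime (frames)."""
        if not 0 < f_star < 1:
            raise ParameterError("f_star must lie in (0, 1)")
        p_off = 1.0 / mean_bound_lifetime
        p_on = p_off * f_star / (1.0 - f_star)
        return cls(p_on=p_on, p_off=p_off, **kwargs)

    @property
    def f_star(self) -> float:
        return self.p_on / (self.p_on + self.p_off)

    @property
    def kd_uM(self) -> float:
        f = self.f_star
        return self.box.c_box_uM * (1.0 - f) ** 2 / f


def sample_frc_ensemble(n_residues: int, model: NullChainModel = NullChainModel(),
                        n_frames: int = 1000, seed: int = 0
                        ) -> ConformationalEnsemble:
    """Freely rotating chains: fixed bond length, fixed bond-angle supplement
    cosine, uniform dihedrals.

    Every bond has length ``model.l`` and every consecutive bond pair the
    angle arccos(alpha) between directions, so the ensemble's mean-square
    inter-residue distances converge to the FRC closed form.
    """
    if n_residues < 2:
        raise ParameterError("n_residues must be >= 2")
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    l, a = model.l, model.alpha
    sin_g = np.sqrt(1.0 - a**2)

    # isotropic first bond direction per frame
    u = rng.normal(size=(n_frames, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    coords = np.zeros((n_frames, n_residues, 3))
    coords[:, 1] = coords[:, 0] + l * u
    for k in range(2, n_residues):
        # orthonormal frame transverse to the previous bond direction
        ref = np.where(np.abs(u[:, :1]) < 0.9,
                       np.tile([1.0, 0.0, 0.0], (n_frames, 1)),
                       np.tile([0.0, 1.0, 0.0], (n_frames, 1)))
        e1 = np.cross(u, ref)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(u, e1)
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n_frames)
        u = (a * u
             + sin_g * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        coords[:, k] = coords[:, k - 1] + l * u
    return ConformationalEnsemble(coords=coords, name="frc")


def simulate_binding_trajectory(truth: BindingTruth, n_frames: int,
                                seed: int = 0, min_run: int = 5
                                ) -> tuple[ComDistanceTrajectory,
                                           BindingTrajectoryRecord]:
    """Two-state Markov COM-distance trace with known stationary occupancy.

    The state chain starts from its stationary distribution.  Bound frames
    draw distances from Normal(μ_b, σ_b) truncated positive; unbound frames
    from the density ∝ r² on (0, half-diagonal) — the distance distribution
    of an ideally mixed pair, approximated without the periodic-image
    corners' anisotropy.
    """
    if n_frames < 10 * min_run:
        raise ParameterError(f"need at least {10 * min_run} frames")
    rng = np.random.default_rng(seed)
    p_on, p_off = truth.p_on, truth.p_off

    u = rng.random(n_frames)
    state = np.empty(n_frames, dtype=bool)
    state[0] = u[0] < truth.f_star
    for i in range(1, n_frames):
        state[i] = (u[i] < p_on) if not state[i - 1] else (u[i] >= p_off)

    d = np.empty(n_frames)
    n_bound = int(state.sum())
    # positive-truncated normal by redraw
    db = rng.normal(truth.mu_b, truth.sigma_b, size=n_bound)
    while np.any(db <= 0):
        bad = db <= 0
        db[bad] = rng.normal(truth.mu_b, truth.sigma_b, size=int(bad.sum()))
    d[state] = db
    r_max = truth.box.half_diagonal_angstrom
    d[~state] = r_max * rng.random(n_frames - n_bound) ** (1.0 / 3.0)
    return ComDistanceTrajectory(distances=d), BindingTrajectoryRecord(truth, state)


def generate_anisotropy_titration(params: BindingModelParams, m_total: float,
                                  ligand_grid, noise_sd: float = 0.0,
                                  seed: int = 0) -> TitrationSeries:
    """Anisotropy titration from the 1:1 model plus Gaussian noise."""
    grid = np.asarray(ligand_grid, float)
    if np.any(grid < 0):
        raise ParameterError("ligand concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    fb = fraction_bound(params.kd, grid, m_total)
    obs = anisotropy_model(fb, params)
    obs = obs + rng.normal(0.0, noise_sd, size=grid.shape)
    return TitrationSeries(ligand_totals=grid, m_total=m_total,
                           observable=obs, kind="anisotropy")


def generate_csp_titration(kd: float, dd_max: float, m_total: float,
                           ligand_grid, noise_sd: float = 0.0,
                           seed: int = 0) -> TitrationSeries:
    """CSP titration Δδ = Δδ_max·F_B plus Gaussian noise."""
    grid = np.asarray(ligand_grid, float)
    if np.any(grid < 0):
        raise ParameterError("ligand concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    obs = dd_max * fraction_bound(kd, grid, m_total)
    obs = obs + rng.normal(0.0, noise_sd, size=grid.shape)
    return TitrationSeries(ligand_totals=grid, m_total=m_total,
                           observable=obs, kind="csp")


def generate_decay_series(T: float, I0: float, delays, noise_sd: float = 0.0,
                          seed: int = 0) -> RelaxationSeries:
    """Single-exponential decay I = I0·exp(−t/T) plus Gaussian noise."""
    if T <= 0:
        raise ParameterError("relaxation time T must be > 0")
    t = np.asarray(delays, float)
    if np.any(t < 0):
        raise ParameterError("delays must be non-negative")
    rng = np.random.default_rng(seed)
    i = I0 * np.exp(-t / T) + rng.normal(0.0, noise_sd, size=t.shape)
    return RelaxationSeries(delays=t, intensities=i)
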