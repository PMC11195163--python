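"""Dissociation constants from two-molecule coarse-grained trajectories.

Pipeline: per-frame centre-of-mass (COM) separation under the minimum-image
convention → two-Gaussian decomposition of the distance histogram (bound mode
at short range, unbound mode at long range) → bound/unbound threshold at the
Gaussian intersection → per-frame labels with a minimum bound-run lifetime
(default 5 frames, separating complexes from stochastic encounters) →
single-pair mass action

    K_D = c_box · (1 − f)² / f,

where f is the bound-frame fraction and c_box the concentration of one
molecule in the periodic box.  Contact footprints are the fraction of bound
frames in which a residue pair lies within a cutoff (default 15 Å).

``BindingTrajectoryModel`` wraps the whole pipeline in a fit()/results
object; the individual stages are exposed as functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit
from scipy.stats import norm

from .exceptions import InputError, ModelDomainError, ParameterError
from .geometry import ConformationalEnsemble

__all__ = [
    "AVOGADRO",
    "SimulationBox",
    "ComDistanceTrajectory",
    "TwoGaussianFit",
    "BoundAnnotation",
    "ContactMap",
    "KdEstimate",
    "coarse_grain_rna_structure",
    "com_distance_trajectory",
    "fit_two_gaussian_rdf",
    "bound_threshold",
    "classify_bound_frames",
    "apparent_kd",
    "relative_kd",
    "contact_frequency",
    "BindingTrajectoryModel",
    "TrajectoryKdResults",
]

AVOGADRO = 6.02214e23


@dataclass(frozen=True)
class SimulationBox:
    """Cubic periodic box; edge in nm."""

    edge_nm: float

    def __post_init__(self):
        if self.edge_nm <= 0:
            raise ParameterError("box edge must be > 0")

    @property
    def edge_angstrom(self) -> float:
        return self.edge_nm * 10.0

    @property
    def volume_nm3(self) -> float:
        return self.edge_nm**3

    @property
    def c_box_uM(self) -> float:
        """Concentration (μM) of a single molecule in the box."""
        litres = self.volume_nm3 * 1e-24
        return 1.0 / (litres * AVOGADRO) * 1e6

    @property
    def half_diagonal_angstrom(self) -> float:
        return self.edge_angstrom * np.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class ComDistanceTrajectory:
    """Per-frame COM separation (Å) of a molecular pair."""

    distances: np.ndarray = field(repr=False)
    frame_interval: float = 1.0
    molecules: tuple = ("A", "B")

    def __post_init__(self):
        d = np.asarray(self.distances, float)
        object.__setattr__(self, "distances", d)
        if d.ndim != 1 or np.any(d < 0) or not np.all(np.isfinite(d)):
            raise InputError("distances must be a finite non-negative 1D array")

    def __len__(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class TwoGaussianFit:
    """A₁N(μ₁,σ₁) + A₂N(μ₂,σ₂) decomposition of the COM distance density."""

    a1: float
    mu1: float
    sigma1: float
    a2: float
    mu2: float
    sigma2: float
    converged: bool
    unbound_present: bool
    message: str = ""

    def density(self, x):
        return (self.a1 * norm.pdf(x, self.mu1, self.sigma1)
                + self.a2 * norm.pdf(x, self.mu2, self.sigma2))


@dataclass(frozen=True)
class BoundAnnotation:
    """Per-frame bound labels after lifetime filtering."""

    bound: np.ndarray = field(repr=False)
    threshold: float = 0.0
    min_run: int = 5

    @property
    def fraction_bound(self) -> float:
        return float(self.bound.mean())

    def __len__(self) -> int:
        return len(self.bound)


@dataclass(frozen=True)
class ContactMap:
    """Contact frequencies over bound frames plus per-residue marginals."""

    frequencies: np.ndarray = field(repr=False)
    cutoff: float = 15.0
    marginal_a_max: np.ndarray = field(repr=False, default=None)
    marginal_a_mean: np.ndarray = field(repr=False, default=None)
    marginal_b_max: np.ndarray = field(repr=False, default=None)
    marginal_b_mean: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class KdEstimate:
    kd_uM: float
    fraction_bound: float
    c_box_uM: float
    correction: float = 1.0


def coarse_grain_rna_structure(structure, atom_name: str = "C1'"
                               ) -> ConformationalEnsemble:
    """One bead per nucleotide from a (multi-model) atomic structure.

    ``structure`` is a Bio.PDB Structure or a path to a multi-model PDB file;
    each model becomes one frame, each nucleotide contributes the coordinates
    of ``atom_name`` (C1′ by default).  Non-nucleotide residues are skipped
    with a warning; a nucleotide lacking the atom is an error naming it.
    """
    import warnings

    from Bio.PDB import PDBParser

    if isinstance(structure, (str, bytes)) or hasattr(structure, "__fspath__"):
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("rna", structure)

    nucleotides = {"A", "C", "G", "U", "RA", "RC", "RG", "RU",
                   "DA", "DC", "DG", "DT"}
    frames, labels = [], None
    for model in structure:
        coords, model_labels = [], []
        for chain in model:
            for res in chain:
                resname = res.get_resname().strip()
                if resname not in nucleotides:
                    warnings.warn(f"skipping non-nucleotide residue {resname} "
                                  f"{res.id[1]}")
                    continue
                if atom_name not in res:
                    raise InputError(
                        f"nucleotide {resname} {res.id[1]} lacks atom {atom_name}"
                    )
                coords.append(res[atom_name].coord)
                model_labels.append(f"{res.id[1]} {resname}")
        frames.append(np.asarray(coords, float))
        labels = labels or model_labels
    if not frames:
        raise InputError("structure contains no models")
    return ConformationalEnsemble(coords=np.stack(frames), labels=labels)


def com_distance_trajectory(traj: ConformationalEnsemble,
                            partition: tuple[np.ndarray, np.ndarray],
                            box: SimulationBox) -> ComDistanceTrajectory:
    """Minimum-image COM separation of two disjoint bead groups per frame."""
    idx_a = np.asarray(partition[0], int)
    idx_b = np.asarray(partition[1], int)
    if np.intersect1d(idx_a, idx_b).size:
        raise InputError("partition groups overlap")
    if len(np.union1d(idx_a, idx_b)) != traj.n_beads:
        raise InputError("partition must cover every bead exactly once")
    m = traj.masses
    com_a = np.einsum("fbi,b->fi", traj.coords[:, idx_a], m[idx_a]) / m[idx_a].sum()
    com_b = np.einsum("fbi,b->fi", traj.coords[:, idx_b], m[idx_b]) / m[idx_b].sum()
    delta = com_a - com_b
    edge = box.edge_angstrom
    delta -= edge * np.round(delta / edge)
    d = np.linalg.norm(delta, axis=1)
    return ComDistanceTrajectory(distances=d)


def _histogram_bins(x: np.ndarray, n_bins: int | None) -> np.ndarray:
    if n_bins is not None:
        if n_bins < 20:
            raise ParameterError("need at least 20 bins")
        return np.histogram_bin_edges(x, bins=n_bins)
    return np.histogram_bin_edges(x, bins="fd")


def _two_gauss(x, a1, mu1, s1, a2, mu2, s2):
    return a1 * norm.pdf(x, mu1, s1) + a2 * norm.pdf(x, mu2, s2)


def _initial_modes(centers: np.ndarray, density: np.ndarray):
    """Two well-separated starting means: the global peak and the highest
    peak at least a quarter of the range away; percentile fallback."""
    i_max = int(np.argmax(density))
    span = centers[-1] - centers[0]
    far = np.abs(centers - centers[i_max]) > span / 4
    if far.any():
        j = int(np.argmax(np.where(far, density, -np.inf)))
        return sorted([centers[i_max], centers[j]])
    return [centers[int(len(centers) * 0.1)], centers[int(len(centers) * 0.75)]]


def fit_two_gaussian_rdf(distances: ComDistanceTrajectory,
                         n_bins: int | None = None) -> TwoGaussianFit:
    """Two-Gaussian fit of the COM distance histogram density.

    The distance histogram is fitted directly (no r² shell normalisation),
    so the component means live in distance space.  The smaller-mean
    component is the bound mode.  The unbound-component-present flag is
    cleared when the larger-mean amplitude is negligible or the fit fails;
    such replicates are meant to be omitted from K_D aggregation.
    """
    x = distances.distances
    edges = _histogram_bins(x, n_bins)
    density, _ = np.histogram(x, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu_lo, mu_hi = _initial_modes(centers, density)
    span = max(centers[-1] - centers[0], 1e-6)
    p0 = [0.5, mu_lo, span / 20, 0.5, mu_hi, span / 8]
    bounds = ([0, centers[0], 1e-6, 0, centers[0], 1e-6],
              [np.inf, centers[-1], span, np.inf, centers[-1], span])
    try:
        popt, _ = curve_fit(_two_gauss, centers, density, p0=p0,
                            bounds=bounds, maxfev=20000)
    except RuntimeError as e:
        return TwoGaussianFit(*p0, converged=False, unbound_present=False,
                              message=f"fit failed: {e}")
    a1, mu1, s1, a2, mu2, s2 = popt
    if mu1 > mu2:  # order components by mean
        a1, mu1, s1, a2, mu2, s2 = a2, mu2, s2, a1, mu1, s1
    fit = TwoGaussianFit(a1=float(a1), mu1=float(mu1), sigma1=float(s1),
                         a2=float(a2), mu2=float(mu2), sigma2=float(s2),
                         converged=True, unbound_present=True)
    # a distinct unbound mode needs non-negligible amplitude AND a genuine
    # valley between the two component means (guards against a unimodal
    # histogram being split into two overlapping Gaussians)
    total = a1 + a2
    bimodal = False
    if total > 0 and a2 / total > 1e-3 and mu2 > mu1:
        between = np.linspace(mu1, mu2, 512)
        valley = fit.density(between).min()
        peaks = min(fit.density(np.array([mu1]))[0],
                    fit.density(np.array([mu2]))[0])
        bimodal = valley < 0.7 * peaks
    if not bimodal:
        fit = TwoGaussianFit(a1=fit.a1, mu1=fit.mu1, sigma1=fit.sigma1,
                             a2=fit.a2, mu2=fit.mu2, sigma2=fit.sigma2,
                             converged=True, unbound_present=False,
                             message="no distinct unbound mode")
    return fit


def bound_threshold(fit: TwoGaussianFit) -> float:
    """Bound/unbound threshold: intersection of the two Gaussians in (μ₁, μ₂)."""
    if not (fit.converged and fit.unbound_present):
        raise ModelDomainError("threshold requires a converged two-component fit")

    def diff(x):
        return (fit.a1 * norm.pdf(x, fit.mu1, fit.sigma1)
                - fit.a2 * norm.pdf(x, fit.mu2, fit.sigma2))

    lo, hi = fit.mu1, fit.mu2
    grid = np.linspace(lo, hi, 2048)
    vals = diff(grid)
    sign = np.sign(vals)
    changes = np.nonzero(np.diff(sign))[0]
    if len(changes) == 0:
        raise ModelDomainError("no Gaussian intersection between the two means")
    i = changes[0]
    return float(brentq(diff, grid[i], grid[i + 1]))


def classify_bound_frames(distances: ComDistanceTrajectory, threshold: float,
                          min_run: int = 5) -> BoundAnnotation:
    """Label frames bound when they sit in a below-threshold run of ≥ min_run."""
    if threshold <= 0:
        raise ParameterError("threshold must be > 0")
    if min_run < 1:
        raise ParameterError("min_run must be >= 1")
    below = distances.distances < threshold
    bound = np.zeros_like(below)
    n = len(below)
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= min_run:
                bound[i:j] = True
            i = j
        else:
            i += 1
    return BoundAnnotation(bound=bound, threshold=float(threshold),
                           min_run=int(min_run))


def apparent_kd(annotation: BoundAnnotation, box: SimulationBox,
                correction: float = 1.0) -> KdEstimate:
    """Single-pair mass-action K_D (μM) from the bound-frame fraction.

    ``correction`` is an optional multiplicative finite-size factor applied
    to the uncorrected relation (default 1, i.e. no correction).
    """
    f = annotation.fraction_bound
    if f <= 0:
        raise ModelDomainError("no bound frames: K_D is unbounded")
    if f >= 1:
        raise ModelDomainError("no unbound frames: K_D is zero-identified")
    c = box.c_box_uM
    return KdEstimate(kd_uM=float(correction * c * (1 - f) ** 2 / f),
                      fraction_bound=f, c_box_uM=c, correction=correction)


def relative_kd(kd: float, reference_kd: float) -> float:
    """Fold tighter than the reference: reference_kd / kd."""
    if kd <= 0 or reference_kd <= 0:
        raise ParameterError("dissociation constants must be > 0")
    return reference_kd / kd


def contact_frequency(traj: ConformationalEnsemble,
                      partition: tuple[np.ndarray, np.ndarray],
                      annotation: BoundAnnotation,
                      cutoff: float = 15.0) -> ContactMap:
    """Pairwise contact frequencies over bound frames.

    frequency(i, j) = fraction of bound frames with |x_i − x_j| < cutoff for
    bead i of group A and bead j of group B.  Marginals report, per residue,
    both the maximum and the mean over partners.
    """
    if len(annotation) != traj.n_frames:
        raise InputError("annotation does not align with the trajectory")
    mask = annotation.bound
    if not mask.any():
        raise ModelDomainError("no bound frames: contact map undefined")
    idx_a = np.asarray(partition[0], int)
    idx_b = np.asarray(partition[1], int)
    xa = traj.coords[mask][:, idx_a]
    xb = traj.coords[mask][:, idx_b]
    d = np.linalg.norm(xa[:, :, None, :] - xb[:, None, :, :], axis=-1)
    freq = (d < cutoff).mean(axis=0)
    return ContactMap(frequencies=freq, cutoff=float(cutoff),
                      marginal_a_max=freq.max(axis=1),
                      marginal_a_mean=freq.mean(axis=1),
                      marginal_b_max=freq.max(axis=0),
                      marginal_b_mean=freq.mean(axis=0))


@dataclass(frozen=True)
class TrajectoryKdResults:
    """End-to-end trajectory K_D analysis: fit, threshold, labels, estimate."""

    rdf_fit: TwoGaussianFit
    threshold: float
    annotation: BoundAnnotation = field(repr=False)
    kd: KdEstimate | None = None
    omitted: bool = False
    message: str = ""

    def summary(self) -> str:
        lines = ["Trajectory dissociation-constant analysis",
                 "-----------------------------------------"]
        f = self.rdf_fit
        lines.append(f"  bound mode:   μ = {f.mu1:.2f} Å, σ = {f.sigma1:.2f} Å")
        lines.append(f"  unbound mode: μ = {f.mu2:.2f} Å, σ = {f.sigma2:.2f} Å"
                     f" (present: {f.unbound_present})")
        if self.omitted:
            lines.append(f"  replicate omitted: {self.message}")
            return "\n".join(lines)
        lines.append(f"  threshold = {self.threshold:.2f} Å "
                     f"(min run {self.annotation.min_run} frames)")
        lines.append(f"  fraction bound = {self.annotation.fraction_bound:.4f}")
        lines.append(f"  K_D = {self.kd.kd_uM:.3g} μM "
                     f"(c_box = {self.kd.c_box_uM:.3g} μM)")
        return "\n".join(lines)


class BindingTrajectoryModel:
    """COM-distance trajectory → apparent K_D, statsmodels-style.

    ``fit()`` runs the two-Gaussian decomposition, threshold determination,
    lifetime filtering and mass-action conversion; a replicate whose
    distance histogram lacks an unbound component is flagged ``omitted``
    instead of yielding a K_D.
    """

    def __init__(self, distances: ComDistanceTrajectory, box: SimulationBox):
        self.distances = distances
        self.box = box

    def fit(self, min_run: int = 5, threshold: float | None = None,
            n_bins: int | None = None, correction: float = 1.0
            ) -> TrajectoryKdResults:
        gfit = fit_two_gaussian_rdf(self.distances, n_bins=n_bins)
        if threshold is None:
            if not (gfit.converged and gfit.unbound_present):
                empty = BoundAnnotation(bound=np.zeros(len(self.distances), bool),
                                        threshold=np.nan, min_run=min_run)
                return TrajectoryKdResults(rdf_fit=gfit, threshold=np.nan,
                                           annotation=empty, omitted=True,
                                           message=gfit.message
                                           or "no unbound component")
            threshold = bound_threshold(gfit)
        ann = classify_bound_frames(self.distances, threshold, min_run=min_run)
        kd = apparent_kd(ann, self.box, correction=correction)
        return TrajectoryKdResults(rdf_fit=gfit, threshold=float(threshold),
                                   annotation=ann, kd=kd)
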