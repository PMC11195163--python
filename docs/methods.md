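# Methods

This note records the models the package implements, the defaults that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was open.

## Charge model

Formal charges use the fixed-charge convention common in coarse-grained
models of charged IDPs: Arg/Lys +1, Asp/Glu −1, His/Cys/Tyr neutral, termini
neutral (the simulated protein construct is capped), and −1 per
ribonucleotide regardless of 5′ end chemistry. The rule is defined at
pH 7.5; no pKa titration model is included. NCPR profiles use truncated
windows at the chain ends so the profile covers every residue. The
charge-match ratio |q_RNA|/q_protein is the protein:RNA molar ratio at which
total charges balance — the stoichiometry at which associative phase
separation of oppositely charged polymers is expected to peak.

## Random-coil references

Two nulls with different roles:

* **Freely rotating chain (FRC)** — fixed bond length l = 3.8 Å (the Cα–Cα
  virtual bond), fixed bond-angle-supplement cosine α = 0.8, uniform
  dihedrals. Its closed-form mean-square separation (README equation) is the
  null for PRE profiles, and the sampler in `synthetic` realises exactly
  these statistics (bond constraints hold to machine precision by
  construction; the closed form is recovered within Monte-Carlo error).

* **Analytical Flory random coil (AFRC)** — a sequence-length-only
  ideal-chain reference: inter-residue separations are Gaussian with
  ⟨r²(n)⟩ = 6R₀²n, ν = 1/2, and the empirical polypeptide prefactor
  R₀ = 2.52 Å (R_g ≈ R₀√N). The mean R_g uses the exact finite-N sum
  R_g² = b²(N²−1)/(6N), giving 20.8 Å at N = 68. Distance-map normalisation
  divides each mean distance by the AFRC expectation at the same sequence
  separation; both the rms (√⟨r²⟩) and mean (⟨r⟩ = √(8⟨r²⟩/3π)) expectations
  are available, rms being the default denominator.

The two models deliberately disagree: the FRC with α = 0.8 has a Flory
characteristic ratio of 9 and is much more expanded (R_g ≈ 34 Å at N = 68)
than the AFRC (20.8 Å), which absorbs real-chain flexibility into its
empirical prefactor.

## Scattering

`debye_scattering` evaluates the Debye double sum with unit form factors, so
I(q→0) → N²; it is forward plumbing for testing Guinier/Kratky analysis, not
a solvent-corrected SAXS predictor. Guinier fitting iteratively shrinks the
upper q bound until q_max·R_g ≤ 1.1 (configurable). Note a mathematical
caveat verified numerically: applied to an exact ideal-chain (Debye-function)
profile, the Guinier estimate is biased ~5% low at the 1.1 limit; 2%
accuracy requires q·R_g ≲ 0.7. The default stays at the field-standard 1.1;
oracle tests of ideal-chain profiles pass an explicit tighter limit. R_g
distributions are summarised by a Gaussian KDE with Silverman bandwidth.

## PRE forward model

Intensity ratios follow the two-step composition: distance → R₂sp (r⁻⁶
dipolar law with the Lorentzian spectral density 4τ_c + 3τ_c/(1+ω²τ_c²)) →
ratio. Defaults: R₂ = 8.1 s⁻¹, t = 50 ms, τ_c = 1 ns, proton constants at a
600 MHz field. Two values of the constant K are exposed because the printed
experimental constants (K_H = 1.23×10⁻²³, K_C = 7.78×10⁻³⁴ cm⁶s⁻²) are
mutually inconsistent with the defining expression
K = (1/15)S(S+1)γ²g²β², which evaluates (cgs) to K_H = 1.234×10⁻³²,
K_C = 1.976×10⁻³³ cm⁶s⁻². `k_mode="paper"` (default) returns the printed
values; `k_mode="computed"` evaluates the expression; every profile records
the mode used. With the printed K_H, any distance under ~430 Å is fully
bleached, so physically interpretable profiles on short chains require the
computed mode.

Ensemble averaging of the label–residue distance supports three modes:
`mean_distance` (⟨r⟩ then r⁻⁶ — the default, matching how the reference
experiments describe ⟨r⟩), `mean_inverse_sixth` (⟨r⁻⁶⟩, the conventional
choice that weights close approaches), and `root_mean_square` (√⟨r²⟩, the
estimator of the FRC null's own statistic — sampler-vs-null equivalence
tests must use this mode, since ⟨r⟩ and √⟨r²⟩ differ by ~8% for Gaussian
separations). The label residue itself is emitted with ratio 0 and flagged
(the null is degenerate at separation 0).

## Binding models

The 1:1 isotherm is solved in closed form (radicand b² − 4LM); F_B is the
fraction of the labelled macromolecule bound, which is what the fluorescence
observable reports. At M_total = 0 the hyperbolic limit L/(K_D+L) is used.
Anisotropy adds the intensity-change factor Q; Q = 1 reduces exactly to
linear mixing of r_F and r_B.

Fitting uses bounded least squares with data-driven starts (r_F from the
first point, r_B from the last, K_D from the half-range concentration,
Q = 1). All four parameters float by default. An identifiability caveat,
established by a Cramér–Rao analysis: at realistic anisotropy noise
(σ ≈ 0.002) K_D and Q trade off so strongly that K_D is effectively
unidentifiable when both float (bound ≈ 60–150% of K_D). Precision work
should calibrate or fix Q; the package's own round-trip experiments fix
Q at the generator truth and average three technical replicates per point,
which brings the K_D bound to ~3%.

CSP titrations fit Δδ_max·F_B. A single CSP curve in the weak-binding
regime (K_D ≈ 100 μM at 0.5 mM macromolecule) carries a K_D bound of
10–14% at 2% noise; the corresponding tests therefore average several
resonance curves, as a multi-resonance NMR titration does.

## Trajectory → K_D pipeline

The distance histogram is fitted directly with two Gaussians (no r² shell
normalisation), so the component means live in distance space; binning is
Freedman–Diaconis by default and the fit is initialised from the two most
prominent well-separated histogram peaks with a percentile fallback. A
distinct unbound mode is accepted only if its amplitude fraction exceeds
10⁻³ **and** the fitted mixture has a genuine valley between the component
means (minimum density < 0.7× the lower peak) — this guards against a
unimodal histogram being split into two overlapping Gaussians. Replicates
without a distinct unbound mode are flagged `omitted` rather than forced
into a K_D, mirroring the exclusion of under-sampled replicates.

The threshold is the root of A₁N(x;μ₁,σ₁) = A₂N(x;μ₂,σ₂) on (μ₁,μ₂) found
by bracketed root finding on a dense grid; a user-supplied threshold (e.g.
the 53.5 Å value used across the reference simulations) can override it.
Bound frames must sit in below-threshold runs of ≥ 5 frames — the lifetime
criterion separating complexes from stochastic encounters. K_D uses the
uncorrected single-pair relation K_D = c_box(1−f)²/f with c_box from the
box volume (25.95 μM for a 40 nm cube); a finite-size/virial correction is
exposed as an explicit multiplicative factor (default 1) rather than
applied silently, since no specific formula is adopted. Contact maps count,
over bound frames only, residue pairs within 15 Å; per-residue marginals
report both the maximum and the mean over partners.

## Synthetic generators and what they do not emulate

All generators are pure functions of their arguments including the seed
(bit-identical reruns). The binding-trajectory generator is a two-state
Markov chain started from its stationary distribution; bound frames emit
positive-truncated N(μ_b = 30 Å, σ_b = 5 Å) distances, unbound frames emit
from the density ∝ r² truncated at the box half-diagonal — a tractable
stand-in for two well-mixed points in a periodic box that ignores the
anisotropy of the box corners (this affects only the unbound mode's shape,
not the occupancy statistics). Default switching: mean bound lifetime 40
frames, with p_on set by the target stationary fraction; the lifetime was
chosen by balancing the ≥5-frame filter's truncation bias (which discards
≈10·p_off² of bound frames) against occupancy-mixing variance. The
generators produce none of the features that make real data hard — spectral
overlap, baseline drift, chemical exchange, force-field inaccuracies — so
passing round trips demonstrate correctness of the estimators, not
robustness to instrument artefacts.

Round-trip study conditions used by the tests and the acceptance script:
titrations on 32 concentrations spanning 0–30 μM at 0.2 μM labelled RNA
with σ = 0.002 per replicate and three replicates averaged; trajectories of
2×10⁵ frames (the scale of the reference simulation trajectories) at
stationary bound fractions 0.2/0.5/0.8.

## Degenerate inputs and tie-breaks

Flat titrations, constant relaxation decays, rising scattering profiles and
histograms without an unbound mode all return failure-flagged results (or
typed errors where the operation cannot produce a result object). Duplicate
relaxation delays are averaged before fitting. The two-Gaussian components
are ordered by mean after fitting; equality of means cannot survive the
ordering and the valley criterion.

## Known limitations

* The AFRC prefactor is a single empirical constant; sequence-specific
  corrections (charge patterning, proline content) are out of scope.
* PRE profiles ignore spin-label rotamers and internal dynamics (a single
  effective τ_c).
* The binding layer is strictly 1:1; cooperative or multi-site binding and
  global fits across titrations are not modelled.
* The K_D pipeline assumes exactly one molecule of each partner in the box
  and reports the uncorrected mass-action estimate by default.
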