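# idpbind

Quantitative analytics for complexes between a highly charged intrinsically
disordered protein (IDP) and RNA — built around the model system of the
68-residue yeast SERF protein (net charge +12) binding the HIV-1 TAR RNA
stem-loop (net charge −29). The package is aimed at biophysicists who
characterise such complexes with NMR, SAXS, fluorescence anisotropy and
coarse-grained simulation, and want the analysis layer of that workflow as
tested, reusable code.

## What it computes

**Sequence charge analytics** — formal net charge (Arg/Lys +1, Asp/Glu −1,
−1 per ribonucleotide), sliding-window net charge per residue (NCPR), and the
charge-matched protein:RNA stoichiometry |q_RNA|/q_protein that marks
complex-coacervation conditions.

**Ensemble geometry** — per-frame radius of gyration
R_g = √(Σmᵢ|xᵢ−x̄|²/Σmᵢ), ensemble-mean distance maps, Debye forward
scattering I(q) = ⟨Σᵢⱼ sinc(q·rᵢⱼ)⟩, Guinier analysis
(ln I ≈ ln I₀ − q²R_g²/3) and the dimensionless Kratky transform
(qR_g)²·I/I₀. Two random-coil nulls: the freely rotating chain (FRC),

    ⟨r²(n)⟩ = n·l²·[(1+α)/(1−α) − 2α(1−αⁿ)/(n(1−α)²)],  l = 3.8 Å, α = 0.8,

and the analytical Flory random coil (AFRC), a length-only Gaussian-chain
reference used to normalise distance maps and R_g.

**PRE forward calculation** — paramagnetic relaxation enhancement profiles
I_P/I_D = R₂·exp(−R₂sp·t)/(R₂+R₂sp) with
R₂sp = (K/r⁶)(4τ_c + 3τ_c/(1+ω²τ_c²)), from ensembles or from the FRC null.

**NMR observables** — single-exponential T₁/T₂ fits, combined chemical shift
perturbations Δδ = √(Δδ_H² + (γ_X/γ_H·Δδ_X)²), secondary chemical shifts
ΔδCα − ΔδCβ against a coil reference, hetNOE ratios.

**1:1 binding fits** — the quadratic isotherm
F_B = [b − √(b² − 4LM)]/2M with b = K_D + L + M, read out through anisotropy
(with the intensity factor Q) or CSP, as statsmodels-style Model/Results
objects with standard errors and `summary()`.

**Simulation K_D pipeline** — centre-of-mass distance trajectories under the
minimum-image convention, two-Gaussian decomposition of the distance
histogram, bound/unbound threshold at the Gaussian intersection, ≥5-frame
lifetime filtering, single-pair mass action K_D = c_box(1−f)²/f, and
bound-state contact maps (15 Å cutoff).

**Synthetic data** — seeded generators for FRC ensembles, two-state binding
trajectories with known stationary occupancy, titrations and relaxation
decays, so every stage is testable without instrument data.

## Worked example

```python
from idpbind import (net_charge, charge_match_ratio, afrc_reference,
                     sample_frc_ensemble, radius_of_gyration)
from idpbind.datasets import SERF_YEAST, TAR_HIV1
from idpbind.synthetic import BindingTruth, simulate_binding_trajectory
from idpbind.simkd import BindingTrajectoryModel

net_charge(SERF_YEAST), net_charge(TAR_HIV1)   # (12, -29)
charge_match_ratio(SERF_YEAST, TAR_HIV1)       # 2.42 : charge-matched ratio
afrc_reference(68).mean_rg()                   # 20.8 Å random-coil reference

ens = sample_frc_ensemble(68, n_frames=5000, seed=0)
radius_of_gyration(ens).mean                   # 34.2 Å (FRC is stiffer than AFRC)

truth = BindingTruth.from_bound_fraction(0.5)  # K_D truth 12.97 μM in a 40 nm box
traj, record = simulate_binding_trajectory(truth, 200_000, seed=0)
print(BindingTrajectoryModel(traj, truth.box).fit().summary())
```

```
Trajectory dissociation-constant analysis
-----------------------------------------
  bound mode:   μ = 30.01 Å, σ = 5.58 Å
  unbound mode: μ = 342.29 Å, σ = 103.81 Å (present: True)
  threshold = 49.77 Å (min run 5 frames)
  fraction bound = 0.5022
  K_D = 12.8 μM (c_box = 25.9 μM)
```

The recovered 12.8 μM agrees with the generator's mass-action truth
(13.0 μM): the pipeline identifies the bound mode near 30 Å, places the
threshold at the intersection of the two Gaussians, filters sub-lifetime
encounters, and converts the bound fraction to a dissociation constant at
the single-pair box concentration.

The same stages are available from the shell (`idpbind charge|rg|dmap|saxs|
pre|relaxfit|csp|bindfit|simkd|synth|run`); `idpbind run --demo` executes the
bundled end-to-end workflow and prints a per-stage report.

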