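# Methods

This note documents the models, estimators and numerical choices behind the
package, and what its desk-scale validation does and does not establish.

## Model landscapes

All collective variables are one-dimensional and all landscapes are sums of
Gaussian wells/barriers over a constant offset, evaluated analytically
(periodic landscapes sum the minimum-image displacement and its two
neighbouring images, so F(s) = F(s + 2π) to machine precision).

**Dihedral double well** (`make_dihedral_potential`).  Two periodic Gaussian
wells at ω = 0 (cis) and ω = π (trans) on [−π, π).  The two well depths are
calibrated by a 2-D root find (`scipy.optimize.fsolve` over refined extrema)
so that the point free-energy difference F(cis)−F(trans) and the barrier
max−F(trans) match the requested values to better than 10⁻⁶ kcal/mol.  The
default geometric well width is 0.5 rad for both basins; with equal widths
the basin-integrated ΔG differs from the point ΔG only through the curvature
ratio of the calibrated depths, about −0.10 kcal/mol for the free-amide
parameters — small against every tolerance used downstream.  Declared basin
intervals extend 2.4 widths (capped at 1.3 rad) around each minimum.

**Encapsulation coordinate** (`make_encapsulation_potential`).  A bounded
radial proxy on [0, r_max]: one in-cage well near 0.35·r_cage, one Gaussian
barrier at the cage radius, flat outside.  The multi-dimensional collective
variables a full atomistic treatment would use are deliberately collapsed
onto this 1-D radius.  Binding ΔG < 0 is measured from the in-well minimum
to the outer wall; requesting an exit barrier smaller than −ΔG is rejected
as infeasible (there would be no barrier seen from outside).

**Reaction profile** (`make_reaction_profile`).  Two bounded wells on
[0, 1]: reactant R at 0.25 (hydroxide at solvation distance from the
carbonyl) and tetrahedral intermediate TI at 0.75, calibrated the same way
from (ΔG_reac, forward barrier).

## Sampler

Overdamped (Brownian) dynamics, Euler–Maruyama:

    ds = −β D (F′(s) + V′(s,t)) dt + sqrt(2 D dt) ξ.

Overdamped rather than inertial Langevin because every quantity the
reconstruction needs enters through free-energy differences and rate
*ratios*, and the overdamped limit has clean analytic oracles (Boltzmann
stationarity, 2Dt free diffusion, detailed balance).  Times are reduced
units; no mapping to seconds is attempted — tabulated residence times in
seconds are used as data, never regenerated.

Defaults: D = 1, dt = 2×10⁻⁴ (dihedral, forces up to ~50 kcal/mol/rad) or
5×10⁻⁵ (reaction profiles, stiffer wells), chosen so the deterministic drift
per step stays far below the basin width; a step larger than half the domain
aborts the run with a step-size error.  Forces (physical and bias) are
linearly interpolated from a 512-point grid; hill deposition updates the
bias and its derivative on that grid analytically, including periodic
images.  Temperature defaults to 300 K with k_B = 0.0019872 kcal/mol/K.

**Well-tempered metadynamics.**  Hills of initial height h₀ are deposited
every `deposit_stride` steps with the standard tempering
h = h₀·exp(−V(s,t)/(k_B ΔT)), ΔT = (γ−1)T.  The isomerization protocol is
γ = 15, h₀ = 1.2 kcal/mol, σ = 0.35 rad, stride 500 steps.  The default run
length is 1.2×10⁷ steps: a 12-seed study showed the per-run spread of the
recovered basin ΔG drops from 0.45 kcal/mol at 2×10⁶ steps to 0.15 at
1.2×10⁷, so the three-seed protocol mean carries ≈0.09 kcal/mol statistical
error against the 0.5 kcal/mol recovery tolerance.

**Infrequent metadynamics.**  Slow deposition (the stride must exceed a
configurable floor so the basin relaxes between hills), stop at the first
commitment to the target basin, rescaled time t\* = Σ dt·exp(βV(s,t)).
Commitment means entering the target-basin interval shrunk by a margin
(default 0.1 CV units) on both edges — the committor definition is an
engineering choice, made conservative so recrossings are not counted.
Hills are never deposited after the transition step.  Replicas exhausting
the step cap are returned flagged censored and excluded from the rate MLE
by default; a censored-likelihood mode (τ = Σ all times / n_events) is
available and labelled.  Passing `metad=None` runs plain unbiased
first-passage sampling, used as the brute-force reference in tests.

## Free-energy estimation and conventions

Two independent estimators: F = −γ/(γ−1)·V(s, t_final) from the hills log,
and −k_BT·ln of the (final-bias reweighted, w ∝ exp(βV(s_i, t_final)))
sample histogram.  Cross-checking them on the same run, after discarding
the first quarter of frames as the fill-in transient, bounds the combined
estimator error (≤0.3 kcal/mol RMSD on all four tabulated landscapes at
10⁶ steps).  Histogram bins never visited are NaN — undefined, not clipped —
and basin integrals or barrier paths crossing them fail loudly with the gap
locations listed.

ΔG between basins follows two conventions, always recorded in the output:
*basin* (Boltzmann-integrated populations, trapezoidal quadrature; the
default, and the one consistent with the tabulated ΔG ↔ K_conf pairs at
300 K) and *point* (F at the minima; the convention behind the much smaller
figure-level conformer ratios).  Barriers are the maximum along the lower
connecting grid path minus the source minimum.  K = exp(−ΔG/k_BT) is used
exactly as printed, with no standard-state volume correction anywhere.

## Kinetics

τ is the maximum-likelihood mean of the uncensored rescaled times; k = 1/τ.
Uncertainty is a seeded percentile bootstrap (2000 resamples, 95% bounds).
Reliability follows the standard infrequent-metadynamics protocol: a
two-sided KS test of the times against Exp(τ) with the asymptotic p-value;
p < 0.05 flags the estimate unreliable.  Note the p-value is conservative
when τ is fitted from the same sample; the null-uniformity property is
therefore tested with the true τ.  k_on measured with the anion constrained
at solvation distance corresponds to a 55.6 M reference concentration (all
water replaced by hydroxide); `concentration_scaled_kon` applies the linear
pseudo-first-order rescaling to any actual concentration and is kept
strictly separate from the per-complex k_on tabulated for encapsulation,
whose concentration reference is not stated.

No rate-from-barrier (Eyring) operation is offered: the tabulated
isomerization times are not consistent with a single prefactor across
systems, so any such fit would be arbitrary.

## Reactivity combination

The ω sum runs over the discrete conformer set {0, π/4, π} — the conformers
with measured attack kinetics.  The π/2 conformer is omitted: it is too
unstable to carry meaningful kinetics, and its χ·P^conf product would be
negligible anyway (the truncation report lists every term with
χ·P^conf < 10⁻¹²; dropping them changes a by <0.1% on all fixtures).  NW
enters as the mean of the solvent-contact distribution.  Two routes for the
cage P^in are implemented and recorded: the strongly-bound simplification
P^in ≡ 1 (default; every tabulated complex has P^in > 0.999) and the
explicit per-conformer partition probabilities.  Uncertainty propagation
draws χ and P^conf log-normally (positive multiplicative quantities; the χ
draw is shared between environments since it is a conformer property) and
NW truncated-normally, independently per environment.

## Fixtures and synthetic data

The transcribed per-system tables (isomerization ΔG, barrier, K_conf,
transition times; encapsulation ΔG, K_enc, barrier, t_off, k_off, k_on) are
carried verbatim with provenance tags (`table1`/`table2`) in every
serialized output.  Two quantities needed by the combination exist only as
figure-level distributions and are therefore **synthetic fixtures**, tagged
`synthetic` everywhere: the mean solvent-contact counts NW_ω (order-unity
counts, decreasing with confinement, with the cis/trans exposure ordering
inverting only in the most crowded ternary complex) and the statistical
weight of the twisted π/4 conformer (10⁻¹²…10⁻⁹, a thousand-fold
stabilization under crowding).  Consequently the absolute acceleration
magnitudes this package prints are illustrative; the monotonic crowding
ordering a(2⊂1) < a(2₂⊂1) < a(2·3⊂1) is the assertable result, and is
insensitive to global NW rescaling by construction.

The bead-model generator exists purely as a substrate for the structural
observables: cage beads fixed on a golden-spiral shell, a guest cluster
whose center follows an exact-update Ornstein–Uhlenbeck walk (harmonic
confinement, so the stationary radial law is known).  It emulates none of
the chemistry — no binding, no conformers — so passing observable tests
demonstrates the estimators, not any property of real trajectories.
Likewise the Gaussian-mixture observable emulator reproduces histogram
*shapes* (SASA, contacts), not their physical origin.

## Observables

Contacts use the rational switching function (1−(r/r₀)ⁿ)/(1−(r/r₀)ᵐ),
default n = 6, m = 12, with the removable singularity at r = r₀ evaluated
as n/m.  SASA is Shrake–Rupley on a deterministic golden-spiral point shell
(default 960 points; exact duplicate spheres are collapsed first so
coincident copies are not double-counted).  Bead systems are finite and
non-periodic, so no minimum-image convention is applied.  2-D histogram
free-energy surfaces follow the same NaN-for-empty-bin rule as the 1-D
estimator.

## Problem sizes used in validation

The validation suite deliberately runs at desk scale: isomerization
recovery at 1.2×10⁷ steps × 3 seeds per landscape; estimator
cross-validation at 10⁶ steps per landscape; kinetics validity as 20
repeated ensembles of 20 replicas per direction on a 6 k_BT double well
(KS pass rate ≥90%, detailed-balance CI coverage ≥80%); stationarity by a
pooled-bin χ² test on a 4 k_BT double well subsampled at roughly the
basin-exchange time.

## Known limitations

* One-dimensional collective variables throughout; the real encapsulation
  and attack coordinates are multi-dimensional.
* Reduced-unit kinetics: the engine validates rate *ratios* and
  distributional properties, never absolute times in seconds.
* The cage never appears explicitly — its effect enters only through the
  conformer weights, partition probabilities and solvent-contact counts, so
  any genuinely catalytic role of the host is outside the model.
* Final-bias reweighting is a static approximation; it is accurate here
  because comparisons discard the fill-in transient, but it would bias
  strongly under-converged runs.
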