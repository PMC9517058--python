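# hostguest

Desk-scale reconstruction of chemical reactivity in dynamic host–guest
systems: how much a confining cavity accelerates a reaction when the guest
keeps exchanging in and out of the host, twisting between conformers of very
different reactivity, and competing with solvent for access to the reactive
group.

The concrete system behind the defaults is an electron-rich diaryl amide
guest whose base-mediated hydrolysis is accelerated inside an octahedral
coordination cage: crowding in the cavity stabilizes the reactive *cis*
(twisted) amide conformer relative to the inert *trans* form.  The package
reproduces that reconstruction on analytic model landscapes, so every
statistical claim can be checked against closed-form or brute-force oracles.

## The model

Three probabilistic ingredients are estimated separately and combined:

1. **Conformer thermodynamics.** The amide dihedral ω lives on a periodic
   double well (cis at ω = 0, trans at ω = π) built from a trans→cis
   free-energy difference ΔG and a barrier ΔG‡ (kcal/mol).  Well-tempered
   metadynamics (WT-MetaD) on overdamped Langevin dynamics reconstructs the
   free-energy profile F(ω) from the final bias,
   F(s) = −γ/(γ−1)·V(s, t_final), and basin-integrated populations give
   ΔG and the conformer weights P^conf_ω = exp(−βΔG_ω) (trans ≡ 1).

2. **Encapsulation equilibrium and kinetics.** A radial coordinate with an
   in-cage well, an exit barrier and a flat outer region carries the
   host–guest equilibrium: K_enc = exp(−βΔG_enc), partition probability
   P^in = K_enc/(1+K_enc), and expulsion rate k_off = 1/t_off.  Rare exit
   and attack events are timed with infrequent metadynamics: slow bias
   deposition, stop at first commitment, and the rescaled time
   t\* = Σ dt·exp(βV(s,t)), validated by a Kolmogorov–Smirnov
   exponentiality test and percentile-bootstrap confidence intervals.

3. **Per-conformer reactivity.** Attack/release rates on a two-basin
   reaction profile (reactant R ⇄ tetrahedral intermediate TI) give
   K_reac = k_on/k_off per conformer; normalizing to the most reactive
   conformer yields scores χ_ω (twisted π/4 ≡ 1, cis ≈ 10⁻³,
   trans ≈ 10⁻⁹).

The combination is a global reaction constant per environment,

    K = Σ_ω  χ_ω · P^conf_ω · P^in_ω · NW_ω ,

where NW_ω is the mean solvent-contact count of the amide carbonyl
(P^in ≡ 1 in solution, and ≈ 1 in the cage because binding is strong), and
the headline observable is the **acceleration index**

    a = K(⊂1) / K(sol).

## Worked example

```python
from hostguest import (make_dihedral_potential, RunParams, MetaDParams,
                       run_wtmetad, fes_from_hills,
                       basin_free_energy_difference)

pot = make_dihedral_potential(dG=6.5, barrier=22.3)   # free amide, kcal/mol
traj, hills = run_wtmetad(pot,
                          RunParams(dt=2e-4, n_steps=12_000_000, seed=1),
                          MetaDParams(hill_height0=1.2, hill_sigma=0.35,
                                      deposit_stride=500, bias_factor=15.0))
prof = fes_from_hills(hills, basins=pot.basins)
print(round(basin_free_energy_difference(prof, "trans", "cis"), 2))
```

prints `6.59` (seed-dependent within ±0.15): the engine recovers the
6.5 kcal/mol trans→cis offset it was built from.  The same loop over all
four tabulated systems (`python analysis/02_isomerization_metad.py`) prints

```
system  dG_input  dG_recovered  dG_spread  barrier_input  barrier_recovered
   sol       6.5      6.456594   0.138592           22.3          22.232943
   2⊂1       5.0      4.996025   0.071802           22.0          21.968374
 2_2⊂1       4.0      4.043476   0.161243           25.9          25.818192
 2·3⊂1       2.7      2.687716   0.205410           19.8          19.708201
```

and `python analysis/04_acceleration.py` combines the tabulated
thermodynamics with the synthetic solvent-contact fixtures into

```
2⊂1:   a =     7.01   (16-84% band [4.8, 10.6])
2_2⊂1: a =    29.89   (16-84% band [20.3, 45.4])
2·3⊂1: a =   308.35   (16-84% band [209.1, 468.1])
```

— the acceleration grows monotonically with cavity crowding.  The absolute
magnitudes depend on the solvent-contact factors, which are synthetic
stand-ins (see `docs/methods.md`); the ordering is the robust result.

The numbered scripts under `analysis/` run the full sequence:
`01_fixture_tables.py` (tabulated equilibria → derived constants),
`02_isomerization_metad.py` (WT-MetaD recovery), `03_reaction_kinetics.py`
(infrequent-metadynamics rates, KS validation, detailed balance),
`04_acceleration.py` (the combination).  A `hostguest` CLI exposes the same
stages (`fixtures`, `simulate`, `fes`, `rates`, `accelerate`, `run`,
`report`).

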