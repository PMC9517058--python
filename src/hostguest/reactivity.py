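"""Combination framework: conformer reactivity scores, global reaction
constants and the confinement acceleration index.

The reactivity of a dynamic host-guest system is summarized per environment
(a cage complex or free solution) by a global reaction constant

    K = sum_omega  chi_omega * P_conf_omega * P_in_omega * NW_omega ,

where chi is the per-conformer reactivity score (attack equilibrium
K_reac normalized to the most reactive conformer), P_conf the relative
conformer weight (trans = 1), P_in the probability that the conformer is
actually in the reactive environment (identically 1 in solution) and NW the
mean solvent-contact count of the amide carbonyl.  The acceleration index

    a = K(cage) / K(sol)

compares the confined and free environments; with P_in ~ 1 (the strongly
bound regime) it reduces to the ratio of conformer-weighted solvent-exposed
reactivities.  Monte-Carlo uncertainty propagation over the input factors is
provided to attach spreads to ``a``.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SystemReactivityInput", "AccelerationResult", "UncertaintySpec",
    "chi_scores", "global_reaction_constant", "acceleration_index",
    "acceleration_ratio", "propagate_uncertainty",
    "write_environment", "read_environment",
]

TRUNCATION_THRESHOLD = 1e-12
"""chi * P_conf products below this are reported as negligible terms."""


def chi_scores(k_reac: Mapping[str, float]) -> pd.DataFrame:
    """Normalize per-conformer attack constants to relative scores.

    chi_omega = K_reac(omega) / max_omega K_reac(omega); the most reactive
    conformer scores exactly 1 and ordering is preserved.
    """
    if not k_reac:
        raise ValueError("need at least one conformer")
    vals = np.array(list(k_reac.values()), dtype=float)
    if np.any(vals <= 0):
        raise ValueError("all K_reac must be positive")
    out = pd.DataFrame({"omega": list(k_reac), "k_reac": vals,
                        "chi": vals / vals.max()})
    return out


@dataclasses.dataclass
class SystemReactivityInput:
    """Per-conformer factors for one environment.

    ``table`` columns: omega (label), chi, p_conf, p_in, nw.  For a
    solution environment ``p_in`` is forced to 1 for every conformer.
    """

    name: str
    table: pd.DataFrame
    is_solution: bool = False

    def __post_init__(self):
        required = {"omega", "chi", "p_conf", "p_in", "nw"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        t = self.table.reset_index(drop=True).copy()
        if self.is_solution:
            t["p_in"] = 1.0
        if np.any(t["chi"] <= 0) or np.any(t["p_conf"] <= 0):
            raise ValueError("chi and p_conf must be positive")
        if np.any((t["p_in"] <= 0) | (t["p_in"] > 1)):
            raise ValueError("p_in must lie in (0, 1]")
        if np.any(t["nw"] < 0):
            raise ValueError("NW must be non-negative")
        if "trans" in set(t["omega"]):
            ref = float(t.loc[t["omega"] == "trans", "p_conf"].iloc[0])
            if abs(ref - 1.0) > 1e-9:
                raise ValueError("p_conf must be 1 for the trans reference")
        self.table = t

    def omegas(self) -> list[str]:
        return list(self.table["omega"])

    def with_unit_pin(self) -> "SystemReactivityInput":
        t = self.table.copy()
        t["p_in"] = 1.0
        return SystemReactivityInput(name=self.name, table=t,
                                     is_solution=self.is_solution)


def global_reaction_constant(inp: SystemReactivityInput
                             ) -> tuple[float, pd.DataFrame]:
    """Global reaction constant K and its per-conformer breakdown."""
    t = inp.table.copy()
    t["term"] = t["chi"] * t["p_conf"] * t["p_in"] * t["nw"]
    t["negligible"] = (t["chi"] * t["p_conf"]) < TRUNCATION_THRESHOLD
    return float(t["term"].sum()), t


@dataclasses.dataclass(frozen=True)
class AccelerationResult:
    """Acceleration index with the provenance of every factor."""

    K_cage: float
    K_sol: float
    a: float
    breakdown_cage: pd.DataFrame
    breakdown_sol: pd.DataFrame
    pin_route: str            # 'eq_pin_unity' or 'eq_pin_explicit'
    truncation_report: tuple[str, ...]  # conformers with chi*p_conf ~ 0


def acceleration_ratio(K_cage: float, K_sol: float) -> float:
    if K_sol <= 0:
        raise ValueError("K_sol must be positive")
    return K_cage / K_sol


def acceleration_index(cage: SystemReactivityInput, sol: SystemReactivityInput,
                       pin_route: str = "unity") -> AccelerationResult:
    """Acceleration index a = K(cage) / K(sol).

    ``pin_route='unity'`` applies the strongly-bound simplification
    P_in(cage) = 1; ``'explicit'`` keeps the per-conformer partition
    probabilities.  Solution P_in is identically 1 either way.
    """
    if pin_route not in ("unity", "explicit"):
        raise ValueError("pin_route must be 'unity' or 'explicit'")
    if set(cage.omegas()) != set(sol.omegas()):
        raise ValueError("cage and solution conformer sets differ")
    cage_eff = cage.with_unit_pin() if pin_route == "unity" else cage
    k_cage, bd_cage = global_reaction_constant(cage_eff)
    k_sol, bd_sol = global_reaction_constant(sol if sol.is_solution
                                             else sol.with_unit_pin())
    trunc = tuple(bd_cage.loc[bd_cage["negligible"], "omega"])
    return AccelerationResult(
        K_cage=k_cage, K_sol=k_sol, a=acceleration_ratio(k_cage, k_sol),
        breakdown_cage=bd_cage, breakdown_sol=bd_sol,
        pin_route="eq_pin_unity" if pin_route == "unity" else "eq_pin_explicit",
        truncation_report=trunc)


@dataclasses.dataclass(frozen=True)
class UncertaintySpec:
    """Relative (1-sigma) uncertainties on the input factors.

    chi and p_conf draws are log-normal (they are ratios of Boltzmann
    weights, positive and multiplicative); NW draws are truncated normal.
    chi is a property of the conformer, so its draw is shared between the
    two environments and largely cancels in the ratio.
    """

    rel_chi: float = 0.0
    rel_pconf: float = 0.0
    rel_nw: float = 0.0

    def __post_init__(self):
        if min(self.rel_chi, self.rel_pconf, self.rel_nw) < 0:
            raise ValueError("uncertainties must be non-negative")


def _lognormal_factor(rng, rel, size):
    if rel == 0:
        return np.ones(size)
    return np.exp(rng.standard_normal(size) * rel)


def _truncated_normal_factor(rng, rel, size):
    if rel == 0:
        return np.ones(size)
    f = 1.0 + rng.standard_normal(size) * rel
    while np.any(f <= 0):
        bad = f <= 0
        f[bad] = 1.0 + rng.standard_normal(int(bad.sum())) * rel
    return f


def propagate_uncertainty(cage: SystemReactivityInput,
                          sol: SystemReactivityInput,
                          spec: UncertaintySpec, n_draws: int = 1000,
                          seed: int = 0, pin_route: str = "unity") -> dict:
    """Monte-Carlo distribution of the acceleration index.

    Returns median and 16-84 percentile band of ``a`` over seeded draws of
    every input factor.
    """
    if n_draws < 100:
        raise ValueError("need at least 100 draws")
    rng = np.random.default_rng(seed)
    base = acceleration_index(cage, sol, pin_route=pin_route)
    n_omega = len(cage.omegas())
    order_c = cage.table.set_index("omega")
    order_s = sol.table.set_index("omega")
    omegas = cage.omegas()
    draws = np.empty(n_draws)
    for d in range(n_draws):
        chi_f = _lognormal_factor(rng, spec.rel_chi, n_omega)
        kc = ks = 0.0
        for j, om in enumerate(omegas):
            pc_c = order_c.loc[om, "p_conf"] * (
                1.0 if om == "trans" else _lognormal_factor(rng, spec.rel_pconf, 1)[0])
            pc_s = order_s.loc[om, "p_conf"] * (
                1.0 if om == "trans" else _lognormal_factor(rng, spec.rel_pconf, 1)[0])
            nw_c = order_c.loc[om, "nw"] * _truncated_normal_factor(rng, spec.rel_nw, 1)[0]
            nw_s = order_s.loc[om, "nw"] * _truncated_normal_factor(rng, spec.rel_nw, 1)[0]
            pin_c = 1.0 if pin_route == "unity" else order_c.loc[om, "p_in"]
            chi = order_c.loc[om, "chi"] * chi_f[j]
            kc += chi * pc_c * pin_c * nw_c
            ks += chi * pc_s * 1.0 * nw_s
        draws[d] = kc / ks
    lo, med, hi = np.percentile(draws, [16, 50, 84])
    return {"a": base.a, "median": float(med), "p16": float(lo),
            "p84": float(hi), "draws": draws}


# ---------------------------------------------------------------------------
# environment TSV I/O (CLI exchange format)
# ---------------------------------------------------------------------------

def write_environment(inp: SystemReactivityInput, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# environment = {inp.name}\n")
        fh.write(f"# is_solution = {str(inp.is_solution).lower()}\n")
        inp.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_environment(path) -> SystemReactivityInput:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line.lstrip("# ").partition(" = ")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
        table = pd.read_csv(fh, sep="\t")
    return SystemReactivityInput(name=meta.get("environment", "env"),
                                 table=table,
                                 is_solution=meta.get("is_solution") == "true")
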