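"""Free-energy-surface estimation and equilibrium/partition quantities.

Two FES estimators are provided: the well-tempered relation
F(s) = -gamma/(gamma-1) V(s, t_final) applied to a hills log, and a
(weighted-)histogram estimator -k_B T ln rho(s) applied to samples, with
final-bias reweighting w_i ~ exp(beta V(s_i, t_final)) connecting the two.
Basin thermodynamics follow two conventions kept explicit throughout:

* ``basin`` — Boltzmann-integrated basin populations,
  dG = -k_B T ln(int_B e^{-beta F} / int_A e^{-beta F});
* ``point`` — free-energy values at the basin minima.

The integrated convention is the default (it is the one consistent with the
published dG <-> K_conf pairs at 300 K); the point convention is retained
because figure-level conformer ratios in the source system follow it.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, beta as beta_of, kbt
from .landscapes import _wrap
from .sampler import HillsLog, Trajectory, evaluate_bias

__all__ = [
    "FreeEnergyProfile", "EncapsulationRecord", "UnsampledRegionError",
    "fes_from_hills", "reweight_trajectory", "fes_from_samples",
    "basin_free_energy_difference", "barrier_height",
    "equilibrium_constant", "partition_probability",
    "conformer_probability_profile", "encapsulation_record",
]


class UnsampledRegionError(ValueError):
    """A basin or path contains undefined (never-sampled) bins."""


@dataclasses.dataclass
class FreeEnergyProfile:
    """Gridded F(s), min-shifted to 0; unsampled bins are NaN."""

    grid: np.ndarray
    F: np.ndarray
    temperature: float
    periodic: bool
    basins: Mapping[str, tuple[float, float]] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.grid.shape != self.F.shape:
            raise ValueError("grid and F must have the same shape")
        if len(self.grid) > 1 and not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        finite = np.isfinite(self.F)
        if not finite.any():
            raise ValueError("profile has no defined bins")
        shift = np.nanmin(self.F[finite])
        self.F = self.F - shift

    @property
    def domain(self) -> tuple[float, float]:
        if self.periodic:
            dx = self.grid[1] - self.grid[0]
            return float(self.grid[0]), float(self.grid[-1] + dx)
        return float(self.grid[0]), float(self.grid[-1])

    def basin_points(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Grid points and F inside a basin, ordered along the basin.

        Handles basin intervals that wrap around a periodic domain edge.
        """
        lo, hi = self.basins[name]
        if self.periodic:
            d0, d1 = self.domain
            L = d1 - d0
            center = 0.5 * (lo + hi)
            half = 0.5 * (hi - lo)
            d = _wrap(self.grid - center, L)
            sel = np.abs(d) <= half
            order = np.argsort(d[sel])
            return (center + d[sel][order], self.F[sel][order])
        sel = (self.grid >= lo) & (self.grid <= hi)
        return self.grid[sel], self.F[sel]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# temperature_K = {self.temperature}\n")
            fh.write(f"# periodic = {str(self.periodic).lower()}\n")
            fh.write("# basins = " + json.dumps(
                {k: [float(v[0]), float(v[1])] for k, v in self.basins.items()}) + "\n")
            fh.write("cv\tF_kcal_mol\n")
            for x, f in zip(self.grid, self.F):
                fh.write(f"{x:.10g}\t{f:.10g}\n")

    @classmethod
    def from_tsv(cls, path) -> "FreeEnergyProfile":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    key, _, val = line.lstrip("# ").partition(" = ")
                    meta[key] = val
                elif line and not line.startswith("cv"):
                    a, b = line.split("\t")
                    rows.append((float(a), float(b)))
        arr = np.array(rows)
        return cls(grid=arr[:, 0], F=arr[:, 1],
                   temperature=float(meta.get("temperature_K", DEFAULT_TEMPERATURE)),
                   periodic=meta.get("periodic", "false") == "true",
                   basins={k: tuple(v) for k, v in
                           json.loads(meta.get("basins", "{}")).items()})


def fes_from_hills(hills: HillsLog, grid: np.ndarray | None = None,
                   temperature: float = DEFAULT_TEMPERATURE,
                   basins: Mapping[str, tuple[float, float]] | None = None,
                   n_grid: int = 512) -> FreeEnergyProfile:
    """Well-tempered FES estimate F = -gamma/(gamma-1) V(s, t_final)."""
    if len(hills) == 0:
        raise ValueError("empty hills log")
    gamma = hills.bias_factor
    if gamma <= 1.0:
        raise ValueError("bias factor must exceed 1")
    if grid is None:
        grid = np.linspace(hills.lo, hills.hi, n_grid, endpoint=not hills.periodic)
    V = evaluate_bias(hills, grid)
    F = -(gamma / (gamma - 1.0)) * V
    return FreeEnergyProfile(grid=grid, F=F, temperature=temperature,
                             periodic=hills.periodic, basins=dict(basins or {}))


def reweight_trajectory(traj: Trajectory, hills: HillsLog) -> np.ndarray:
    """Final-bias weights w_i ~ exp(beta V(s_i, t_final)), normalized.

    Standard static reweighting of a well-tempered trajectory onto the
    unbiased ensemble; trajectory and hills must come from the same run.
    """
    if traj.run_id is not None and hills.run_id is not None \
            and traj.run_id != hills.run_id:
        raise ValueError(
            f"trajectory ({traj.run_id}) and hills ({hills.run_id}) "
            "come from different runs")
    V = evaluate_bias(hills, traj.cv_values)
    b = beta_of(traj.params.temperature)
    logw = b * (V - V.max())
    w = np.exp(logw)
    return w / w.sum()


def fes_from_samples(samples: np.ndarray, weights: np.ndarray | None,
                     grid: np.ndarray, temperature: float = DEFAULT_TEMPERATURE,
                     periodic: bool = False,
                     basins: Mapping[str, tuple[float, float]] | None = None
                     ) -> FreeEnergyProfile:
    """Histogram FES: F = -k_B T ln(weighted density) on bin centers ``grid``.

    Empty bins are NaN (undefined), never clipped to a finite cap.
    """
    samples = np.asarray(samples, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if len(samples) < len(grid):
        raise ValueError("need at least as many samples as grid bins")
    dx = grid[1] - grid[0]
    edges = np.concatenate([grid - 0.5 * dx, [grid[-1] + 0.5 * dx]])
    if periodic:
        L = len(grid) * dx
        samples = edges[0] + (samples - edges[0]) % L
    hist, _ = np.histogram(samples, bins=edges, weights=weights)
    if not np.any(hist > 0):
        raise ValueError("all histogram bins are empty")
    F = np.full(hist.shape, np.nan)
    pos = hist > 0
    F[pos] = -kbt(temperature) * np.log(hist[pos])
    return FreeEnergyProfile(grid=grid, F=F, temperature=temperature,
                             periodic=periodic, basins=dict(basins or {}))


def _check_defined(xs: np.ndarray, fs: np.ndarray, label: str) -> None:
    bad = ~np.isfinite(fs)
    if bad.any():
        gaps = ", ".join(f"{x:.4g}" for x in xs[bad][:8])
        raise UnsampledRegionError(
            f"{label} contains {int(bad.sum())} undefined bins (at CV ~ {gaps})")


def basin_free_energy_difference(profile: FreeEnergyProfile, basin_a: str,
                                 basin_b: str, convention: str = "basin") -> float:
    """dG(A->B) in kcal/mol under the basin or point convention."""
    if convention not in ("basin", "point"):
        raise ValueError("convention must be 'basin' or 'point'")
    xa, fa = profile.basin_points(basin_a)
    xb, fb = profile.basin_points(basin_b)
    _check_defined(xa, fa, f"basin {basin_a!r}")
    _check_defined(xb, fb, f"basin {basin_b!r}")
    if convention == "point":
        return float(np.min(fb) - np.min(fa))
    b = beta_of(profile.temperature)
    za = np.trapezoid(np.exp(-b * fa), xa)
    zb = np.trapezoid(np.exp(-b * fb), xb)
    return float(-kbt(profile.temperature) * np.log(zb / za))


def barrier_height(profile: FreeEnergyProfile, source_basin: str,
                   target_basin: str) -> float:
    """Barrier: max F along the lower connecting path minus F(source min)."""
    xs, fs = profile.basin_points(source_basin)
    xt, ft = profile.basin_points(target_basin)
    _check_defined(xs, fs, f"basin {source_basin!r}")
    _check_defined(xt, ft, f"basin {target_basin!r}")
    n = len(profile.grid)
    i_src = int(np.argmin(np.abs(profile.grid - xs[np.argmin(fs)])))
    i_tgt = int(np.argmin(np.abs(profile.grid - xt[np.argmin(ft)])))
    f_src = profile.F[i_src]
    lo, hi = sorted((i_src, i_tgt))
    paths = [profile.F[lo:hi + 1]]
    if profile.periodic:
        paths.append(np.concatenate([profile.F[hi:], profile.F[:lo + 1]]))
    maxima = []
    for p in paths:
        if np.all(np.isfinite(p)):
            maxima.append(float(np.max(p)))
    if not maxima:
        raise UnsampledRegionError(
            "every path between the basins crosses undefined bins")
    return float(min(maxima) - f_src)


def equilibrium_constant(dG: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """K = exp(-dG / k_B T) for a free-energy difference in kcal/mol."""
    if not np.isfinite(dG):
        raise ValueError("dG must be finite")
    return float(np.exp(-dG * beta_of(temperature)))


def partition_probability(k_enc: float) -> float:
    """In-cage partition probability P_in = K_enc / (1 + K_enc)."""
    if k_enc < 0:
        raise ValueError("K_enc must be non-negative")
    return k_enc / (1.0 + k_enc)


def conformer_probability_profile(profile: FreeEnergyProfile,
                                  reference: float = np.pi,
                                  convention: str = "point",
                                  omegas: Mapping[str, float] | None = None
                                  ) -> pd.DataFrame:
    """Relative conformer probabilities P_conf(omega) vs the reference.

    ``point`` convention: P = exp(-beta (F(omega) - F(ref))) evaluated on
    grid points (per named omega if ``omegas`` is given, else the full
    grid).  ``basin`` convention: one row per declared basin using
    Boltzmann-integrated populations; the reference is the basin containing
    the reference coordinate.  The convention is recorded in ``attrs``.
    """
    if convention not in ("basin", "point"):
        raise ValueError("convention must be 'basin' or 'point'")
    b = beta_of(profile.temperature)
    if convention == "point":
        def f_at(x):
            i = int(np.argmin(np.abs(profile.grid - x)))
            f = profile.F[i]
            if not np.isfinite(f):
                raise UnsampledRegionError(f"F undefined at reference/omega {x:.4g}")
            return f
        f_ref = f_at(reference)
        if omegas is None:
            items = [(f"{x:.4g}", x) for x in profile.grid]
        else:
            items = list(omegas.items())
        rows = [{"omega_label": lab, "omega": x,
                 "dG_vs_ref": f_at(x) - f_ref,
                 "p_conf": float(np.exp(-b * (f_at(x) - f_ref)))}
                for lab, x in items]
    else:
        ref_name = None
        for name in profile.basins:
            xs, _ = profile.basin_points(name)
            if xs.min() - 1e-9 <= reference <= xs.max() + 1e-9:
                ref_name = name
        if ref_name is None:
            raise ValueError("reference coordinate lies in no declared basin")
        rows = []
        for name in profile.basins:
            dg = basin_free_energy_difference(profile, ref_name, name, "basin")
            xs, fs = profile.basin_points(name)
            rows.append({"omega_label": name, "omega": float(xs[np.argmin(fs)]),
                         "dG_vs_ref": dg, "p_conf": float(np.exp(-b * dg))})
    out = pd.DataFrame(rows)
    out.attrs["convention"] = convention
    out.attrs["temperature"] = profile.temperature
    return out


@dataclasses.dataclass(frozen=True)
class EncapsulationRecord:
    """Derived encapsulation equilibrium/kinetics for one complex."""

    dG_enc: float        # kcal/mol
    K_enc: float         # dimensionless, exp(-beta dG)
    P_in: float          # K/(1+K)
    t_off: float         # s
    k_off: float         # 1/s, = 1/t_off
    k_on: float          # 1/s, = K_enc * k_off
    temperature: float

    def __post_init__(self):
        if not 0.0 < self.P_in < 1.0:
            raise ValueError("P_in must lie strictly between 0 and 1")


def encapsulation_record(dG_enc: float, t_off: float,
                         temperature: float = DEFAULT_TEMPERATURE
                         ) -> EncapsulationRecord:
    """Build the derived encapsulation record from dG and residence time."""
    if t_off <= 0:
        raise ValueError("t_off must be positive")
    K = equilibrium_constant(dG_enc, temperature)
    k_off = 1.0 / t_off
    return EncapsulationRecord(dG_enc=dG_enc, K_enc=K,
                               P_in=partition_probability(K), t_off=t_off,
                               k_off=k_off, k_on=K * k_off,
                               temperature=temperature)
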