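"""Overdamped-Langevin dynamics with well-tempered / infrequent metadynamics.

The sampler propagates a single collective variable s on an analytic
``PotentialSpec`` with the Euler-Maruyama update

    ds = -beta D (F'(s) + V'(s,t)) dt + sqrt(2 D dt) xi,

where V is the history-dependent Gaussian bias.  Well-tempered deposition
scales hill heights by exp(-V/(k_B dT)) with dT = (gamma - 1) T; infrequent
runs deposit slowly, stop at the first commitment to a target basin and
accumulate the rescaled transition time t* = sum dt exp(beta V(s,t)).

Bias histories are exchanged as plain-text HILLS/COLVAR files in the PLUMED
dialect (``#! FIELDS ...`` header, whitespace-separated numeric rows).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np

from . import _core
from .constants import KB_KCAL_MOL_K, DEFAULT_TEMPERATURE, beta as beta_of
from .landscapes import PotentialSpec, _wrap

__all__ = [
    "RunParams", "MetaDParams", "HillsLog", "Trajectory", "TransitionEvent",
    "StepSizeError", "HillsParseError",
    "run_langevin", "run_wtmetad", "run_infrequent_ensemble",
    "evaluate_bias", "write_hills", "read_hills", "write_colvar", "read_colvar",
]


class StepSizeError(RuntimeError):
    """A single step moved the CV by more than half the domain."""


class HillsParseError(ValueError):
    """Malformed HILLS/COLVAR file; carries the offending line number."""


@dataclasses.dataclass(frozen=True)
class RunParams:
    """Langevin integration parameters (reduced units)."""

    dt: float = 2e-4
    diffusion: float = 1.0
    temperature: float = DEFAULT_TEMPERATURE
    n_steps: int = 1_000_000
    seed: int = 0
    boundary: str | None = None  # {periodic, reflecting} or None = infer
    save_stride: int = 100
    n_grid: int = 512

    def __post_init__(self):
        if self.dt <= 0 or self.diffusion <= 0:
            raise ValueError("dt and diffusion must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.boundary not in (None, "periodic", "reflecting"):
            raise ValueError("boundary must be 'periodic' or 'reflecting'")


@dataclasses.dataclass(frozen=True)
class MetaDParams:
    """Well-tempered metadynamics parameters."""

    hill_height0: float = 1.2     # kcal/mol
    hill_sigma: float = 0.35      # CV units
    deposit_stride: int = 500     # steps
    bias_factor: float = 15.0     # gamma > 1

    def __post_init__(self):
        if min(self.hill_height0, self.hill_sigma) <= 0 or self.deposit_stride < 1:
            raise ValueError("metadynamics parameters must be positive")
        if self.bias_factor <= 1.0:
            raise ValueError("bias factor must exceed 1")


@dataclasses.dataclass
class HillsLog:
    """Deposited Gaussian bias history (post-tempering heights)."""

    times: np.ndarray
    centers: np.ndarray
    sigmas: np.ndarray
    heights: np.ndarray
    bias_factor: float
    lo: float
    hi: float
    periodic: bool
    cv_name: str = "cv"
    run_id: str | None = None

    def __post_init__(self):
        n = len(self.times)
        if not (len(self.centers) == len(self.sigmas) == len(self.heights) == n):
            raise ValueError("hills columns must have equal length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("hill times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def __eq__(self, other) -> bool:
        if not isinstance(other, HillsLog):
            return NotImplemented
        return (np.array_equal(self.times, other.times)
                and np.array_equal(self.centers, other.centers)
                and np.array_equal(self.sigmas, other.sigmas)
                and np.array_equal(self.heights, other.heights)
                and self.bias_factor == other.bias_factor)


@dataclasses.dataclass
class Trajectory:
    """Saved CV samples with the instantaneous bias at each visit."""

    times: np.ndarray
    cv_values: np.ndarray
    bias_at_point: np.ndarray
    seed: int
    params: RunParams
    run_id: str | None = None

    def __len__(self) -> int:
        return len(self.times)


@dataclasses.dataclass(frozen=True)
class TransitionEvent:
    """One first-passage event from an infrequent-metadynamics replica."""

    physical_steps: int
    physical_time: float
    rescaled_time: float
    source_basin: str
    target_basin: str
    seed: int
    censored: bool = False


def _resolve_boundary(potential: PotentialSpec, params: RunParams) -> bool:
    periodic = potential.periodic
    if params.boundary == "periodic" and not periodic:
        raise ValueError("periodic boundary requested on a bounded landscape")
    if params.boundary == "reflecting" and periodic:
        raise ValueError("reflecting boundary requested on a periodic landscape")
    return periodic


def _force_table(potential: PotentialSpec, n_grid: int) -> np.ndarray:
    return np.asarray(potential.force(potential.grid(n_grid)), dtype=float)


def _default_start(potential: PotentialSpec) -> float:
    g = potential.grid(2048)
    return float(g[int(np.argmin(potential.energy(g)))])


def _run(potential, params, metad=None, s0=None, stop_interval=None,
         track_alpha=False):
    periodic = _resolve_boundary(potential, params)
    n_grid = params.n_grid
    pot_force = _force_table(potential, n_grid)
    bias = np.zeros(n_grid)
    bias_force = np.zeros(n_grid)
    if metad is not None:
        cap_hills = params.n_steps // metad.deposit_stride + 2
        h0, sig, stride = metad.hill_height0, metad.hill_sigma, metad.deposit_stride
        kbdT = KB_KCAL_MOL_K * (metad.bias_factor - 1.0) * params.temperature
        metad_on = 1
    else:
        cap_hills, h0, sig, stride, kbdT, metad_on = 1, 1.0, 1.0, 1, 0.0, 0
    hills_t = np.empty(cap_hills)
    hills_c = np.empty(cap_hills)
    hills_h = np.empty(cap_hills)
    save_stride = params.save_stride
    cap_traj = params.n_steps // max(save_stride, 1) + 2 if save_stride > 0 else 1
    traj_t = np.empty(cap_traj)
    traj_s = np.empty(cap_traj)
    traj_v = np.empty(cap_traj)
    if stop_interval is not None:
        stop_on, t_lo, t_hi = 1, float(stop_interval[0]), float(stop_interval[1])
    else:
        stop_on, t_lo, t_hi = 0, 0.0, 0.0
    if s0 is None:
        s0 = _default_start(potential)
    status, steps_done, n_saved, n_hills, s_final, alpha, exited = _core.run_core(
        pot_force, potential.lo, potential.hi, 1 if periodic else 0,
        params.dt, beta_of(params.temperature), params.diffusion,
        params.n_steps, int(params.seed) % (2 ** 31), float(s0),
        metad_on, h0, sig, stride, kbdT,
        bias, bias_force, hills_t, hills_c, hills_h,
        stop_on, t_lo, t_hi, 1 if track_alpha else 0,
        save_stride, traj_t, traj_s, traj_v)
    if status == _core.STATUS_STEP_DIVERGED:
        raise StepSizeError(
            f"step size diverged at step {steps_done}; reduce dt "
            f"(dt={params.dt}, D={params.diffusion})")
    return dict(steps_done=steps_done, s_final=s_final, alpha=alpha, exited=exited,
                traj=(traj_t[:n_saved], traj_s[:n_saved], traj_v[:n_saved]),
                hills=(hills_t[:n_hills], hills_c[:n_hills], hills_h[:n_hills]),
                bias_grid=bias)


def run_langevin(potential: PotentialSpec, params: RunParams,
                 s0: float | None = None) -> Trajectory:
    """Unbiased overdamped-Langevin trajectory on the landscape."""
    out = _run(potential, params, s0=s0)
    tt, ss, vv = out["traj"]
    return Trajectory(times=tt, cv_values=ss, bias_at_point=vv,
                      seed=params.seed, params=params,
                      run_id=f"lgv-{params.seed}-{params.n_steps}")


def run_wtmetad(potential: PotentialSpec, params: RunParams,
                metad: MetaDParams, s0: float | None = None
                ) -> tuple[Trajectory, HillsLog]:
    """Well-tempered metadynamics run; returns trajectory and hills log."""
    out = _run(potential, params, metad=metad, s0=s0)
    run_id = f"wtm-{params.seed}-{params.n_steps}-{metad.deposit_stride}"
    tt, ss, vv = out["traj"]
    ht, hc, hh = out["hills"]
    traj = Trajectory(times=tt, cv_values=ss, bias_at_point=vv,
                      seed=params.seed, params=params, run_id=run_id)
    hills = HillsLog(times=ht, centers=hc, sigmas=np.full(len(ht), metad.hill_sigma),
                     heights=hh, bias_factor=metad.bias_factor,
                     lo=potential.lo, hi=potential.hi, periodic=potential.periodic,
                     run_id=run_id)
    return traj, hills


def _target_window(potential: PotentialSpec, target_basin: str,
                   margin: float) -> tuple[float, float]:
    lo, hi = potential.basins[target_basin]
    lo, hi = lo + margin, hi - margin
    if hi <= lo:
        raise ValueError("commitment margin swallows the target basin")
    if potential.periodic:
        L = potential.length
        lo = potential.lo + (lo - potential.lo) % L
        hi = potential.lo + (hi - potential.lo) % L
    return lo, hi


def run_infrequent_ensemble(potential: PotentialSpec, params: RunParams,
                            metad: MetaDParams | None, source_basin: str,
                            target_basin: str, n_replicas: int,
                            commit_margin: float = 0.1,
                            stride_floor: int = 100) -> list[TransitionEvent]:
    """Replica ensemble of infrequent-metadynamics first-passage events.

    Each replica starts at the source-basin minimum, deposits bias slowly
    (``deposit_stride`` must respect ``stride_floor`` so the basin relaxes
    between hills) and stops at the first entry into the target basin past
    its edges by ``commit_margin``.  Replicas that exhaust ``n_steps`` are
    returned flagged as censored.  ``metad=None`` runs plain unbiased
    first-passage sampling (the brute-force reference), in which case the
    rescaled time equals the physical time.
    """
    if source_basin == target_basin:
        raise ValueError("source and target basins must differ")
    if metad is not None and metad.deposit_stride < stride_floor:
        raise ValueError(
            f"deposit_stride {metad.deposit_stride} below the infrequent floor "
            f"{stride_floor}; deposition would outrun basin relaxation")
    window = _target_window(potential, target_basin, commit_margin)
    s0, _ = potential.basin_minimum(source_basin)
    seeds = np.random.SeedSequence(params.seed).generate_state(n_replicas) % (2 ** 31)
    events = []
    for rep_seed in seeds:
        p = dataclasses.replace(params, seed=int(rep_seed), save_stride=0)
        out = _run(potential, p, metad=metad, s0=s0, stop_interval=window,
                   track_alpha=True)
        censored = not bool(out["exited"])
        events.append(TransitionEvent(
            physical_steps=int(out["steps_done"]),
            physical_time=out["steps_done"] * params.dt,
            rescaled_time=float(out["alpha"]),
            source_basin=source_basin, target_basin=target_basin,
            seed=int(rep_seed), censored=censored))
    return events


def evaluate_bias(hills: HillsLog, s, t: float | None = None):
    """Total deposited bias V(s, t) from a hills log (kcal/mol).

    Includes all hills with deposit time <= ``t`` (all hills if ``t`` is
    None); periodic CVs include the wrapped images of every hill.
    """
    arr = np.atleast_1d(np.asarray(s, dtype=float)).ravel()
    v = np.zeros(arr.shape)
    if len(hills) > 0:
        sel = slice(None) if t is None else hills.times <= t
        c = hills.centers[sel]
        h = hills.heights[sel]
        sig = hills.sigmas[sel]
        # chunked to keep the (points x hills) intermediate small
        chunk = max(1, 2_000_000 // max(len(c), 1))
        for i in range(0, len(arr), chunk):
            d = arr[i:i + chunk, None] - c[None, :]
            if hills.periodic:
                L = hills.hi - hills.lo
                d = _wrap(d, L)
                acc = np.zeros(d.shape[0])
                for k in (-1.0, 0.0, 1.0):
                    acc += np.sum(h * np.exp(-0.5 * ((d + k * L) / sig) ** 2),
                                  axis=1)
                v[i:i + chunk] = acc
            else:
                v[i:i + chunk] = np.sum(h * np.exp(-0.5 * (d / sig) ** 2),
                                        axis=1)
    return v.reshape(np.shape(s)) if np.ndim(s) else float(v[0])


# ---------------------------------------------------------------------------
# PLUMED-dialect file I/O
# ---------------------------------------------------------------------------

_FMT = "%.17g"


def write_hills(hills: HillsLog, path) -> None:
    """Write a hills log in the PLUMED HILLS dialect."""
    cv = hills.cv_name
    with open(path, "w") as fh:
        fh.write(f"#! FIELDS time {cv} sigma_{cv} height biasf\n")
        for t, c, s, h in zip(hills.times, hills.centers, hills.sigmas, hills.heights):
            fh.write(" ".join(_FMT % v for v in (t, c, s, h, hills.bias_factor)) + "\n")


def read_hills(path, lo: float = -np.pi, hi: float = np.pi,
               periodic: bool = True) -> HillsLog:
    """Parse a PLUMED-dialect HILLS file.

    The file itself does not carry the CV domain, so the caller supplies
    ``lo``/``hi``/``periodic`` (defaults suit the dihedral CV).
    """
    times, centers, sigmas, heights, biasf = [], [], [], [], []
    cv_name = "cv"
    header_seen = False
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#!") and not header_seen:
                    tok = line.split()
                    if (len(tok) != 7 or tok[1] != "FIELDS" or tok[2] != "time"
                            or tok[4] != f"sigma_{tok[3]}" or tok[5] != "height"
                            or tok[6] != "biasf"):
                        raise HillsParseError(f"line {ln}: malformed FIELDS header")
                    cv_name = tok[3]
                    header_seen = True
                continue
            if not header_seen:
                raise HillsParseError(f"line {ln}: data before FIELDS header")
            tok = line.split()
            if len(tok) != 5:
                raise HillsParseError(f"line {ln}: expected 5 columns, got {len(tok)}")
            try:
                vals = [float(v) for v in tok]
            except ValueError as exc:
                raise HillsParseError(f"line {ln}: non-numeric value") from exc
            times.append(vals[0]); centers.append(vals[1]); sigmas.append(vals[2])
            heights.append(vals[3]); biasf.append(vals[4])
    if not header_seen:
        raise HillsParseError("no FIELDS header found")
    return HillsLog(times=np.array(times), centers=np.array(centers),
                    sigmas=np.array(sigmas), heights=np.array(heights),
                    bias_factor=biasf[0] if biasf else 1.0,
                    lo=lo, hi=hi, periodic=periodic, cv_name=cv_name)


def write_colvar(traj: Trajectory, path, cv_name: str = "cv") -> None:
    with open(path, "w") as fh:
        fh.write(f"#! FIELDS time {cv_name} bias\n")
        for t, s, v in zip(traj.times, traj.cv_values, traj.bias_at_point):
            fh.write(" ".join(_FMT % x for x in (t, s, v)) + "\n")


def read_colvar(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a COLVAR file; returns (times, cv, bias) arrays."""
    times, cvs, biases = [], [], []
    header_seen = False
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#!") and not header_seen:
                    tok = line.split()
                    if len(tok) != 5 or tok[1] != "FIELDS" or tok[2] != "time":
                        raise HillsParseError(f"line {ln}: malformed FIELDS header")
                    header_seen = True
                continue
            if not header_seen:
                raise HillsParseError(f"line {ln}: data before FIELDS header")
            tok = line.split()
            if len(tok) != 3:
                raise HillsParseError(f"line {ln}: expected 3 columns, got {len(tok)}")
            times.append(float(tok[0])); cvs.append(float(tok[1]))
            biases.append(float(tok[2]))
    if not header_seen:
        raise HillsParseError("no FIELDS header found")
    return np.array(times), np.array(cvs), np.array(biases)


def run_manifest(params: RunParams, metad: MetaDParams | None = None) -> str:
    """JSON manifest of a run's parameters (for provenance files)."""
    d = {"params": dataclasses.asdict(params)}
    if metad is not None:
        d["metad"] = dataclasses.asdict(metad)
    return json.dumps(d, indent=2, sort_keys=True)
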