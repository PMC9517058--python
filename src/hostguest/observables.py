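"""Structural observables on bead-model trajectories.

Coordination-style contacts through the rational switching function,
cage-center distances, Shrake-Rupley solvent-accessible surface area on a
deterministic golden-spiral point shell, and 2-D histogram free-energy
surfaces.  Bead systems are finite and non-periodic, so no minimum-image
handling is applied anywhere.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, kbt
from .landscapes import BeadSystem, _golden_spiral

__all__ = [
    "ObservableSeries", "switching_function", "switching_contacts",
    "center_distance", "shrake_rupley_sasa", "histogram_fes2d",
    "contacts_series", "center_distance_series", "sasa_series",
    "write_series", "read_series", "write_xyz", "read_xyz",
]


@dataclasses.dataclass(frozen=True)
class ObservableSeries:
    """A per-frame observable with name and units."""

    times: np.ndarray
    values: np.ndarray
    name: str
    units: str

    def __post_init__(self):
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("observable values must be finite")

    def __len__(self) -> int:
        return len(self.values)


def switching_function(r, r0: float, n: int = 6, m: int = 12):
    """Rational switching s(r) = (1 - (r/r0)^n) / (1 - (r/r0)^m).

    The removable singularity at r = r0 evaluates to n/m.
    """
    if not 0 < n < m:
        raise ValueError("need 0 < n < m")
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    x = np.asarray(r, dtype=float) / r0
    xn = x ** n
    xm = x ** m
    denom_ok = np.abs(1.0 - xm) > 1e-12
    out = np.where(denom_ok, (1.0 - xn) / np.where(denom_ok, 1.0 - xm, 1.0),
                   float(n) / float(m))
    return out if np.ndim(r) else float(out)


def switching_contacts(coords_a: np.ndarray, coords_b: np.ndarray,
                       r0: float, n: int = 6, m: int = 12) -> float:
    """Total switched contact count between two bead groups."""
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("bead groups must be non-empty")
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(np.sum(switching_function(d, r0, n, m)))


def center_distance(cage_coords: np.ndarray, guest_coords: np.ndarray) -> float:
    """Distance between unweighted geometric centers of two selections."""
    cage = np.atleast_2d(np.asarray(cage_coords, dtype=float))
    guest = np.atleast_2d(np.asarray(guest_coords, dtype=float))
    if cage.size == 0 or guest.size == 0:
        raise ValueError("selections must be non-empty")
    return float(np.linalg.norm(cage.mean(axis=0) - guest.mean(axis=0)))


def shrake_rupley_sasa(centers: np.ndarray, radii: np.ndarray,
                       probe_radius: float = 0.0, n_points: int = 960) -> float:
    """Shrake-Rupley solvent-accessible surface area.

    Each sphere carries a golden-spiral shell of ``n_points`` test points at
    radius r + probe; points strictly inside any other inflated sphere are
    occluded, and the exposed fraction scales 4*pi*(r+probe)^2.  Exact
    duplicate spheres are collapsed before counting so overlapping copies do
    not double the area.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if centers.shape[0] == 0:
        return 0.0
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    if n_points < 32:
        raise ValueError("need at least 32 shell points")
    # collapse exact duplicates (identical center and radius)
    keep = []
    for i in range(len(centers)):
        dup = False
        for j in keep:
            if radii[i] == radii[j] and np.allclose(centers[i], centers[j],
                                                    rtol=0.0, atol=1e-12):
                dup = True
                break
        if not dup:
            keep.append(i)
    centers = centers[keep]
    radii = radii[keep]
    shell = _golden_spiral(n_points)
    inflated = radii + probe_radius
    area = 0.0
    for i in range(len(centers)):
        pts = centers[i] + inflated[i] * shell
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(centers)):
            if j == i:
                continue
            d = np.linalg.norm(pts - centers[j], axis=1)
            exposed &= d >= inflated[j] - 1e-12
        area += exposed.mean() * 4.0 * np.pi * inflated[i] ** 2
    return float(area)


def histogram_fes2d(x: np.ndarray, y: np.ndarray, bins: int = 40,
                    temperature: float = DEFAULT_TEMPERATURE
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D histogram FES: F = -k_B T ln(density), min-shifted, NaN when empty.

    Returns (F, x_edges, y_edges).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    if np.ndim(bins) == 0 and bins < 2:
        raise ValueError("need at least 2 bins per axis")
    hist, xe, ye = np.histogram2d(x, y, bins=bins)
    if not np.any(hist > 0):
        raise ValueError("all histogram bins are empty")
    F = np.full(hist.shape, np.nan)
    pos = hist > 0
    F[pos] = -kbt(temperature) * np.log(hist[pos])
    F = F - np.nanmin(F)
    return F, xe, ye


# ---------------------------------------------------------------------------
# per-frame series on BeadSystems
# ---------------------------------------------------------------------------

def contacts_series(system: BeadSystem, r0: float, n: int = 6,
                    m: int = 12) -> ObservableSeries:
    vals = np.array([switching_contacts(system.cage_coords,
                                        system.guest_frames[k], r0, n, m)
                     for k in range(system.n_frames)])
    return ObservableSeries(times=system.times, values=vals,
                            name="cage_guest_contacts", units="count")


def center_distance_series(system: BeadSystem) -> ObservableSeries:
    vals = np.array([center_distance(system.cage_coords, system.guest_frames[k])
                     for k in range(system.n_frames)])
    return ObservableSeries(times=system.times, values=vals,
                            name="center_distance", units="length")


def sasa_series(system: BeadSystem, probe_radius: float = 0.0,
                n_points: int = 240) -> ObservableSeries:
    """Guest SASA per frame with cage beads as occluders."""
    vals = np.empty(system.n_frames)
    for k in range(system.n_frames):
        centers = np.vstack([system.guest_frames[k], system.cage_coords])
        radii = np.concatenate([system.guest_radii, system.cage_radii])
        total = shrake_rupley_sasa(centers, radii, probe_radius, n_points)
        cage_only = shrake_rupley_sasa(system.cage_coords, system.cage_radii,
                                       probe_radius, n_points)
        vals[k] = total - cage_only
    return ObservableSeries(times=system.times, values=vals, name="guest_sasa",
                            units="length^2")


def write_series(series: ObservableSeries, path) -> None:
    df = pd.DataFrame({"time": series.times, series.name: series.values})
    with open(path, "w") as fh:
        fh.write(f"# observable = {series.name} [{series.units}]\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_series(path) -> ObservableSeries:
    with open(path) as fh:
        meta = fh.readline().strip()
        df = pd.read_csv(fh, sep="\t")
    name = df.columns[1]
    units = meta.split("[")[-1].rstrip("]") if "[" in meta else ""
    return ObservableSeries(times=df["time"].to_numpy(),
                            values=df[name].to_numpy(), name=name, units=units)


def write_xyz(system: BeadSystem, path) -> None:
    """Write cage+guest frames as an XYZ-format text trajectory."""
    n_cage = len(system.cage_coords)
    n_guest = system.guest_frames.shape[1]
    with open(path, "w") as fh:
        for k in range(system.n_frames):
            fh.write(f"{n_cage + n_guest}\n")
            fh.write(f"frame {k} time {system.times[k]:.10g}\n")
            for xyz in system.cage_coords:
                fh.write("C %.10g %.10g %.10g\n" % tuple(xyz))
            for xyz in system.guest_frames[k]:
                fh.write("G %.10g %.10g %.10g\n" % tuple(xyz))


def read_xyz(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an XYZ trajectory written by :func:`write_xyz`.

    Returns (cage_coords, guest_frames); bead roles come from the C/G
    element labels.
    """
    cage_frames, guest_frames = [], []
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head.strip():
                break
            n = int(head)
            fh.readline()  # comment
            cage, guest = [], []
            for _ in range(n):
                tok = fh.readline().split()
                (cage if tok[0] == "C" else guest).append(
                    [float(v) for v in tok[1:4]])
            cage_frames.append(cage)
            guest_frames.append(guest)
    return np.array(cage_frames[0]), np.array(guest_frames)
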