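"""Geometries (reflective box / capped slab / open medium) and scorers.

Specular reflection off an axis-aligned face is implemented by *folding*:
the straight unfolded trajectory is mapped into the region with period-2L
mirror folding per reflective axis, which handles any number of reflections
in one step exactly and preserves energy and tangential momentum.

Scorers: secondary-electron birth spectrum, projected range, cylindrical
radial dose, and the sphere-lattice lineal-energy tally (single-event
microdosimetric convention: one y value per history per sphere with a
nonzero deposit, y = energy / mean chord, mean chord = (2/3) * diameter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .proton_transport import ParticleState

__all__ = [
    "UnboundedGeometry",
    "ReflectiveBox",
    "ReflectiveSlabZ",
    "reflect",
    "SphereLattice",
    "LinealEnergyResult",
    "lineal_energy_finalize",
    "RadialDoseTally",
    "RangeTally",
    "SpectrumTally",
    "mean_chord_mc",
    "MEAN_CHORD_FACTOR",
]

#: mean chord length of a sphere of diameter d is MEAN_CHORD_FACTOR * d
MEAN_CHORD_FACTOR = 2.0 / 3.0


def _fold(u: np.ndarray, length: float) -> tuple[np.ndarray, np.ndarray]:
    """Map unfolded coordinates into [0, L] with mirror folding.

    Returns (folded coordinate, direction sign in {+1, -1})."""
    m = np.mod(u, 2.0 * length)
    over = m > length
    x = np.where(over, 2.0 * length - m, m)
    sign = np.where(over, -1.0, 1.0)
    return x, sign


class UnboundedGeometry:
    """Infinite homogeneous medium."""

    def advance(self, pos, dirs, s):
        return pos + dirs * np.asarray(s)[:, None], dirs

    def path_points(self, pos0, dir0, s_arr):
        return pos0[None, :] + np.outer(np.asarray(s_arr), dir0)

    def path_with_dirs(self, pos0, dir0, s_arr):
        pts = self.path_points(pos0, dir0, s_arr)
        return pts, np.broadcast_to(dir0, pts.shape).copy()

    def contains(self, pos) -> np.ndarray:
        return np.ones(np.atleast_2d(pos).shape[0], dtype=bool)


class ReflectiveBox:
    """Axis-aligned box [0, Lx] x [0, Ly] x [0, Lz], all faces reflective."""

    def __init__(self, sides):
        self.sides = np.array(sides if np.ndim(sides) else [sides] * 3,
                              dtype=float)
        if np.any(self.sides <= 0):
            raise ValueError("box sides must be positive")

    def advance(self, pos, dirs, s):
        u = pos + dirs * np.asarray(s)[:, None]
        out = np.empty_like(u)
        sign = np.empty_like(u)
        for ax in range(3):
            out[:, ax], sign[:, ax] = _fold(u[:, ax], self.sides[ax])
        return out, dirs * sign

    def path_points(self, pos0, dir0, s_arr):
        return self.path_with_dirs(pos0, dir0, s_arr)[0]

    def path_with_dirs(self, pos0, dir0, s_arr):
        """Folded positions and directions along one straight unfolded path."""
        u = pos0[None, :] + np.outer(np.asarray(s_arr), dir0)
        out = np.empty_like(u)
        dirs = np.empty_like(u)
        for ax in range(3):
            out[:, ax], sign = _fold(u[:, ax], self.sides[ax])
            dirs[:, ax] = dir0[ax] * sign
        return out, dirs

    def contains(self, pos) -> np.ndarray:
        p = np.atleast_2d(pos)
        return np.all((p >= 0) & (p <= self.sides), axis=1)


class ReflectiveSlabZ:
    """Infinite in x, y; reflective caps at z = 0 and z = thickness."""

    def __init__(self, thickness: float):
        if thickness <= 0:
            raise ValueError("thickness must be positive")
        self.thickness = float(thickness)

    def advance(self, pos, dirs, s):
        u = pos + dirs * np.asarray(s)[:, None]
        z, sign = _fold(u[:, 2], self.thickness)
        out = u.copy()
        out[:, 2] = z
        d = dirs.copy()
        d[:, 2] = dirs[:, 2] * sign
        return out, d

    def path_points(self, pos0, dir0, s_arr):
        return self.path_with_dirs(pos0, dir0, s_arr)[0]

    def path_with_dirs(self, pos0, dir0, s_arr):
        u = pos0[None, :] + np.outer(np.asarray(s_arr), dir0)
        dirs = np.broadcast_to(dir0, u.shape).copy()
        u[:, 2], sign = _fold(u[:, 2], self.thickness)
        dirs[:, 2] = dir0[2] * sign
        return u, dirs

    def contains(self, pos) -> np.ndarray:
        p = np.atleast_2d(pos)
        return (p[:, 2] >= 0) & (p[:, 2] <= self.thickness)


def reflect(state: ParticleState, face: tuple[int, float]) -> ParticleState:
    """Specular reflection of a particle sitting on a reflective face.

    ``face`` is (axis, plane coordinate); the particle must be on the plane
    and moving out of it.  Energy, position and tangential direction are
    unchanged; the normal direction component is negated.
    """
    ax, coord = face
    if abs(state.position[ax] - coord) > 1e-9:
        raise ValueError("particle is not on the given face")
    state.direction = state.direction.copy()
    state.direction[ax] = -state.direction[ax]
    return state


# --------------------------------------------------------------------------
# sphere-lattice lineal-energy scoring
# --------------------------------------------------------------------------

class SphereLattice:
    """Simple-cubic lattice of touching spheres filling a cube.

    ``diameter`` [nm] spheres, ``n_side`` per edge (cube side = n_side *
    diameter).  Deposits falling between spheres count toward the energy
    balance but toward no sphere.  One energy sum is accumulated per
    (history, sphere) with a nonzero deposit.
    """

    def __init__(self, diameter: float, n_side: int = 179):
        if diameter <= 0 or n_side < 1:
            raise ValueError("invalid lattice parameters")
        self.diameter = float(diameter)
        self.n_side = int(n_side)
        self.side = self.diameter * self.n_side
        self._events: list[np.ndarray] = []
        self.scored_energy = 0.0
        self.unscored_energy = 0.0

    def sphere_index(self, positions) -> np.ndarray:
        """Flat sphere index per point, or -1 for interstitial points."""
        p = np.atleast_2d(np.asarray(positions, dtype=float))
        cell = np.clip((p // self.diameter).astype(np.int64), 0, self.n_side - 1)
        centre = (cell + 0.5) * self.diameter
        inside = np.sum((p - centre) ** 2, axis=1) <= (self.diameter / 2.0) ** 2
        flat = (cell[:, 0] * self.n_side + cell[:, 1]) * self.n_side + cell[:, 2]
        return np.where(inside, flat, -1)

    def score_history(self, positions, energies):
        """Accumulate one history's deposits into per-sphere event energies."""
        e = np.asarray(energies, dtype=float)
        idx = self.sphere_index(positions)
        hit = idx >= 0
        self.unscored_energy += float(e[~hit].sum())
        if not np.any(hit):
            return
        uniq, inv = np.unique(idx[hit], return_inverse=True)
        sums = np.bincount(inv, weights=e[hit], minlength=uniq.size)
        self._events.append(sums)
        self.scored_energy += float(sums.sum())

    @property
    def event_energies(self) -> np.ndarray:
        """Energy [eV] per (history, sphere) event."""
        return np.concatenate(self._events) if self._events else np.empty(0)

    def finalize(self, y_max: float | None = None,
                 bins_per_decade: int = 20) -> "LinealEnergyResult":
        return lineal_energy_finalize(self.event_energies, self.diameter,
                                      y_max=y_max,
                                      bins_per_decade=bins_per_decade)


@dataclass
class LinealEnergyResult:
    """Single-event lineal-energy distribution and its moments.

    ``y`` in keV/um (== eV/nm).  ``y_f`` / ``y_d`` are the frequency- and
    dose-mean lineal energies; ``f`` is the normalized probability density
    on log-spaced ``bin_edges``.
    """

    y_events: np.ndarray
    mean_chord: float                  # nm
    bin_edges: np.ndarray
    f: np.ndarray
    y_f: float
    y_d: float
    y_max_cut: float | None = None

    @property
    def yf_y(self) -> np.ndarray:
        centres = np.sqrt(self.bin_edges[1:] * self.bin_edges[:-1])
        return centres * self.f


def lineal_energy_finalize(event_energies, diameter: float,
                           y_max: float | None = None,
                           bins_per_decade: int = 20) -> LinealEnergyResult:
    """Convert per-(history, sphere) energies [eV] to the lineal-energy
    distribution for spheres of ``diameter`` [nm].

    y = energy / ((2/3) * diameter); with ``y_max`` the moments integrate
    only events with y <= y_max (restricted dose mean).
    """
    eps = np.asarray(event_energies, dtype=float)
    eps = eps[eps > 0]
    if eps.size == 0:
        raise ValueError("no scored events")
    chord = MEAN_CHORD_FACTOR * diameter
    y = eps / chord                    # eV/nm == keV/um
    y_sel = y if y_max is None else y[y <= y_max]
    if y_sel.size == 0:
        raise ValueError("no events below y_max")
    y_f = float(np.mean(y_sel))
    y_d = float(np.sum(y_sel**2) / np.sum(y_sel))
    lo = 10 ** np.floor(np.log10(y.min()))
    hi = 10 ** np.ceil(np.log10(y.max()) + 1e-12)
    n_bins = int(round(np.log10(hi / lo) * bins_per_decade)) or 1
    edges = np.geomspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(y, bins=edges)
    f = counts / (np.diff(edges) * y.size)
    return LinealEnergyResult(y, chord, edges, f, y_f, y_d, y_max)


def mean_chord_mc(diameter: float, n: int, rng: np.random.Generator) -> float:
    """Monte-Carlo mean chord of a sphere under uniform isotropic randomness
    (independent oracle route: sample impact parameters uniformly over the
    projected disk)."""
    radius = diameter / 2.0
    b2 = rng.random(n) * radius**2
    return float(np.mean(2.0 * np.sqrt(radius**2 - b2)))


# --------------------------------------------------------------------------
# other scorers
# --------------------------------------------------------------------------

class RadialDoseTally:
    """Cylindrical-shell energy/dose profile around the beam axis (z)."""

    def __init__(self, r_min: float = 0.1, r_max: float = 1.0e6,
                 bins_per_decade: int = 16):
        n = int(round(np.log10(r_max / r_min) * bins_per_decade))
        self.edges = np.geomspace(r_min, r_max, n + 1)   # nm
        self.energy = np.zeros(n)                        # eV
        self.core_energy = 0.0                           # r < r_min
        self.histories = 0

    def score(self, positions, energies):
        p = np.atleast_2d(np.asarray(positions, dtype=float))
        e = np.asarray(energies, dtype=float)
        r = np.hypot(p[:, 0], p[:, 1])
        core = r < self.edges[0]
        self.core_energy += float(e[core].sum())
        h, _ = np.histogram(r[~core], bins=self.edges, weights=e[~core])
        self.energy += h

    def finalize(self, mass_density: float, thickness_nm: float):
        """Dose [eV/g] per radial bin, per history."""
        vol_cm3 = (np.pi * (self.edges[1:]**2 - self.edges[:-1]**2)
                   * thickness_nm * 1e-21)
        mass_g = mass_density * vol_cm3
        n = max(self.histories, 1)
        return {
            "r_edges_nm": self.edges,
            "energy_eV": self.energy / n,
            "dose_eV_per_g": self.energy / mass_g / n,
        }


@dataclass
class RangeTally:
    """Final longitudinal coordinates [cm] at the transport threshold."""

    z_values: list = field(default_factory=list)

    def score(self, z: float):
        self.z_values.append(float(z))

    def finalize(self):
        z = np.asarray(self.z_values)
        return {"mean_cm": float(z.mean()), "std_cm": float(z.std(ddof=1))
                if z.size > 1 else 0.0, "n": int(z.size),
                "z_cm": [float(v) for v in z]}


class SpectrumTally:
    """Histogram of first-generation secondary-electron birth energies,
    normalized per incident proton per unit energy [1/eV]."""

    def __init__(self, e_min: float = 0.1, e_max: float = 1.0e6,
                 bins_per_decade: int = 16):
        n = int(round(np.log10(e_max / e_min) * bins_per_decade))
        self.edges = np.geomspace(e_min, e_max, n + 1)
        self.counts = np.zeros(n)
        self.n_born = 0
        self.histories = 0

    def score(self, energies):
        e = np.asarray(energies, dtype=float)
        h, _ = np.histogram(e, bins=self.edges)
        self.counts += h
        self.n_born += e.size

    def finalize(self):
        n = max(self.histories, 1)
        return {
            "e_edges_eV": self.edges,
            "per_proton_per_eV": self.counts / np.diff(self.edges) / n,
            "ionisations_per_proton": self.n_born / n,
        }
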