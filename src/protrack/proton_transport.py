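"""Event-by-event proton transport with restricted-stopping-power bookkeeping.

A proton flies freely between ionisations; flight lengths are sampled from
the macroscopic ionisation cross section.  Over a flight of length dL the
kinetic energy drops by the *total* stopping-power budget minus the mean
ionising contribution (which is instead realised discretely at the
collision: the sampled shell potential is deposited on the spot and the
sampled secondary-electron energy leaves with the electron):

    E_C = E_A - S_tot dL + (kinetic moment) dL + (potential moment) dL
    E_D = E_C - E' - eps_I

The continuous ("non-ionising") deposit along the step is the same
S_tot dL - (total ionising moment) dL.  Because the stopping model and the
cross sections are independent fits this can occasionally be negative
(pre-collision energy above the flight-start energy); the combined
step+collision deposit is then floored at zero so no history ever deposits
negative energy, at the cost of a <<1% bias in the track-averaged loss.
The end-of-flight energy is always strictly below the start energy.

Positions are in nm, energies in eV, cross sections in cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import ELECTRON_MASS_EV, NM_PER_CM, PROTON_MASS_EV
from .materials import Material
from .rudd_xs import CrossSectionTable, get_table
from .stopping import StoppingModel, _model as _stopping_model

__all__ = [
    "ParticleState",
    "DepositBuffer",
    "CutoffPolicy",
    "MECHANISMS",
    "sample_free_path",
    "step_energy_update",
    "electron_emission_kinematics",
    "transport_proton",
    "slow_down_projected",
]

#: Deposit mechanism tags (column codes in :class:`DepositBuffer`).
MECHANISMS = {
    "non-ionising-continuous": 0,
    "ionisation-potential": 1,
    "electron-collision": 2,
    "electron-cutoff": 3,
    "residual": 4,
}


@dataclass
class ParticleState:
    """Kinematic state of one transported particle."""

    position: np.ndarray          # nm
    direction: np.ndarray         # unit vector
    energy: float                 # eV kinetic
    time: float = 0.0             # s (advanced kinematically, non-relativistic)
    history: int = 0
    species: str = "proton"
    alive: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.energy < 0:
            raise ValueError("kinetic energy must be non-negative")


class DepositBuffer:
    """Column store of deposit events: position [nm], energy [eV], mechanism
    code and history id.  The atomic unit every tally consumes."""

    def __init__(self):
        self._pos: list[np.ndarray] = []
        self._energy: list[np.ndarray] = []
        self._mech: list[np.ndarray] = []
        self._hist: list[np.ndarray] = []

    def add(self, positions, energies, mechanism: int, history: int):
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        e = np.atleast_1d(np.asarray(energies, dtype=float))
        if np.any(e < 0):
            raise ValueError("deposit energies must be >= 0")
        keep = e > 0
        if not np.any(keep):
            return
        self._pos.append(pos[keep])
        self._energy.append(e[keep])
        self._mech.append(np.full(int(keep.sum()), mechanism, dtype=np.int8))
        self._hist.append(np.full(int(keep.sum()), history, dtype=np.int64))

    @property
    def positions(self) -> np.ndarray:
        return np.concatenate(self._pos) if self._pos else np.empty((0, 3))

    @property
    def energies(self) -> np.ndarray:
        return np.concatenate(self._energy) if self._energy else np.empty(0)

    @property
    def mechanisms(self) -> np.ndarray:
        return np.concatenate(self._mech) if self._mech else np.empty(0, dtype=np.int8)

    @property
    def histories(self) -> np.ndarray:
        return np.concatenate(self._hist) if self._hist else np.empty(0, dtype=np.int64)

    def total(self) -> float:
        return float(sum(a.sum() for a in self._energy))

    def __len__(self) -> int:
        return sum(a.size for a in self._energy)

    def to_csv(self, path):
        """Phase-space dump: history, mechanism, x_nm, y_nm, z_nm, E_eV."""
        pos = self.positions
        data = np.column_stack([self.histories, self.mechanisms,
                                pos, self.energies])
        np.savetxt(path, data, delimiter=",", comments="",
                   header="history,mechanism,x_nm,y_nm,z_nm,E_eV",
                   fmt=["%d", "%d", "%.6g", "%.6g", "%.6g", "%.8g"])


@dataclass
class CutoffPolicy:
    """When and how a proton history ends.

    ``energy_floor``: terminate below this kinetic energy [eV].
    ``fractional_loss``: terminate once the proton has lost this fraction of
    its initial energy (benchmark-style fixed-energy sampling).
    ``deposit_remainder``: deposit the remaining kinetic energy locally on
    termination (closed-geometry energy balance) or discard it.
    """

    energy_floor: float = 1.0e3
    fractional_loss: float | None = None
    deposit_remainder: bool = True

    def __post_init__(self):
        if self.energy_floor <= 0:
            raise ValueError("energy_floor must be positive")
        if self.fractional_loss is not None and not 0 < self.fractional_loss < 1:
            raise ValueError("fractional_loss must be in (0, 1)")

    def threshold(self, e0: float) -> float:
        thr = self.energy_floor
        if self.fractional_loss is not None:
            thr = max(thr, e0 * (1.0 - self.fractional_loss))
        return thr


def sample_free_path(material: Material, ep: float, rng: np.random.Generator,
                     table: CrossSectionTable | None = None) -> float:
    """Exponential free-flight length [cm]: dL = -ln(r) / Sigma_ion(Ep)."""
    table = table or get_table(material)
    sig = table.macroscopic(ep)
    if sig <= 0:
        raise ValueError(f"Sigma_ion = 0 at Ep = {ep} eV (sub-threshold)")
    r = rng.random()
    while r == 0.0:  # pragma: no cover - measure-zero guard
        r = rng.random()
    return -math.log(r) / sig


@dataclass
class StepResult:
    energy_end: float       # E_D [eV]
    deposit_step: float     # continuous deposit spread along the flight [eV]
    deposit_collision: float  # deposit at the collision point [eV]
    floored: bool           # combined deposit was clipped at zero
    terminated: bool        # E_D fell below zero; history must stop here


def step_energy_update(ep_start: float, material: Material, dl: float,
                       sampled: tuple[int, float],
                       table: CrossSectionTable | None = None,
                       stopping: StoppingModel | None = None) -> StepResult:
    """Apply the energy bookkeeping for one flight + collision.

    ``dl`` in cm; ``sampled`` is (shell index, ejected-electron energy E').
    Guarantees ``ep_start - energy_end == deposit_step + deposit_collision
    + E'`` exactly (closure audit), and ``energy_end < ep_start``.
    """
    if ep_start <= 0:
        raise ValueError("ep_start must be positive")
    table = table or get_table(material)
    stopping = stopping or _stopping_model(material)
    ishell, e_sec = sampled
    eps_i = table.shells[ishell].ionisation_potential
    s_tot = stopping(ep_start)                      # eV/cm
    loss_tot, _, _ = table.loss_rates(ep_start)     # eV/cm
    d_cont = (s_tot - loss_tot) * dl                # may be negative
    combined = d_cont + eps_i
    if combined < 0:
        # floor: no deposit, no continuous credit beyond the potential
        d_step, d_coll, floored = 0.0, 0.0, True
    else:
        d_step = max(d_cont, 0.0)
        d_coll = combined - d_step
        floored = False
    e_end = ep_start - d_step - d_coll - e_sec
    if e_end < 0:
        return StepResult(0.0, d_step, d_coll, floored, True)
    return StepResult(e_end, d_step, d_coll, floored, False)


def _p_of(mass_ev: float, e_kin: float) -> float:
    """Non-relativistic momentum [eV/c]."""
    return math.sqrt(2.0 * mass_ev * max(e_kin, 0.0))


def rotate_directions(dirs: np.ndarray, cos_t: np.ndarray,
                      phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors [n,3] by polar angle (cosine) and azimuth."""
    cos_t = np.asarray(cos_t, dtype=float)
    phi = np.asarray(phi, dtype=float)
    sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 0.0))
    swap = np.abs(dirs[:, 0]) > 0.9
    a = np.zeros_like(dirs)
    a[~swap, 0] = 1.0
    a[swap, 1] = 1.0
    u = np.cross(dirs, a)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(dirs, u)
    out = (cos_t[:, None] * dirs
           + sin_t[:, None] * (np.cos(phi)[:, None] * u
                               + np.sin(phi)[:, None] * v))
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _onb(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``direction``."""
    a = np.array([1.0, 0.0, 0.0]) if abs(direction[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, a)
    u /= np.linalg.norm(u)
    return u, np.cross(direction, u)


def electron_emission_kinematics(ep: float, e_sec: float, eps_i: float,
                                 proton_dir: np.ndarray, phi: float):
    """Binary-collision emission kinematics.

    cos^2(theta) = E'/E'_max with E'_max = 4 (m_e/m_p) Ep; azimuth ``phi``.
    The proton direction is updated so that proton + electron momenta balance
    the incoming proton momentum; the magnitude mismatch (the binding energy
    makes exact closure impossible, extreme at very forward emission where
    the cosine clamps to 1) is returned as a residual momentum vector
    [eV/c] assigned to the target atom.

    Returns ``(electron_dir, new_proton_dir, residual_momentum)``.
    """
    if e_sec < 0 or ep <= 0:
        raise ValueError("energies must be non-negative (Ep positive)")
    proton_dir = np.asarray(proton_dir, dtype=float)
    e_max = 4.0 * ELECTRON_MASS_EV / PROTON_MASS_EV * ep
    cos_t = math.sqrt(min(e_sec / e_max, 1.0))
    sin_t = math.sqrt(max(1.0 - cos_t * cos_t, 0.0))
    u, v = _onb(proton_dir)
    e_dir = (cos_t * proton_dir
             + sin_t * (math.cos(phi) * u + math.sin(phi) * v))
    p_in = _p_of(PROTON_MASS_EV, ep)
    p_e = _p_of(ELECTRON_MASS_EV, e_sec)
    balance = p_in * proton_dir - p_e * e_dir
    bnorm = float(np.linalg.norm(balance))
    new_dir = balance / bnorm
    e_after = max(ep - e_sec - eps_i, 0.0)
    residual = (bnorm - _p_of(PROTON_MASS_EV, e_after)) * new_dir
    return e_dir, new_dir, residual


_PROTON_SPEED = 2.99792458e17  # nm/s times beta, see _speed_nm_s


def _speed_nm_s(e_kin: float) -> float:
    gamma = 1.0 + e_kin / PROTON_MASS_EV
    beta = math.sqrt(max(1.0 - 1.0 / gamma**2, 0.0))
    return beta * _PROTON_SPEED


def transport_proton(state: ParticleState, material: Material, geometry,
                     deposits: DepositBuffer, rng: np.random.Generator,
                     cutoff: CutoffPolicy | None = None,
                     table: CrossSectionTable | None = None,
                     stopping: StoppingModel | None = None,
                     substep_nm: float = 10.0,
                     collect_secondaries: bool = True):
    """Transport one proton history to its cutoff.

    Returns ``(secondaries, info)`` where ``secondaries`` is a dict of arrays
    (``position`` [n,3] nm, ``direction`` [n,3], ``energy`` [n] eV) describing
    the electrons born along the track, and ``info`` carries counters
    (collisions, floored steps, discarded energy).
    """
    cutoff = cutoff or CutoffPolicy()
    table = table or get_table(material)
    stopping = stopping or _stopping_model(material)
    e0 = state.energy
    threshold = cutoff.threshold(e0)

    sec_pos, sec_dir, sec_e = [], [], []
    n_coll = 0
    n_floor = 0
    discarded = 0.0

    while state.alive:
        ep = state.energy
        if ep <= threshold or table.macroscopic(ep) <= 0:
            if cutoff.deposit_remainder and ep > 0:
                deposits.add(state.position.copy(), ep, MECHANISMS["residual"],
                             state.history)
            else:
                discarded += ep
            state.alive = False
            break
        dl_cm = sample_free_path(material, ep, rng, table)
        dl_nm = dl_cm * NM_PER_CM

        ishell, e_sec = table.sample_secondary(ep, rng)
        step = step_energy_update(ep, material, dl_cm, (ishell, e_sec),
                                  table, stopping)
        n_floor += step.floored

        # advance with boundary folding; spread the continuous deposit
        pos0, dir0 = state.position, state.direction
        if step.deposit_step > 0:
            k = max(int(math.ceil(dl_nm / substep_nm)), 1)
            s_mid = (np.arange(k) + 0.5) * (dl_nm / k)
            pts = geometry.path_points(pos0, dir0, s_mid)
            deposits.add(pts, np.full(k, step.deposit_step / k),
                         MECHANISMS["non-ionising-continuous"], state.history)
        new_pos, new_dir = geometry.advance(pos0[None, :], dir0[None, :],
                                            np.array([dl_nm]))
        pos_c = new_pos[0]
        dir_c = new_dir[0]
        state.time += dl_nm / _speed_nm_s(ep)

        deposits.add(pos_c, step.deposit_collision,
                     MECHANISMS["ionisation-potential"], state.history)

        eps_i = table.shells[ishell].ionisation_potential
        phi = rng.uniform(0.0, 2.0 * math.pi)
        e_dir, p_dir, _residual = electron_emission_kinematics(
            ep, e_sec, eps_i, dir_c, phi)
        if collect_secondaries:
            sec_pos.append(pos_c)
            sec_dir.append(e_dir)
            sec_e.append(e_sec)
        else:
            discarded += e_sec

        state.position = pos_c
        state.direction = p_dir

        if step.terminated:
            # E_D < 0: remaining energy deposited at the collision point
            leftover = ep - step.deposit_step - step.deposit_collision - e_sec
            deposits.add(pos_c, max(leftover, 0.0), MECHANISMS["residual"],
                         state.history)
            state.energy = 0.0
            state.alive = False
        else:
            state.energy = step.energy_end
        n_coll += 1

    secondaries = {
        "position": np.array(sec_pos) if sec_pos else np.empty((0, 3)),
        "direction": np.array(sec_dir) if sec_dir else np.empty((0, 3)),
        "energy": np.array(sec_e) if sec_e else np.empty(0),
    }
    info = {"collisions": n_coll, "floored": n_floor, "discarded": discarded}
    return secondaries, info


def transport_proton_grouped(state: ParticleState, material: Material,
                             geometry, deposits: DepositBuffer,
                             rng: np.random.Generator,
                             cutoff: CutoffPolicy | None = None,
                             table: CrossSectionTable | None = None,
                             stopping: StoppingModel | None = None,
                             substep_nm: float = 10.0,
                             refresh_fraction: float = 0.002):
    """Vectorised variant of :func:`transport_proton`.

    Collisions are processed in blocks over which the cross sections and
    stopping power are evaluated at the block-start energy (refreshed every
    ``refresh_fraction`` of the current energy, well below the fractional
    scale on which the rates vary).  The per-collision bookkeeping, deposit
    placement and kinematics are otherwise identical; recoil deflection is
    applied once per block from the accumulated transverse electron momentum.
    """
    cutoff = cutoff or CutoffPolicy()
    table = table or get_table(material)
    stopping = stopping or _stopping_model(material)
    e0 = state.energy
    threshold = cutoff.threshold(e0)
    eps_of = np.array([sh.ionisation_potential for sh in table.shells])

    sec_pos, sec_dir, sec_e = [], [], []
    n_coll = 0
    n_floor = 0
    discarded = 0.0

    while state.alive:
        ep = state.energy
        sig = table.macroscopic(ep) if ep > 0 else 0.0
        if ep <= threshold or sig <= 0:
            if cutoff.deposit_remainder and ep > 0:
                deposits.add(state.position.copy(), ep,
                             MECHANISMS["residual"], state.history)
            else:
                discarded += ep
            state.alive = False
            break
        loss_tot, _, _ = table.loss_rates(ep)
        s_tot = stopping(ep)
        mean_loss = s_tot / sig
        g = int(np.clip(refresh_fraction * ep / mean_loss, 1, 50000))

        dl_cm = -np.log(rng.random(g)) / sig
        ish, e_sec = table.sample_secondary(ep, rng, size=g)
        eps_arr = eps_of[ish]
        d_cont = (s_tot - loss_tot) * dl_cm
        combined = d_cont + eps_arr
        floored = combined < 0
        combined = np.where(floored, 0.0, combined)
        d_step = np.where(floored, 0.0, np.maximum(d_cont, 0.0))
        d_coll = combined - d_step
        de = combined + e_sec
        cum = np.cumsum(de)
        e_before = ep - np.concatenate([[0.0], cum[:-1]])
        n_used = int(np.sum(e_before > threshold))
        if n_used == 0:
            n_used = 1  # always take at least the first collision
        sl = slice(0, n_used)
        dl_nm = dl_cm[sl] * NM_PER_CM
        s_coll = np.cumsum(dl_nm)
        pos0, dir0 = state.position, state.direction

        # continuous deposit, sub-sampled along each flight
        dsl = d_step[sl]
        has = dsl > 0
        if np.any(has):
            k = np.ceil(dl_nm / substep_nm).astype(int)
            k[~has] = 0
            kk = int(k.sum())
            if kk:
                flight = np.repeat(np.arange(n_used), k)
                j = np.arange(kk) - np.repeat(np.cumsum(k) - k, k)
                start = s_coll - dl_nm
                s_pts = start[flight] + (j + 0.5) * (dl_nm / np.maximum(k, 1))[flight]
                pts = geometry.path_points(pos0, dir0, s_pts)
                deposits.add(pts, (dsl / np.maximum(k, 1))[flight],
                             MECHANISMS["non-ionising-continuous"],
                             state.history)

        coll_pts, coll_dirs = geometry.path_with_dirs(pos0, dir0, s_coll)
        deposits.add(coll_pts, d_coll[sl], MECHANISMS["ionisation-potential"],
                     state.history)

        # electron emission kinematics (vectorised, clamped-forward included)
        e_max = 4.0 * ELECTRON_MASS_EV / PROTON_MASS_EV * e_before[sl]
        cos_t = np.sqrt(np.minimum(e_sec[sl] / e_max, 1.0))
        phi = rng.uniform(0.0, 2.0 * math.pi, n_used)
        e_dirs = rotate_directions(coll_dirs, cos_t, phi)
        sec_pos.append(coll_pts)
        sec_dir.append(e_dirs)
        sec_e.append(e_sec[sl])

        # block-end state
        new_pos, new_dir = geometry.advance(pos0[None, :], dir0[None, :],
                                            np.array([s_coll[-1]]))
        ep_end = float(ep - cum[n_used - 1])
        # accumulated recoil: transverse electron momenta in the folded frame
        p_e = np.sqrt(2.0 * ELECTRON_MASS_EV * e_sec[sl])
        sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 0.0))
        dp = (p_e * sin_t)[:, None] * (e_dirs - cos_t[:, None] * coll_dirs)
        p_long = _p_of(PROTON_MASS_EV, max(ep_end, 0.0))
        p_vec = p_long * new_dir[0] - dp.sum(axis=0)
        norm = np.linalg.norm(p_vec)
        state.position = new_pos[0]
        state.direction = p_vec / norm if norm > 0 else new_dir[0]
        state.time += float(np.sum(dl_nm / _speed_nm_s(ep)))
        state.energy = max(ep_end, 0.0)
        n_coll += n_used
        n_floor += int(np.sum(floored[sl]))

    secondaries = {
        "position": np.concatenate(sec_pos) if sec_pos else np.empty((0, 3)),
        "direction": np.concatenate(sec_dir) if sec_dir else np.empty((0, 3)),
        "energy": np.concatenate(sec_e) if sec_e else np.empty(0),
    }
    info = {"collisions": n_coll, "floored": n_floor, "discarded": discarded}
    return secondaries, info


# --------------------------------------------------------------------------
# fast grouped slowing-down (projected-range benchmark; no secondaries kept)
# --------------------------------------------------------------------------

def slow_down_projected(material: Material, e0: float,
                        rng: np.random.Generator,
                        e_stop: float = 1.0e3,
                        table: CrossSectionTable | None = None,
                        stopping: StoppingModel | None = None,
                        refresh_fraction: float = 0.003) -> float:
    """March a proton to ``e_stop`` and return its projected depth [cm].

    Statistically equivalent to :func:`transport_proton` with secondaries
    discarded: collisions are processed in groups over which the energy is
    frozen for rate evaluation (refreshed every ``refresh_fraction`` of the
    current energy), which keeps the Python overhead per history at
    O(energy decades) instead of O(collisions).
    """
    table = table or get_table(material)
    stopping = stopping or _stopping_model(material)
    ep = e0
    z = 0.0                       # projected depth, cm
    direction = np.array([0.0, 0.0, 1.0])
    p_vec = _p_of(PROTON_MASS_EV, ep) * direction
    while ep > e_stop:
        sig = table.macroscopic(ep)
        if sig <= 0:
            break
        loss_tot, _, loss_pot = table.loss_rates(ep)
        s_tot = stopping(ep)
        mean_loss = s_tot / sig   # eV per collision (track-average contract)
        de_block = max(refresh_fraction * ep, 10.0 * mean_loss)
        g = max(int(de_block / mean_loss), 1)

        dl = -np.log(rng.random(g)) / sig
        ish, e_sec = table.sample_secondary(ep, rng, size=g)
        eps_arr = np.array([sh.ionisation_potential for sh in table.shells])[ish]
        d_cont = (s_tot - loss_tot) * dl
        combined = np.maximum(d_cont + eps_arr, 0.0)
        de = combined + e_sec
        cum = np.cumsum(de)
        e_arr = ep - cum
        stop_idx = int(np.searchsorted(-e_arr, -e_stop))  # first below e_stop
        n_used = min(stop_idx + 1, g)
        dz = float(np.sum(dl[:n_used])) * direction[2]
        z += dz
        ep = float(e_arr[n_used - 1])

        # accumulated recoil deflection over the group (tiny at these energies)
        u, v = _onb(direction)
        e_max = 4.0 * ELECTRON_MASS_EV / PROTON_MASS_EV * ep
        cos_t = np.sqrt(np.minimum(e_sec[:n_used] / e_max, 1.0))
        sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 0.0))
        p_e = np.sqrt(2.0 * ELECTRON_MASS_EV * e_sec[:n_used])
        phi = rng.uniform(0.0, 2.0 * math.pi, n_used)
        dp_perp = (p_e * sin_t * np.cos(phi)).sum() * u \
            + (p_e * sin_t * np.sin(phi)).sum() * v
        p_long = _p_of(PROTON_MASS_EV, max(ep, 0.0))
        p_vec = p_long * direction - dp_perp
        direction = p_vec / np.linalg.norm(p_vec)
        if ep <= 0:
            break
    return z
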