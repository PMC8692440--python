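"""Proton-impact singly-differential ionisation cross sections (SDCS).

Per-shell nine-parameter model: with ``w = E/eps`` (ejected-electron energy
scaled by the shell potential) and ``v = sqrt(Ep * m_e/m_p / eps)`` (scaled
projectile speed),

    d(sigma)/dE = (S / eps) * [F1(v) + F2(v) w] /
                  [(1 + w)^3 * (1 + exp(alpha (w - w_c) / v))]

    S   = 4 pi a0^2 N (Ry/eps)^2
    w_c = 4 v^2 - 2 v - Ry / (4 eps)
    F1  = L1 + H1,  H1 = A1 ln(1+v^2) / (v^2 + B1/v^2),
                    L1 = C1 v^D1 / (1 + E1 v^(D1+4))
    F2  = L2 H2 / (L2 + H2),  H2 = A2/v^2 + B2/v^4,  L2 = C2 v^D2

The per-shell cross section includes the shell occupancy ``N``; material-level
sums additionally weight each shell by its per-average-molecule multiplicity.

Two evaluation routes are provided: direct adaptive quadrature
(:func:`total_shell_xs`, :func:`mean_ionising_loss_rate`) and the
pre-tabulated :class:`CrossSectionTable` used by the transport loop. Tests
cross-check them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BOHR_RADIUS_CM, ME_OVER_MP, RYDBERG_EV
from .materials import ElectronShell, Material

__all__ = [
    "sdcs",
    "total_shell_xs",
    "macroscopic_ionisation_xs",
    "mean_ionising_loss_rate",
    "sample_secondary",
    "CrossSectionTable",
    "get_table",
]

_FOUR_PI_A0_SQ = 4.0 * np.pi * BOHR_RADIUS_CM**2


def sdcs(shell: ElectronShell, ep: float, e) -> np.ndarray | float:
    """SDCS [cm^2/eV] for ejecting an electron of energy ``e`` [eV] from
    ``shell`` by a proton of kinetic energy ``ep`` [eV].

    ``e`` may be a scalar or array; the value is per ``shell.occupancy``
    electrons.
    """
    if ep <= 0:
        raise ValueError(f"proton energy must be positive, got {ep}")
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr < 0):
        raise ValueError("ejected-electron energy must be non-negative")
    p = shell.parameter_set
    eps = shell.ionisation_potential
    v2 = ep * ME_OVER_MP / eps
    v = np.sqrt(v2)
    s = _FOUR_PI_A0_SQ * shell.occupancy * (RYDBERG_EV / eps) ** 2
    wc = 4.0 * v2 - 2.0 * v - RYDBERG_EV / (4.0 * eps)
    h1 = p.A1 * np.log1p(v2) / (v2 + p.B1 / v2)
    l1 = p.C1 * v**p.D1 / (1.0 + p.E1 * v ** (p.D1 + 4.0))
    f1 = l1 + h1
    h2 = p.A2 / v2 + p.B2 / (v2 * v2)
    l2 = p.C2 * v**p.D2
    f2 = l2 * h2 / (l2 + h2)
    w = e_arr / eps
    cut = np.exp(np.clip(p.alpha * (w - wc) / v, -700.0, 700.0))
    out = (s / eps) * (f1 + f2 * w) / (1.0 + w) ** 3 / (1.0 + cut)
    return out if out.ndim else float(out)


def _e_upper(shell: ElectronShell, ep: float) -> float:
    """Upper integration limit: past the kinematic cutoff the exponential
    suppresses the integrand below ~1e-12 of its peak."""
    eps = shell.ionisation_potential
    v2 = ep * ME_OVER_MP / eps
    v = np.sqrt(v2)
    wc = 4.0 * v2 - 2.0 * v - RYDBERG_EV / (4.0 * eps)
    w_hi = max(wc, 0.0) + 40.0 * v / shell.parameter_set.alpha + 10.0
    return eps * w_hi


def _grid(shell: ElectronShell, ep: float, n: int) -> np.ndarray:
    """[0] + log-spaced grid up to the effective kinematic limit."""
    eps = shell.ionisation_potential
    e_hi = _e_upper(shell, ep)
    e_lo = eps * 1e-4
    return np.concatenate([[0.0], np.geomspace(e_lo, e_hi, n)])


def total_shell_xs(shell: ElectronShell, ep: float, rtol: float = 1e-6) -> float:
    """Integrated ionisation cross section [cm^2] of one shell, converged
    adaptively to relative tolerance ``rtol``."""
    if ep <= 0:
        raise ValueError(f"proton energy must be positive, got {ep}")
    n = 512
    prev = None
    for _ in range(8):
        grid = _grid(shell, ep, n)
        val = float(np.trapezoid(sdcs(shell, ep, grid), grid))
        if prev is not None and abs(val - prev) <= rtol * max(abs(val), 1e-300):
            return val
        prev = val
        n *= 2
    raise RuntimeError(
        f"shell {shell.label}: quadrature did not converge to rtol={rtol} "
        f"(last={val}, prev={prev}, n={n})")


def _shell_moments(shell: ElectronShell, ep: float, n: int = 2048):
    """(sigma, int E sigma dE, int (eps+E) sigma dE) by quadrature."""
    grid = _grid(shell, ep, n)
    y = sdcs(shell, ep, grid)
    sig = np.trapezoid(y, grid)
    kin = np.trapezoid(grid * y, grid)
    return float(sig), float(kin), float(kin + shell.ionisation_potential * sig)


def macroscopic_ionisation_xs(material: Material, ep: float) -> float:
    """Macroscopic ionisation cross section Sigma_ion [1/cm]."""
    sig = sum(w * total_shell_xs(sh, ep) for sh, w in material.shells)
    return material.number_density * sig


def mean_ionising_loss_rate(material: Material, ep: float) -> tuple[float, float]:
    """Mean ionising energy-loss rate [eV/cm].

    Returns ``(total, kinetic)`` where ``total = n sum_i int (eps_i + E)
    sigma_i dE`` and ``kinetic`` is the same without the potential term.
    """
    tot = 0.0
    kin = 0.0
    for sh, w in material.shells:
        _, k, t = _shell_moments(sh, ep)
        kin += w * k
        tot += w * t
    n = material.number_density
    return n * tot, n * kin


# --------------------------------------------------------------------------
# tabulation
# --------------------------------------------------------------------------

def _quantile_levels(n_tail: int = 64) -> np.ndarray:
    lin = np.linspace(0.0, 0.98, 197)
    tail = 1.0 - 0.02 * 10.0 ** (-np.linspace(0.0, 5.3, n_tail + 1)[1:])
    return np.concatenate([lin, tail])


@dataclass
class CrossSectionTable:
    """Per-material tabulation of shell cross sections, loss-rate moments and
    inverse-CDF sampling tables on a log proton-energy grid."""

    material: Material
    ep_grid: np.ndarray                 # [nEp] eV
    shells: list[ElectronShell]
    weights: np.ndarray                 # [nsh] per-average-molecule multiplicity
    sigma: np.ndarray                   # [nsh, nEp] cm^2 (per shell, incl. occupancy)
    kin_moment: np.ndarray              # [nsh, nEp] eV cm^2
    tot_moment: np.ndarray              # [nsh, nEp] eV cm^2
    q_levels: np.ndarray                # [nq]
    log_e_quant: np.ndarray             # [nsh, nEp, nq] log10(E' [eV])
    _log_ep: np.ndarray = field(init=False)

    def __post_init__(self):
        self._log_ep = np.log10(self.ep_grid)
        if np.any(self.sigma < 0):
            raise ValueError("negative cross section in table")

    # -- construction ------------------------------------------------------

    @classmethod
    def build(cls, material: Material, ep_min: float = 1e3, ep_max: float = 1e9,
              pts_per_decade: int = 32, n_e: int = 1024) -> "CrossSectionTable":
        n_ep = int(round(np.log10(ep_max / ep_min) * pts_per_decade)) + 1
        ep_grid = np.geomspace(ep_min, ep_max, n_ep)
        shells = [sh for sh, _ in material.shells]
        weights = np.array([w for _, w in material.shells])
        nsh = len(shells)
        q = _quantile_levels()
        sigma = np.zeros((nsh, n_ep))
        kin = np.zeros((nsh, n_ep))
        tot = np.zeros((nsh, n_ep))
        logeq = np.zeros((nsh, n_ep, q.size))
        for i, sh in enumerate(shells):
            for j, ep in enumerate(ep_grid):
                grid = _grid(sh, ep, n_e)
                y = sdcs(sh, ep, grid)
                cdf = np.concatenate([[0.0], np.cumsum(
                    0.5 * (y[1:] + y[:-1]) * np.diff(grid))])
                sigma[i, j] = cdf[-1]
                kin[i, j] = np.trapezoid(grid * y, grid)
                tot[i, j] = kin[i, j] + sh.ionisation_potential * sigma[i, j]
                if cdf[-1] > 0:
                    u = cdf / cdf[-1]
                    # strictly increasing section for inversion
                    keep = np.concatenate([[True], np.diff(u) > 0])
                    logeq[i, j] = np.interp(
                        q, u[keep], np.log10(np.maximum(grid[keep], 1e-6)))
        return cls(material, ep_grid, shells, weights, sigma, kin, tot, q, logeq)

    # -- lookups -----------------------------------------------------------

    def _bracket(self, ep: float):
        x = np.log10(ep)
        j = int(np.clip(np.searchsorted(self._log_ep, x) - 1, 0, self.ep_grid.size - 2))
        t = (x - self._log_ep[j]) / (self._log_ep[j + 1] - self._log_ep[j])
        return j, float(np.clip(t, 0.0, 1.0))

    def _interp(self, arr: np.ndarray, ep: float) -> np.ndarray:
        """Log-log interpolation of a [nsh, nEp] table at proton energy ``ep``."""
        j, t = self._bracket(ep)
        lo = np.log10(np.maximum(arr[:, j], 1e-300))
        hi = np.log10(np.maximum(arr[:, j + 1], 1e-300))
        out = 10.0 ** ((1.0 - t) * lo + t * hi)
        return np.where((arr[:, j] > 0) | (arr[:, j + 1] > 0), out, 0.0)

    def sigma_shells(self, ep: float) -> np.ndarray:
        """Per-shell cross sections [cm^2] at ``ep``, occupancy included."""
        return self._interp(self.sigma, ep)

    def macroscopic(self, ep: float) -> float:
        """Sigma_ion [1/cm]; zero below the tabulated energy range
        (sub-threshold for transport purposes)."""
        if ep < self.ep_grid[0]:
            return 0.0
        return float(self.material.number_density
                     * np.dot(self.weights, self.sigma_shells(ep)))

    def loss_rates(self, ep: float) -> tuple[float, float, float]:
        """(total ionising, kinetic-only, potential-only) loss rates [eV/cm]."""
        n = self.material.number_density
        tot = float(n * np.dot(self.weights, self._interp(self.tot_moment, ep)))
        kin = float(n * np.dot(self.weights, self._interp(self.kin_moment, ep)))
        return tot, kin, tot - kin

    def shell_probs(self, ep: float) -> np.ndarray:
        p = self.weights * self.sigma_shells(ep)
        total = p.sum()
        if total <= 0:
            raise ValueError(f"no shell is ionisable at Ep={ep} eV")
        return p / total

    def sample_secondary(self, ep: float, rng: np.random.Generator,
                         size: int | None = None):
        """Sample (shell index, ejected energy E' [eV]); vectorised if ``size``."""
        scalar = size is None
        m = 1 if scalar else size
        probs = self.shell_probs(ep)
        idx = rng.choice(probs.size, size=m, p=probs)
        u = rng.random(m)
        j, t = self._bracket(ep)
        e_out = np.empty(m)
        for i in np.unique(idx):
            sel = idx == i
            lo = np.interp(u[sel], self.q_levels, self.log_e_quant[i, j])
            hi = np.interp(u[sel], self.q_levels, self.log_e_quant[i, j + 1])
            e_out[sel] = 10.0 ** ((1.0 - t) * lo + t * hi)
        if scalar:
            return int(idx[0]), float(e_out[0])
        return idx, e_out


_TABLE_CACHE: dict[int, CrossSectionTable] = {}


def get_table(material: Material, **kwargs) -> CrossSectionTable:
    """Build (and memoize) the cross-section table for a material."""
    key = id(material)
    tab = _TABLE_CACHE.get(key)
    if tab is None or tab.material is not material:
        tab = CrossSectionTable.build(material, **kwargs)
        _TABLE_CACHE[key] = tab
    return tab


def sample_secondary(material: Material, ep: float, rng: np.random.Generator):
    """Sample (shell index, E') for one ionisation; shell chosen with
    probability proportional to its weighted cross section."""
    return get_table(material).sample_secondary(ep, rng)
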