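"""Time evolution and structural relaxation of chromatin conformations.

Langevin dynamics is integrated in the overdamped (Brownian) limit with an
Euler-Maruyama step,

    x_{t+dt} = x_t + (dt/gamma) F(x_t) + sqrt(2 kT dt / gamma) xi,

which is adequate for the diffusive phenomenology the virtual Hi-C protocol
probes. Beads crosslinked to the nuclear matrix are masked out of the
position update but still exert forces on mobile beads. Energy minimisation
uses FIRE (fast inertial relaxation engine) with the standard published
parameter set, augmented with an energy-backtracking acceptance test so the
sequence of accepted iterates is monotone non-increasing in energy.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import _kernels
from .model import (Conformation, FeneDomainError, ModelParams, ParameterError,
                    Topology, as_positions, compute_forces)


@dataclass
class IntegratorSettings:
    """Langevin integration parameters, in reduced units.

    dt       timestep, tau
    gamma    friction per bead
    kT       thermal energy (equals epsilon = 1 at the model temperature)
    seed     RNG seed (used when no explicit generator is supplied)
    n_steps  default step count for run_trajectory
    """

    dt: float = 1e-4
    gamma: float = 1.0
    kT: float = 1.0
    seed: int | None = None
    n_steps: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.gamma <= 0 or self.kT < 0:
            raise ParameterError("require dt > 0, gamma > 0, kT >= 0")

    def asdict(self) -> dict:
        return asdict(self)


def _frozen_mask(frozen, n: int) -> np.ndarray:
    if frozen is None:
        return np.zeros(n, dtype=bool)
    frozen = np.asarray(frozen, dtype=bool)
    if frozen.shape != (n,):
        raise ParameterError("frozen mask length must equal n_beads")
    return frozen


class LangevinEngine:
    """Stateful integrator holding positions and the Verlet pair list.

    The pair list uses a 0.9 sigma skin and is rebuilt whenever any bead has
    moved more than half the skin since the last build; the pair set within
    the interaction cutoff is exact regardless of the skin, which only
    trades list size against rebuild frequency.
    """

    SKIN = 0.9

    def __init__(self, conf, topo: Topology, params: ModelParams | None = None,
                 settings: IntegratorSettings | None = None, frozen=None, *,
                 labels=None, attraction: float = 0.0,
                 attraction_cutoff: float = 1.8,
                 confinement_radius: float = 0.0, confinement_k: float = 10.0):
        self.params = params or ModelParams()
        self.settings = settings or IntegratorSettings()
        self.topo = topo
        self.pos = as_positions(conf).copy()
        n = self.pos.shape[0]
        if n != topo.n_beads:
            raise ParameterError("conformation/topology size mismatch")
        self.frozen = _frozen_mask(frozen, n)
        self._mobile = (~self.frozen).astype(np.float64)
        if labels is None:
            labels = np.zeros(n, dtype=np.int64)
        self._labels = np.ascontiguousarray(labels, dtype=np.int64)
        self._attraction = float(attraction)
        self._attr_cut = float(attraction_cutoff)
        self._conf_r = float(confinement_radius)
        self._conf_k = float(confinement_k)
        rmax = max(self.params.lj_cutoff,
                   self._attr_cut if attraction > 0 else 0.0)
        self._rlist = rmax + self.SKIN
        self._move2 = (self.SKIN / 2.0) ** 2
        self._pi, self._pj = _kernels.neighbor_pairs(self.pos, self._rlist)
        self._pos0 = self.pos.copy()
        self.step_count = 0

    #: largest noise block drawn at once (keeps memory flat for long runs)
    MAX_CHUNK = 2000

    def advance(self, n_steps: int, rng: np.random.Generator) -> None:
        """Advance n_steps Langevin steps in place."""
        s = self.settings
        n = self.pos.shape[0]
        p = self.params
        nscale = np.sqrt(2.0 * s.kT * s.dt / s.gamma) if s.kT > 0 else 0.0
        left = n_steps
        while left > 0:
            block = min(left, self.MAX_CHUNK)
            if s.kT > 0:
                noise = rng.standard_normal((block, n, 3))
            else:
                noise = np.zeros((block, n, 3))
            out = _kernels.langevin_chunk(
                self.pos, self._mobile, noise, s.dt / s.gamma, nscale,
                self._rlist, self._move2, self._pos0, self._pi, self._pj,
                self.topo.bond_mask, self.topo.angle_mask, self._labels,
                p.kb, p.R0, p.Rshift, p.lj_cutoff, p.ka, p.theta0,
                p.energy_shifted_lj, p.exclude_bonded_lj,
                self._attraction, self._attr_cut, self._conf_r, self._conf_k)
            self._pi, self._pj, self._pos0, bad, done = out
            self.step_count += int(done)
            left -= block
            if bad >= 0:
                raise FeneDomainError(
                    f"bond {bad} exceeded its finite-extension limit after "
                    f"{self.step_count} steps; reduce dt", bond_index=int(bad))


def langevin_step(conf, topo: Topology, params: ModelParams | None = None,
                  settings: IntegratorSettings | None = None, frozen=None,
                  rng: np.random.Generator | None = None) -> Conformation:
    """One overdamped Langevin step; frozen beads are returned bit-identical."""
    settings = settings or IntegratorSettings()
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    eng = LangevinEngine(conf, topo, params, settings, frozen)
    eng.advance(1, rng)
    return Conformation(eng.pos)


def run_trajectory(conf, topo: Topology, params: ModelParams | None = None,
                   settings: IntegratorSettings | None = None, frozen=None,
                   observers=(), observe_every: int = 100,
                   rng: np.random.Generator | None = None,
                   n_steps: int | None = None) -> Conformation:
    """Evolve a conformation, invoking observers every observe_every steps.

    Observers are callables ``obs(step, positions)`` (positions is a copy);
    they are also invoked at step 0 and at the final step. Deterministic
    given the seed/generator.
    """
    settings = settings or IntegratorSettings()
    if n_steps is None:
        n_steps = settings.n_steps
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    if observe_every <= 0:
        raise ParameterError("observe_every must be positive")
    eng = LangevinEngine(conf, topo, params, settings, frozen)
    for obs in observers:
        obs(0, eng.pos.copy())
    done = 0
    while done < n_steps:
        chunk = min(observe_every, n_steps - done)
        eng.advance(chunk, rng)
        done += chunk
        for obs in observers:
            obs(done, eng.pos.copy())
    return Conformation(eng.pos)


@dataclass
class MinimizeResult:
    """Outcome of FIRE relaxation."""

    conformation: Conformation
    energy: float
    max_force: float
    n_iter: int
    converged: bool


def fire_minimize(conf, topo: Topology, params: ModelParams | None = None,
                  ftol: float = 1e-2, max_iter: int = 5000, frozen=None,
                  dt_start: float = 0.01, **force_kwargs) -> MinimizeResult:
    """Relax a conformation with FIRE until max per-bead |F| <= ftol.

    Standard scheme (alpha0 = 0.1, f_inc = 1.1, f_dec = 0.5, N_min = 5,
    dt_max = 10 dt_start) with semi-implicit Euler and velocity mixing.
    Steps that would raise the energy or break the FENE domain are rejected
    (velocity reset, dt halved), so accepted iterates never increase energy.
    Non-convergence within max_iter is reported, not fatal.
    """
    pos = as_positions(conf).copy()
    n = pos.shape[0]
    mobile = (~_frozen_mask(frozen, n)).astype(float)[:, None]

    f, e = compute_forces(pos, topo, params, **force_kwargs)
    f = f * mobile
    v = np.zeros_like(pos)
    dt = dt_start
    dt_max = 10.0 * dt_start
    alpha = 0.1
    n_pos = 0
    it = 0
    fmax = float(np.sqrt((f ** 2).sum(axis=1)).max()) if n else 0.0
    while fmax > ftol and it < max_iter:
        it += 1
        power = float((f * v).sum())
        if power > 0.0:
            n_pos += 1
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            v[:] = 0.0
            dt *= 0.5
            alpha = 0.1
            n_pos = 0
        v += dt * f
        vnorm = float(np.sqrt((v ** 2).sum()))
        fnorm = float(np.sqrt((f ** 2).sum()))
        if fnorm > 0:
            v = (1.0 - alpha) * v + alpha * (vnorm / fnorm) * f
        trial = pos + dt * v * mobile
        try:
            f_new, e_new = compute_forces(trial, topo, params, **force_kwargs)
        except FeneDomainError:
            v[:] = 0.0
            dt *= 0.5
            n_pos = 0
            continue
        if e_new > e + 1e-12:
            v[:] = 0.0
            dt *= 0.5
            n_pos = 0
            continue
        pos, f, e = trial, f_new * mobile, e_new
        fmax = float(np.sqrt((f ** 2).sum(axis=1)).max())
    return MinimizeResult(Conformation(pos), e, fmax, it, fmax <= ftol)
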