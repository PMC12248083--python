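"""The virtual Hi-C experiment: crosslink, digest, evolve, ligate.

The protocol mirrors the bench assay on a single chromatin fibre:

1. a random subset of nucleosomes is crosslinked to the nuclear protein
   matrix and thereby fixed in place (the matrix is rigid);
2. a random subset of linker bonds is enzymatically cleaved, partitioning
   the chain into fragments whose ends are free to ligate;
3. the structure evolves under Langevin dynamics; every ``check_interval``
   steps, each unordered pair of active free ends within the capture radius
   ligates with probability p * dt_check (p in units of p0 = 1/tau);
4. a ligation deactivates both ends permanently and is recorded, together
   with the pair's Euclidean separation in the native structure, as one
   entry of the ligation map.

Ligated ends are recorded but no new mechanical bond is created: the map,
not the mechanics, is the readout of interest.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from .dynamics import IntegratorSettings, LangevinEngine
from .model import (ModelParams, ParameterError, Topology, as_positions)


@dataclass
class ProtocolParams:
    """Virtual Hi-C protocol parameters.

    n_crosslinks        nucleosomes fixed to the matrix
    n_cuts              linker bonds cleaved
    ligation_rate       p, in units of p0 = 1/tau
    capture_radius      maximum end-end separation for a ligation attempt,
                        sigma (1.5 sigma = 15 nm)
    check_interval      integration steps between ligation sweeps
    duration            total integration steps
    seed                protocol RNG seed
    ligatable_termini   treat the two original chain termini as free ends
    exact_waiting_times draw per-sweep ligation success as 1 - exp(-p dt)
                        instead of p dt (identical for p dt << 1)
    """

    n_crosslinks: int = 0
    n_cuts: int = 0
    ligation_rate: float = 1e-2
    capture_radius: float = 1.5
    check_interval: int = 10
    duration: int = 1_000_000
    seed: int | None = None
    ligatable_termini: bool = False
    exact_waiting_times: bool = False

    def __post_init__(self):
        if self.n_crosslinks < 0 or self.n_cuts < 0:
            raise ParameterError("counts must be non-negative")
        if self.ligation_rate < 0:
            raise ParameterError("ligation_rate must be >= 0")
        if self.capture_radius <= 0:
            raise ParameterError("capture_radius must be positive")
        if self.check_interval < 1 or self.duration < 0:
            raise ParameterError("invalid check_interval/duration")

    def asdict(self) -> dict:
        return asdict(self)


@dataclass
class FreeEnd:
    """A ligatable fragment end; deactivates permanently upon ligation."""

    bead: int
    fragment: int
    side: str  # 'left' | 'right'
    active: bool = True


@dataclass
class FragmentSet:
    """Partition of the chain into maximal uncut runs of beads."""

    slices: list  # list of (start, stop) half-open bead ranges

    @property
    def n_fragments(self) -> int:
        return len(self.slices)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([stop - start for start, stop in self.slices])


@dataclass
class LigationEvent:
    """One recorded proximity ligation between two fragment-end beads."""

    bead_a: int
    bead_b: int
    time: int        # integration step at which the ligation fired
    end_a: int = -1  # indices into the experiment's free-end list
    end_b: int = -1


def select_crosslinks(n_beads: int, n_crosslinks: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Uniformly choose nucleosomes to freeze; returns a boolean mask."""
    if not (0 <= n_crosslinks <= n_beads):
        raise ParameterError("n_crosslinks must lie in [0, n_beads]")
    mask = np.zeros(n_beads, dtype=bool)
    if n_crosslinks:
        mask[rng.choice(n_beads, size=n_crosslinks, replace=False)] = True
    return mask


def digest(topo: Topology, n_cuts: int, rng: np.random.Generator,
           ligatable_termini: bool = False):
    """Cleave n_cuts bonds uniformly at random.

    Returns (new_topology, fragments, free_ends). On a linear chain the
    fragment count is n_cuts + 1. Each cut produces two free ends; the
    original chain termini are ends only if ligatable_termini is set.
    """
    present = np.flatnonzero(topo.bond_mask)
    if not (0 <= n_cuts <= present.size):
        raise ParameterError("n_cuts must lie in [0, n_bonds]")
    cut_idx = np.sort(rng.choice(present, size=n_cuts, replace=False)) \
        if n_cuts else np.empty(0, dtype=int)
    new_topo = topo.cut(cut_idx)

    # fragments: maximal runs of beads not separated by an absent bond
    slices = []
    start = 0
    for i in range(topo.n_beads - 1):
        if not new_topo.bond_mask[i]:
            slices.append((start, i + 1))
            start = i + 1
    slices.append((start, topo.n_beads))
    fragments = FragmentSet(slices)

    ends: list[FreeEnd] = []
    for fid, (lo, hi) in enumerate(slices):
        left_is_terminus = lo == 0
        right_is_terminus = hi == topo.n_beads
        if ligatable_termini or not left_is_terminus:
            ends.append(FreeEnd(bead=lo, fragment=fid, side="left"))
        if ligatable_termini or not right_is_terminus:
            ends.append(FreeEnd(bead=hi - 1, fragment=fid, side="right"))
    return new_topo, fragments, ends


def _sweep_probability(proto: ProtocolParams, dt: float) -> float:
    """Per-sweep firing probability for one candidate end pair."""
    lam = proto.ligation_rate * proto.check_interval * dt
    if proto.exact_waiting_times:
        return 1.0 - np.exp(-lam)
    return min(1.0, lam)


def attempt_ligations(conf, free_ends: list, proto: ProtocolParams, dt: float,
                      rng: np.random.Generator, step: int = 0):
    """One ligation sweep over the active free ends of a conformation.

    Each unordered pair of distinct active ends within the capture radius
    fires with probability min(1, p * check_interval * dt). Candidate pairs
    are processed in random order; the first success claims both ends.
    Fired ends are deactivated in place; new events are returned.
    """
    pos = as_positions(conf)
    end_beads = np.array([e.bead for e in free_ends], dtype=np.int64)
    active = np.array([e.active for e in free_ends], dtype=bool)
    q = _sweep_probability(proto, dt)
    events = _sweep(pos, end_beads, active, q, proto.capture_radius, rng, step)
    for ev in events:
        free_ends[ev.end_a].active = False
        free_ends[ev.end_b].active = False
    return events


def _sweep(pos, end_beads, active, q, capture_radius, rng, step):
    """Shared sweep core operating on arrays; mutates ``active``."""
    if q <= 0.0 or not active.any():
        return []
    ca, cb = _kernels.end_candidate_pairs(pos, end_beads, active,
                                          capture_radius)
    if ca.size == 0:
        return []
    events = []
    order = rng.permutation(ca.size)
    draws = rng.random(ca.size)
    for k in order:
        a, b = int(ca[k]), int(cb[k])
        if not (active[a] and active[b]):
            continue
        if draws[k] < q:
            active[a] = False
            active[b] = False
            events.append(LigationEvent(int(end_beads[a]), int(end_beads[b]),
                                        step, a, b))
    return events


@dataclass
class ExperimentResult:
    """Everything one protocol run records.

    ``end_native_positions`` snapshots the free-end beads' coordinates in
    the native (pre-evolution) structure; together with the per-event end
    indices it supports the ligation-frequency-versus-Euclidean-distance
    analysis without rerunning dynamics.
    """

    events: list
    end_beads: np.ndarray
    end_native_positions: np.ndarray
    n_beads: int
    frozen: np.ndarray
    fragments: FragmentSet
    free_ends: list
    proto: ProtocolParams
    sweeps_run: int

    def event_array(self) -> np.ndarray:
        """(m, 2) bead-index pairs of all recorded ligations."""
        if not self.events:
            return np.empty((0, 2), dtype=int)
        return np.array([[e.bead_a, e.bead_b] for e in self.events], dtype=int)

    def event_end_array(self) -> np.ndarray:
        """(m, 2) free-end-index pairs of all recorded ligations."""
        if not self.events:
            return np.empty((0, 2), dtype=int)
        return np.array([[e.end_a, e.end_b] for e in self.events], dtype=int)


def run_experiment(native, topo: Topology, params: ModelParams | None = None,
                   proto: ProtocolParams | None = None,
                   settings: IntegratorSettings | None = None,
                   rng: np.random.Generator | None = None) -> ExperimentResult:
    """Run one virtual Hi-C experiment on a native conformation.

    Steps: crosslink selection, digestion, then time evolution with a
    ligation sweep every check_interval steps. Deterministic given the seed.

    When every bead is crosslinked the geometry is static, so the sweep
    process is sampled exactly without integrating: each static candidate
    pair's first-success sweep is geometric with the per-sweep probability,
    and simultaneous conflicts are resolved in random order, the same law
    as the step-by-step simulation.
    """
    params = params or ModelParams()
    proto = proto or ProtocolParams()
    settings = settings or IntegratorSettings()
    if rng is None:
        rng = np.random.default_rng(proto.seed)
    pos = as_positions(native)
    n = pos.shape[0]

    frozen = select_crosslinks(n, proto.n_crosslinks, rng)
    cut_topo, fragments, free_ends = digest(topo, proto.n_cuts, rng,
                                            proto.ligatable_termini)
    end_beads = np.array([e.bead for e in free_ends], dtype=np.int64)
    native_end_pos = pos[end_beads].copy() if end_beads.size \
        else np.empty((0, 3))
    active = np.ones(end_beads.size, dtype=bool)
    q = _sweep_probability(proto, settings.dt)
    n_sweeps = proto.duration // proto.check_interval
    events: list[LigationEvent] = []

    if frozen.all():
        events = _run_static(pos, end_beads, active, q, proto, rng, n_sweeps)
    elif end_beads.size and n_sweeps:
        engine = LangevinEngine(pos, cut_topo, params, settings, frozen)
        for sweep in range(1, n_sweeps + 1):
            engine.advance(proto.check_interval, rng)
            step = sweep * proto.check_interval
            events.extend(_sweep(engine.pos, end_beads, active, q,
                                 proto.capture_radius, rng, step))
            if not active.any():
                break
    for ev in events:
        free_ends[ev.end_a].active = False
        free_ends[ev.end_b].active = False
    return ExperimentResult(events, end_beads, native_end_pos, n, frozen,
                            fragments, free_ends, proto, n_sweeps)


def _run_static(pos, end_beads, active, q, proto, rng, n_sweeps):
    """Exact sweep sampling for fully arrested (all-crosslinked) structures."""
    if q <= 0.0 or n_sweeps == 0 or end_beads.size == 0:
        return []
    ca, cb = _kernels.end_candidate_pairs(pos, end_beads, active,
                                          proto.capture_radius)
    if ca.size == 0:
        return []
    first = rng.geometric(q, size=ca.size)  # sweep index of first success
    tie = rng.random(ca.size)
    order = np.lexsort((tie, first))
    events = []
    for k in order:
        if first[k] > n_sweeps:
            break
        a, b = int(ca[k]), int(cb[k])
        if not (active[a] and active[b]):
            continue
        active[a] = False
        active[b] = False
        step = int(first[k]) * proto.check_interval
        events.append(LigationEvent(int(end_beads[a]), int(end_beads[b]),
                                    step, a, b))
    return events


def run_ensemble(natives, topo: Topology, params: ModelParams | None = None,
                 proto: ProtocolParams | None = None,
                 settings: IntegratorSettings | None = None,
                 n_repeats: int = 1, seed: int | None = None):
    """Run the protocol over an ensemble and/or repeats of one structure.

    ``natives`` is a sequence of conformations (ensemble mode) or a single
    conformation repeated (single-structure scHi-C mode uses n_repeats > 1);
    both modes share this one code path. Each run gets an independent child
    seed spawned from ``seed`` (or proto.seed). Per-run event lists are
    preserved in the returned list of ExperimentResult.
    """
    proto = proto or ProtocolParams()
    if seed is None:
        seed = proto.seed
    natives = list(natives)
    if not natives:
        raise ParameterError("need at least one native structure")
    children = np.random.SeedSequence(seed).spawn(len(natives) * n_repeats)
    results = []
    k = 0
    for structure in natives:
        for _ in range(n_repeats):
            rng = np.random.default_rng(children[k])
            k += 1
            results.append(run_experiment(structure, topo, params, proto,
                                          settings, rng=rng))
    return results
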