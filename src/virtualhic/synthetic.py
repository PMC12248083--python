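"""Synthetic native chromatin ensembles with A/B compartments.

The virtual Hi-C protocol needs an ensemble of native conformations whose
maps carry the checkerboard compartment signal of real chromatin. These
are produced from first principles: a confined random walk at the FENE
bond length, annealed under the chromatin Hamiltonian plus a short-range
attraction between like-labelled (same-compartment) beads so that A and B
blocks phase-separate, then relaxed with FIRE under the plain homopolymer
Hamiltonian into an energetically optimised state, which is the form the
protocol consumes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import IntegratorSettings, LangevinEngine, fire_minimize
from .model import Conformation, ModelParams, ParameterError, Topology


@dataclass
class CompartmentTrack:
    """Per-bead A/B compartment labels (0 = A, 1 = B) in contiguous blocks."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ParameterError("labels must be one-dimensional")

    @classmethod
    def blocks(cls, n_beads: int, n_blocks: int = 5) -> "CompartmentTrack":
        """Alternating A/B blocks of (near-)equal size."""
        if n_blocks < 1:
            raise ParameterError("need at least one block")
        edges = np.linspace(0, n_beads, n_blocks + 1).astype(int)
        labels = np.zeros(n_beads, dtype=np.int64)
        for b in range(n_blocks):
            labels[edges[b]:edges[b + 1]] = b % 2
        return cls(labels)

    @property
    def n_beads(self) -> int:
        return self.labels.size

    @property
    def signed(self) -> np.ndarray:
        """+1 for A, -1 for B; the reference track for FPC sign fixing."""
        return np.where(self.labels == 0, 1.0, -1.0)


def confinement_radius_for_density(n_beads: int, density: float = 0.25) -> float:
    """Sphere radius (sigma) holding n_beads at the given beads/sigma^3."""
    return (3.0 * n_beads / (4.0 * np.pi * density)) ** (1.0 / 3.0)


def generate_initial_walk(n_beads: int, bond_length: float = 1.3,
                          confinement_radius: float | None = None,
                          rng: np.random.Generator | None = None,
                          min_separation: float = 0.9,
                          max_tries: int = 60) -> Conformation:
    """Self-avoiding-ish fixed-bond-length walk inside a sphere.

    Steps that leave the sphere or come within ``min_separation`` of an
    earlier bead are rejected (up to max_tries, after which the least-bad
    candidate is accepted so dense walks still terminate). The density must
    stay below 0.3 beads/sigma^3 for packing to be feasible.
    """
    rng = rng or np.random.default_rng()
    if confinement_radius is None:
        confinement_radius = confinement_radius_for_density(n_beads)
    density = n_beads / (4.0 / 3.0 * np.pi * confinement_radius ** 3)
    if density >= 0.3:
        raise ParameterError(
            f"packing infeasible: density {density:.3f} beads/sigma^3 >= 0.3")
    pos = np.empty((n_beads, 3))
    pos[0] = rng.normal(size=3)
    pos[0] *= (0.3 * confinement_radius * rng.random() ** (1 / 3)
               / np.linalg.norm(pos[0]))
    for i in range(1, n_beads):
        best, best_score = None, -np.inf
        for _ in range(max_tries):
            step = rng.normal(size=3)
            step *= bond_length / np.linalg.norm(step)
            cand = pos[i - 1] + step
            if np.linalg.norm(cand) >= confinement_radius:
                continue
            dmin = np.min(np.linalg.norm(pos[:i] - cand, axis=1))
            if dmin > min_separation:
                best = cand
                break
            if dmin > best_score:
                best, best_score = cand, dmin
        if best is None:  # every try left the sphere: step back inward
            best = pos[i - 1] * (1.0 - bond_length
                                 / max(np.linalg.norm(pos[i - 1]), 1e-9))
        pos[i] = best
    return Conformation(pos)


def anneal_block_copolymer(conf, track: CompartmentTrack,
                           attraction: float = 0.5, n_steps: int = 20000,
                           rng: np.random.Generator | None = None,
                           params: ModelParams | None = None,
                           settings: IntegratorSettings | None = None,
                           attraction_cutoff: float = 1.8,
                           confinement_radius: float | None = None) -> Conformation:
    """Langevin-anneal a chain with a like-compartment attractive well.

    The attraction (a cut-and-shifted Lennard-Jones well of range
    ``attraction_cutoff`` sigma and depth ``attraction`` epsilon between
    same-label beads) drives A/B phase separation; the optional spherical
    wall maintains nuclear density during annealing. attraction = 0 is the
    null homopolymer case.
    """
    if attraction < 0:
        raise ParameterError("attraction must be >= 0")
    rng = rng or np.random.default_rng()
    settings = settings or IntegratorSettings()
    topo = Topology.linear(track.n_beads)
    if confinement_radius is None:
        confinement_radius = confinement_radius_for_density(track.n_beads)
    eng = LangevinEngine(conf, topo, params, settings,
                         labels=track.labels, attraction=attraction,
                         attraction_cutoff=attraction_cutoff,
                         confinement_radius=confinement_radius)
    chunk = 1000
    done = 0
    while done < n_steps:
        step = min(chunk, n_steps - done)
        eng.advance(step, rng)
        done += step
    return Conformation(eng.pos)


def generate_native_ensemble(n_structures: int, n_beads: int,
                             track: CompartmentTrack | None = None,
                             seed: int | None = None,
                             attraction: float = 0.5,
                             anneal_steps: int = 20000,
                             fire_ftol: float = 0.1,
                             fire_max_iter: int = 2000,
                             params: ModelParams | None = None,
                             settings: IntegratorSettings | None = None):
    """Independent annealed + FIRE-relaxed native structures.

    Returns (conformations, track, metadata). Each structure grows from an
    independent child seed and is FIRE-relaxed under the generator's own
    Hamiltonian — homopolymer terms plus the like-compartment attraction,
    inside the annealing confinement sphere. Relaxing without those two
    generator terms would let the bending term straighten and inflate the
    coil (its minimum is a rod), erasing every non-bonded contact; with
    them, the relaxed states stay compact and compartmentalised, which is
    what a native chromatin snapshot looks like to the protocol.
    """
    if n_structures < 1:
        raise ParameterError("need at least one structure")
    track = track or CompartmentTrack.blocks(n_beads)
    if track.n_beads != n_beads:
        raise ParameterError("track length must equal n_beads")
    params = params or ModelParams()
    topo = Topology.linear(n_beads)
    children = np.random.SeedSequence(seed).spawn(n_structures)
    radius = confinement_radius_for_density(n_beads)
    confs = []
    for child in children:
        rng = np.random.default_rng(child)
        walk = generate_initial_walk(n_beads, confinement_radius=radius,
                                     rng=rng)
        # short overlap-relief minimisation: a dense walk can start with
        # hard-core overlaps whose forces would destabilise the first
        # Langevin steps
        eased = fire_minimize(walk, topo, params, ftol=20.0, max_iter=300,
                              confinement_radius=radius).conformation
        annealed = anneal_block_copolymer(eased, track, attraction,
                                          anneal_steps, rng, params, settings,
                                          confinement_radius=radius)
        relaxed = fire_minimize(annealed, topo, params, ftol=fire_ftol,
                                max_iter=fire_max_iter,
                                labels=track.labels, attraction=attraction,
                                confinement_radius=radius)
        confs.append(relaxed.conformation)
    meta = {"n_structures": n_structures, "n_beads": n_beads, "seed": seed,
            "attraction": attraction, "anneal_steps": anneal_steps,
            "fire_ftol": fire_ftol}
    return confs, track, meta
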