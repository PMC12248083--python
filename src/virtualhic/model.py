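"""Nucleosome-resolution bead-spring chromatin model.

One bead represents a nucleosome and its linker (~200 bp: ~150 bp wrapped
plus ~50 bp linker DNA). The homopolymer Hamiltonian is

    U = sum_bonds U_FENE(r) + sum_pairs U_hc(r) + sum_angles U_angle(theta)

with shifted finitely-extensible (FENE) bonds, truncated Lennard-Jones
(WCA) excluded volume acting between all bead pairs, and harmonic bending
terms. Reduced units throughout: sigma = 1 (10 nm), epsilon = k_B T = 1;
times are measured in the Langevin unit tau (2.2678 us in physical units,
a calibration constant carried only as metadata).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels

#: physical length of the reduced unit sigma
SIGMA_NM = 10.0
#: genomic content of one bead
BP_PER_BEAD = 200
#: physical duration of the reduced time unit tau, in microseconds (metadata)
TAU_US = 2.2678


class ParameterError(ValueError):
    """Invalid model or protocol parameter."""


class FeneDomainError(ValueError):
    """A bonded pair reached the finite-extension limit r >= Rshift + R0.

    During time integration this signals integrator instability: reduce dt.
    """

    def __init__(self, message: str, bond_index: int | None = None):
        super().__init__(message)
        self.bond_index = bond_index


@dataclass
class ModelParams:
    """Parameters of the chromatin Hamiltonian, in reduced units.

    sigma_nm          physical size of sigma, nm (metadata only)
    epsilon           energy unit, equals k_B T (1 in reduced units)
    kb                FENE stiffness, epsilon/sigma^2
    R0                FENE extensibility range, sigma
    Rshift            FENE shift: the bond energy is zero below Rshift and
                      diverges at Rshift + R0
    lj_cutoff         excluded-volume cutoff, 2^(1/6) sigma (WCA)
    ka                angle stiffness, epsilon
    theta0            rest angle, radians (pi: straight chain)
    energy_shifted_lj add +epsilon to the truncated LJ so the energy is
                      continuous at the cutoff; forces are identical either
                      way, so dynamics do not depend on this flag
    exclude_bonded_lj drop the excluded-volume term for directly bonded
                      pairs (off by default; the FENE rest range plus WCA
                      makes including them benign)
    """

    sigma_nm: float = SIGMA_NM
    epsilon: float = 1.0
    kb: float = 30.0
    R0: float = 1.5
    Rshift: float = 1.5
    lj_cutoff: float = 2.0 ** (1.0 / 6.0)
    ka: float = 4.0
    theta0: float = math.pi
    energy_shifted_lj: bool = True
    exclude_bonded_lj: bool = False

    def __post_init__(self):
        if self.kb <= 0 or self.ka <= 0 or self.epsilon <= 0:
            raise ParameterError("stiffnesses and epsilon must be positive")
        if not (0 < self.Rshift and self.R0 > 0):
            raise ParameterError("require 0 < Rshift and R0 > 0")
        if self.lj_cutoff <= 0:
            raise ParameterError("lj_cutoff must be positive")
        if not (0 < self.theta0 <= math.pi):
            raise ParameterError("theta0 must lie in (0, pi]")

    @property
    def r_max(self) -> float:
        """Finite-extension limit of a bond."""
        return self.Rshift + self.R0

    def asdict(self) -> dict:
        return asdict(self)


@dataclass
class Topology:
    """Chain connectivity: which consecutive-bead bonds are present.

    ``bond_mask[i]`` is the bond between beads i and i+1. An angle centred
    on bead i exists iff both flanking bonds are present, so digestion
    automatically removes angle triples that span a cleaved bond.
    """

    n_beads: int
    bond_mask: np.ndarray

    def __post_init__(self):
        self.bond_mask = np.asarray(self.bond_mask, dtype=bool)
        if self.n_beads < 1:
            raise ParameterError("need at least one bead")
        if self.bond_mask.shape != (max(self.n_beads - 1, 0),):
            raise ParameterError("bond_mask must have length n_beads - 1")

    @classmethod
    def linear(cls, n_beads: int) -> "Topology":
        """Unbroken linear chain of n_beads nucleosomes."""
        return cls(n_beads, np.ones(max(n_beads - 1, 0), dtype=bool))

    @property
    def n_bonds(self) -> int:
        return int(self.bond_mask.sum())

    @property
    def bonds(self) -> np.ndarray:
        """(m, 2) array of bonded bead index pairs (i, i+1)."""
        i = np.flatnonzero(self.bond_mask)
        return np.column_stack([i, i + 1])

    @property
    def angle_mask(self) -> np.ndarray:
        m = np.zeros(self.n_beads, dtype=bool)
        if self.n_beads >= 3:
            m[1:-1] = self.bond_mask[:-1] & self.bond_mask[1:]
        return m

    @property
    def angles(self) -> np.ndarray:
        """(k, 3) array of angle triples (i-1, i, i+1)."""
        i = np.flatnonzero(self.angle_mask)
        return np.column_stack([i - 1, i, i + 1])

    def cut(self, bond_indices) -> "Topology":
        """New topology with the given bonds (by left-bead index) removed."""
        idx = np.asarray(bond_indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_beads - 1):
            raise ParameterError("bond index out of range")
        if not self.bond_mask[idx].all():
            raise ParameterError("cannot cut an already absent bond")
        mask = self.bond_mask.copy()
        mask[idx] = False
        return Topology(self.n_beads, mask)


@dataclass
class Conformation:
    """3D bead coordinates in sigma units."""

    positions: np.ndarray

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ParameterError("positions must have shape (n_beads, 3)")
        if not np.isfinite(self.positions).all():
            raise ParameterError("positions must be finite")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]


def as_positions(conf) -> np.ndarray:
    """Accept a Conformation or a bare (n, 3) array; return the array."""
    if isinstance(conf, Conformation):
        return conf.positions
    pos = np.ascontiguousarray(conf, dtype=np.float64)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ParameterError("positions must have shape (n_beads, 3)")
    return pos


def fene_energy(r, params: ModelParams | None = None):
    """Shifted FENE bond energy at separation r (sigma units).

    Zero below Rshift per the piecewise definition; raises FeneDomainError
    at or beyond the finite-extension limit Rshift + R0.
    """
    params = params or ModelParams()
    arr = np.asarray(r, dtype=float)
    if np.any(arr < 0):
        raise ParameterError("bond length must be non-negative")
    if np.any(arr >= params.r_max):
        raise FeneDomainError(
            f"bond length reaches finite-extension limit {params.r_max} sigma"
        )
    e = np.zeros_like(arr)
    m = arr > params.Rshift
    u = (arr[m] - params.Rshift) / params.R0
    e[m] = -0.5 * params.kb * params.R0 ** 2 * np.log(1.0 - u * u)
    return float(e) if np.isscalar(r) else e


def hardcore_energy(r, params: ModelParams | None = None):
    """Truncated Lennard-Jones (WCA) excluded-volume energy at separation r.

    4 eps [(sigma/r)^12 - (sigma/r)^6] below the 2^(1/6) sigma cutoff
    (+eps if energy_shifted_lj so the minimum sits at zero), else 0.
    """
    params = params or ModelParams()
    arr = np.asarray(r, dtype=float)
    if np.any(arr <= 0):
        raise ParameterError("pair separation must be positive (r = 0 is singular)")
    e = np.zeros_like(arr)
    m = arr < params.lj_cutoff
    inv6 = (1.0 / arr[m]) ** 6
    e[m] = 4.0 * params.epsilon * (inv6 * inv6 - inv6)
    if params.energy_shifted_lj:
        e[m] += params.epsilon
    return float(e) if np.isscalar(r) else e


def angle_energy(theta, params: ModelParams | None = None):
    """Harmonic bending energy ka/2 (theta - theta0)^2 at interior angle theta."""
    params = params or ModelParams()
    arr = np.asarray(theta, dtype=float)
    if np.any((arr < -1e-12) | (arr > math.pi + 1e-12)):
        raise ParameterError("interior angle must lie in [0, pi]")
    e = 0.5 * params.ka * (arr - params.theta0) ** 2
    return float(e) if np.isscalar(theta) else e


def _kernel_args(params: ModelParams, labels, attraction, attraction_cutoff,
                 confinement_radius, confinement_k):
    return (params.kb, params.R0, params.Rshift, params.lj_cutoff,
            params.ka, params.theta0, params.energy_shifted_lj,
            params.exclude_bonded_lj, float(attraction),
            float(attraction_cutoff), float(confinement_radius),
            float(confinement_k))


def compute_forces(conf, topo: Topology, params: ModelParams | None = None, *,
                   labels: np.ndarray | None = None, attraction: float = 0.0,
                   attraction_cutoff: float = 1.8,
                   confinement_radius: float = 0.0,
                   confinement_k: float = 10.0):
    """Per-bead forces (negative energy gradient) and total energy.

    The nonbonded term is applied to all bead pairs within the cutoff via
    exact pair enumeration. Optional generator terms: a like-label
    attractive LJ well (labels + attraction) and a spherical harmonic wall.

    Returns (forces, energy); raises FeneDomainError naming the offending
    bond if a bond is at or beyond its finite-extension limit.
    """
    params = params or ModelParams()
    pos = as_positions(conf)
    n = pos.shape[0]
    if labels is None:
        labels = np.zeros(n, dtype=np.int64)
    else:
        labels = np.ascontiguousarray(labels, dtype=np.int64)
    rmax = max(params.lj_cutoff, attraction_cutoff if attraction > 0 else 0.0)
    pi, pj = _kernels.neighbor_pairs(pos, rmax)
    f = np.empty_like(pos)
    e, bad = _kernels.forces_energy(
        pos, pi, pj, topo.bond_mask, topo.angle_mask, labels,
        *_kernel_args(params, labels, attraction, attraction_cutoff,
                      confinement_radius, confinement_k), f)
    if bad >= 0:
        raise FeneDomainError(
            f"bond {bad} at or beyond finite-extension limit", bond_index=bad)
    return f, float(e)


def total_energy(conf, topo: Topology, params: ModelParams | None = None,
                 **kwargs) -> float:
    """Total Hamiltonian energy of a conformation."""
    return compute_forces(conf, topo, params, **kwargs)[1]
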