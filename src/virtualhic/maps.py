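"""Distance, contact and ligation matrices over genomic bins.

Bins are half-open, 0-based: bead i maps to bin floor(i * 200 / bin_bp),
matching pairs-format conventions. Distance maps are reported in nm;
contact maps are binary (or frequencies after ensemble averaging) with a
self-contact diagonal of 1; ligation maps count events symmetrically, so
the total mass equals twice the event count (diagonal self-bin events
contribute 2 to the diagonal).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .model import BP_PER_BEAD, SIGMA_NM, ParameterError, as_positions


class DataError(ValueError):
    """Inconsistent map/event data."""


@dataclass
class ContactMatrix:
    """A square symmetric map over genomic bins.

    kind is one of 'distance' (nm), 'contact' (binary or frequency) or
    'ligation' (counts); meta records provenance (aggregation counts,
    thresholds, units).
    """

    data: np.ndarray
    bin_bp: int = BP_PER_BEAD
    kind: str = "contact"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise DataError("map must be square")
        if self.kind not in ("distance", "contact", "ligation"):
            raise DataError(f"unknown map kind {self.kind!r}")

    @property
    def n_bins(self) -> int:
        return self.data.shape[0]

    def bin_starts_bp(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=int) * self.bin_bp


def distance_map(conf) -> ContactMatrix:
    """Euclidean bead-pair distances in nm (sigma coordinates x 10 nm)."""
    pos = as_positions(conf)
    d = squareform(pdist(pos)) * SIGMA_NM
    return ContactMatrix(d, BP_PER_BEAD, "distance", {"units": "nm"})


def contact_map(conf, threshold: float = 1.5) -> ContactMatrix:
    """Binary contacts: 1 iff pair distance <= threshold (sigma units).

    The diagonal (self-contact) is 1. The ensemble convention uses
    threshold = 1.5 sigma; single-structure display maps use 7.5 sigma.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    pos = as_positions(conf)
    d = squareform(pdist(pos))
    m = (d <= threshold).astype(float)
    np.fill_diagonal(m, 1.0)
    return ContactMatrix(m, BP_PER_BEAD, "contact",
                         {"threshold_sigma": threshold})


def ligation_map(events, n_beads: int, bin_bp: int = BP_PER_BEAD) -> ContactMatrix:
    """Accumulate ligation events into a symmetric count matrix.

    ``events`` is an iterable of LigationEvent or (bead_a, bead_b) pairs.
    Each event increments (bin_a, bin_b) and (bin_b, bin_a); a same-bin
    event adds 2 to the diagonal, so the total mass is 2 x event count.
    """
    if bin_bp < 1:
        raise ParameterError("bin_bp must be >= 1")
    n_bins = int(np.ceil(n_beads * BP_PER_BEAD / bin_bp))
    m = np.zeros((n_bins, n_bins))
    for ev in events:
        a, b = (ev.bead_a, ev.bead_b) if hasattr(ev, "bead_a") else ev
        if not (0 <= a < n_beads and 0 <= b < n_beads):
            raise DataError(f"event bead index out of range: ({a}, {b})")
        ia = a * BP_PER_BEAD // bin_bp
        ib = b * BP_PER_BEAD // bin_bp
        m[ia, ib] += 1
        m[ib, ia] += 1
    return ContactMatrix(m, bin_bp, "ligation",
                         {"n_events": int(m.sum() // 2),
                          "diagonal": "self-bin events count 2"})


def aggregate_maps(matrices, how: str | None = None) -> ContactMatrix:
    """Combine same-shaped maps: mean for distance/contact, sum for ligation.

    ``how`` ('mean' | 'sum') overrides the kind-based default; the choice
    and the number aggregated are recorded in metadata.
    """
    matrices = list(matrices)
    if not matrices:
        raise DataError("nothing to aggregate")
    first = matrices[0]
    for m in matrices[1:]:
        if m.data.shape != first.data.shape or m.kind != first.kind:
            raise DataError("aggregation requires identical shapes and kinds")
    if how is None:
        how = "sum" if first.kind == "ligation" else "mean"
    stack = np.stack([m.data for m in matrices])
    data = stack.sum(axis=0) if how == "sum" else stack.mean(axis=0)
    meta = dict(first.meta)
    meta.update({"aggregated": len(matrices), "how": how})
    return ContactMatrix(data, first.bin_bp, first.kind, meta)


def coarse_bin(matrix: ContactMatrix, factor: int) -> ContactMatrix:
    """Re-bin by an integer factor: block-sum counts, block-mean otherwise.

    The trailing partial block is kept (its mean uses the true block area).
    """
    if factor < 1 or int(factor) != factor:
        raise ParameterError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return ContactMatrix(matrix.data.copy(), matrix.bin_bp, matrix.kind,
                             dict(matrix.meta))
    n = matrix.n_bins
    edges = np.arange(0, n, factor)
    sums = np.add.reduceat(np.add.reduceat(matrix.data, edges, axis=0),
                           edges, axis=1)
    if matrix.kind == "ligation":
        data = sums
    else:
        widths = np.diff(np.append(edges, n))
        area = np.outer(widths, widths)
        data = sums / area
    meta = dict(matrix.meta)
    meta["coarse_factor"] = factor
    return ContactMatrix(data, matrix.bin_bp * factor, matrix.kind, meta)
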