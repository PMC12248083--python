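"""Restriction-site position statistics on DNA sequences.

Supports the statistical rationale for modelling enzymatic digestion as
uniform random bond cleavage: on genomic sequence, restriction sites of
common 4- and 6-cutters (MboI GATC, HindIII AAGCTT, NcoI CCATGG) are close
to uniformly distributed, with exponentially distributed inter-site
spacings. The functions here find motif matches (overlapping matches are
counted; N never matches), summarise successive spacings, and test the
exponential/uniform hypotheses with a Kolmogorov-Smirnov fit and a
windowed index of dispersion.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from scipy import stats

from .maps import DataError

_ALPHABET = set("ACGTN")


@dataclass
class SiteList:
    """Match start positions (0-based) of a motif on a sequence."""

    motif: str
    positions: np.ndarray
    seq_length: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.size:
            if (np.any(np.diff(self.positions) < 0)
                    or self.positions.min() < 0
                    or self.positions.max() > self.seq_length - len(self.motif)):
                raise DataError("site positions out of order or range")

    @property
    def n_sites(self) -> int:
        return self.positions.size


def _scan(seq: str, motif: str) -> list[int]:
    """All (overlapping) exact match starts; any N in the window blocks it."""
    out = []
    start = seq.find(motif)
    while start != -1:
        out.append(start)
        start = seq.find(motif, start + 1)
    return out


def find_sites(sequence: str, motif: str, both_strands: bool = False) -> SiteList:
    """Exact motif match positions on a DNA sequence.

    Overlapping matches are kept. With both_strands, matches of the reverse
    complement are reported at their forward-strand start coordinate (a
    no-op for palindromic motifs like GATC or AAGCTT).
    """
    seq = sequence.upper()
    motif = motif.upper()
    if not motif or set(motif) - _ALPHABET or set(seq) - _ALPHABET:
        raise DataError("sequence/motif must be over the alphabet {A,C,G,T,N}")
    if "N" in motif:
        raise DataError("motif must be ungapped and unambiguous")
    positions = _scan(seq, motif)
    rc = str(Seq(motif).reverse_complement())
    if both_strands and rc != motif:
        positions = sorted(set(positions) | set(_scan(seq, rc)))
    return SiteList(motif, np.array(sorted(positions), dtype=np.int64),
                    len(seq), {"both_strands": both_strands,
                               "overlapping_matches": True})


def inter_site_distances(sites: SiteList) -> np.ndarray:
    """Successive differences of match starts, in bp."""
    if sites.n_sites < 2:
        warnings.warn("fewer than 2 sites: no spacings")
        return np.empty(0, dtype=np.int64)
    return np.diff(sites.positions)


@dataclass
class SpacingFit:
    """Maximum-likelihood exponential fit of inter-site spacings."""

    rate: float          # 1/mean spacing, per bp
    mean: float
    ks_statistic: float
    ks_pvalue: float
    n: int
    ok: bool             # enough data for a meaningful fit


def spacing_fit(distances) -> SpacingFit:
    """Fit spacings to an exponential and report the KS goodness of fit.

    The ML rate is 1/mean; the KS distance is computed against the fitted
    exponential. Fewer than 30 spacings sets ok=False.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 30:
        return SpacingFit(np.nan, np.nan, np.nan, np.nan, int(d.size), False)
    mean = float(d.mean())
    ks = stats.kstest(d, "expon", args=(0, mean))
    return SpacingFit(1.0 / mean, mean, float(ks.statistic),
                      float(ks.pvalue), int(d.size), True)


def uniformity_scan(sites: SiteList, window: int):
    """Per-window site counts and their index of dispersion.

    Windows tile [0, seq_length) with the given width (the ragged final
    window is dropped). Dispersion var/mean is ~1 for homogeneous (Poisson)
    site placement, > 1 for clustering.
    """
    if window < 1:
        raise DataError("window must be >= 1 bp")
    n_windows = sites.seq_length // window
    if n_windows < 2:
        raise DataError("sequence shorter than two windows")
    edges = np.arange(n_windows + 1) * window
    counts, _ = np.histogram(sites.positions, bins=edges)
    mean = counts.mean()
    dispersion = float(counts.var(ddof=1) / mean) if mean > 0 else np.nan
    return counts, dispersion


def random_dna(length: int, rng: np.random.Generator,
               gc: float = 0.5) -> str:
    """IID random DNA at the given GC content (synthetic test sequence)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("AGCT"))[rng.choice(4, size=length, p=p)])
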