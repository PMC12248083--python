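"""File formats and configuration plumbing.

Structures travel as (multi-frame) XYZ in sigma units; ligation events as a
pairs-style TSV (readID chrom pos chrom pos strand strand + event time);
maps and curves as TSV with bp labels; compartment tracks and restriction
sites as TSV/BED. Every output carries a comment header with the package
version, the config hash and the seed, and the reduced-unit convention
(sigma = 1 = 10 nm, epsilon = k_B T = 1, tau = 2.2678 us metadata).
"""
from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .maps import ContactMatrix, DataError
from .model import BP_PER_BEAD, SIGMA_NM, TAU_US, Conformation

VERSION = "0.1.0"
UNIT_HEADER = f"sigma=1 (={SIGMA_NM} nm) epsilon=kT=1 tau_us={TAU_US}"


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha1(canon.encode()).hexdigest()[:12]


def header_lines(config: dict | None = None, seed=None) -> list[str]:
    lines = [f"virtualhic v{VERSION}", UNIT_HEADER]
    if config is not None:
        lines.append(f"config_hash={config_hash(config)}")
    if seed is not None:
        lines.append(f"seed={seed}")
    return lines


def derive_seeds(master_seed: int | None, n: int) -> list[int]:
    """n independent child seeds from one master seed (documented scheme:
    numpy SeedSequence spawning, truncated below 2**31)."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


# ---------------------------------------------------------------- XYZ ----

def write_xyz(path, frames, comment: str = "", config: dict | None = None,
              seed=None):
    """Write one conformation or a list of frames as plain XYZ (sigma units)."""
    if isinstance(frames, (Conformation, np.ndarray)):
        frames = [frames]
    head = " | ".join(header_lines(config, seed) + ([comment] if comment else []))
    with open(path, "w") as fh:
        for k, frame in enumerate(frames):
            pos = frame.positions if isinstance(frame, Conformation) else \
                np.asarray(frame, dtype=float)
            fh.write(f"{pos.shape[0]}\n")
            fh.write(f"{head} | frame={k}\n")
            for x, y, z in pos:
                fh.write(f"C {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path) -> list[Conformation]:
    """Read all frames of a plain XYZ file (coordinates in sigma units)."""
    frames = []
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line.strip():
                break
            n = int(line)
            fh.readline()  # comment
            pos = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                pos[i] = [float(v) for v in parts[1:4]]
            frames.append(Conformation(pos))
    if not frames:
        raise DataError(f"no frames in {path}")
    return frames


# -------------------------------------------------------------- pairs ----

PAIRS_COLUMNS = ["readID", "chr1", "pos1", "chr2", "pos2",
                 "strand1", "strand2", "time_step"]


def write_pairs(path, events, chrom: str = "chrS",
                config: dict | None = None, seed=None):
    """Ligation events as a pairs-style TSV; positions are bead * 200 bp."""
    with open(path, "w") as fh:
        for line in header_lines(config, seed):
            fh.write(f"# {line}\n")
        fh.write("# columns: " + " ".join(PAIRS_COLUMNS) + "\n")
        for k, ev in enumerate(events):
            a, b = sorted((ev.bead_a, ev.bead_b))
            fh.write(f"lig{k}\t{chrom}\t{a * BP_PER_BEAD}\t{chrom}\t"
                     f"{b * BP_PER_BEAD}\t+\t+\t{ev.time}\n")


def read_pairs(path) -> pd.DataFrame:
    """Read a pairs TSV back into a DataFrame (positions in bp)."""
    df = pd.read_csv(path, sep="\t", comment="#", names=PAIRS_COLUMNS)
    return df


# --------------------------------------------------------------- maps ----

def write_map(path, matrix: ContactMatrix, config: dict | None = None,
              seed=None):
    """Dense TSV with bp bin-start labels on both axes."""
    labels = matrix.bin_starts_bp()
    df = pd.DataFrame(matrix.data, index=labels, columns=labels)
    with open(path, "w") as fh:
        for line in header_lines(config, seed):
            fh.write(f"# {line}\n")
        fh.write(f"# kind={matrix.kind} bin_bp={matrix.bin_bp}\n")
        df.to_csv(fh, sep="\t")


def read_map(path) -> ContactMatrix:
    kind, bin_bp = "contact", BP_PER_BEAD
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if tok.startswith("kind="):
                    kind = tok.split("=", 1)[1]
                elif tok.startswith("bin_bp="):
                    bin_bp = int(tok.split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return ContactMatrix(df.to_numpy(dtype=float), bin_bp, kind)


def write_triplets(path, matrix: ContactMatrix, config: dict | None = None,
                   seed=None):
    """Sparse upper-triangle triplet export: bin1 bin2 value."""
    i, j = np.nonzero(np.triu(matrix.data))
    with open(path, "w") as fh:
        for line in header_lines(config, seed):
            fh.write(f"# {line}\n")
        fh.write(f"# kind={matrix.kind} bin_bp={matrix.bin_bp}\n")
        for a, b in zip(i, j):
            fh.write(f"{a}\t{b}\t{matrix.data[a, b]:g}\n")


# -------------------------------------------------------------- curves ----

def write_curve(path, curve, config: dict | None = None, seed=None):
    """ScalingCurve as TSV: abscissa, frequency, count (+ fit echo)."""
    with open(path, "w") as fh:
        for line in header_lines(config, seed):
            fh.write(f"# {line}\n")
        fh.write(f"# kind={curve.kind}\n")
        if curve.fit:
            fit = " ".join(f"{k}={v}" for k, v in curve.fit.items())
            fh.write(f"# fit: {fit}\n")
        fh.write("distance\tfrequency\tcount\n")
        for x, y, c in zip(curve.x, curve.y, curve.counts):
            fh.write(f"{x:g}\t{y:g}\t{c:g}\n")


def write_track(path, track, config: dict | None = None, seed=None):
    """Compartment track as TSV: bead, start_bp, label (A/B)."""
    with open(path, "w") as fh:
        for line in header_lines(config, seed):
            fh.write(f"# {line}\n")
        fh.write("bead\tstart_bp\tcompartment\n")
        for i, lab in enumerate(track.labels):
            fh.write(f"{i}\t{i * BP_PER_BEAD}\t{'AB'[int(lab)]}\n")


def read_track_labels(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", comment="#")
    return (df["compartment"].to_numpy() == "B").astype(np.int64)


# ----------------------------------------------------------------- BED ----

def write_bed(path, sites, chrom: str = "chr1"):
    """Restriction sites as BED (0-based, half-open)."""
    L = len(sites.motif)
    with open(path, "w") as fh:
        for p in sites.positions:
            fh.write(f"{chrom}\t{p}\t{p + L}\t{sites.motif}\n")


# -------------------------------------------------------------- config ----

def write_config(path, config: dict, seed=None):
    """Echo the effective run configuration (YAML) with hash and units."""
    doc = {"virtualhic_version": VERSION,
           "units": {"sigma_nm": SIGMA_NM, "epsilon": "k_B T",
                     "tau_us": TAU_US},
           "seed": seed,
           "config": config,
           "config_hash": config_hash(config)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
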