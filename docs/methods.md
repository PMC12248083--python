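# Methods

## Model and units

Chromatin is a linear bead-spring chain at nucleosome resolution: one bead
per 200 bp (~150 bp wrapped plus ~50 bp linker). Reduced units are used
throughout: sigma = 1 is 10 nm, epsilon = k_B T = 1, and the Langevin time
unit tau corresponds to 2.2678 us (a calibration constant carried only as
output metadata; nothing in the code depends on it). The Hamiltonian has
three terms:

- **Shifted FENE bonds** between consecutive beads,
  U = −(k_b R0²/2) ln[1 − ((r − R_shift)/R0)²] for R_shift ≤ r < R_shift+R0
  and 0 below R_shift, with k_b = 30 ε/σ², R0 = R_shift = 1.5 σ. The
  piecewise form is implemented literally: below R_shift a bond feels no
  bond force and overlap is penalised only by excluded volume. At or beyond
  R_shift + R0 the model is undefined; the integrator treats that as an
  instability and aborts with the offending bond index.
- **WCA excluded volume** between *all* bead pairs within 2^{1/6} σ,
  4ε[(σ/r)¹² − (σ/r)⁶]. By default the energy is shifted by +ε so it is
  continuous at the cutoff; the force — hence every trajectory and result —
  is identical with or without the shift (`energy_shifted_lj` flag).
  Bonded neighbours are included in the pair sum by default; the FENE rest
  range keeps this benign (`exclude_bonded_lj` to drop them).
- **Harmonic bending**, (k_a/2)(θ − π)² with k_a = 4 ε, giving a
  persistence length of roughly 4 beads (~40 nm).

Pair interactions are enumerated exactly via a linked-cell Verlet list with
a 0.9 σ skin, rebuilt whenever any bead has moved more than half the skin;
a brute-force enumerator provides the reference pair set in tests. The
force kernels are numba-compiled; analytic forces agree with central-
difference gradients to better than 10⁻⁵ relative.

## Dynamics

Time evolution is overdamped Langevin (Euler–Maruyama):
x ← x + (dt/γ) F + sqrt(2 kT dt/γ) ξ, with dt = 10⁻⁴ τ and γ = 1 by
default. The overdamped limit is appropriate because every observable here
is diffusive/conformational; there is no inertial phenomenology in the
protocol. Beads crosslinked to the nuclear matrix are masked out of the
position update (not given infinite mass), so they stay bit-identical while
still exerting forces on mobile beads.

Energy minimisation uses FIRE with the standard published parameters
(α₀ = 0.1, f_inc = 1.1, f_dec = 0.5, N_min = 5, dt_max = 10 dt₀), plus an
energy-backtracking acceptance test: a step that would raise the energy or
break the FENE domain is rejected, the velocity zeroed and dt halved, so
accepted iterates are monotone non-increasing in energy. Non-convergence
within the iteration cap is reported in the result, not fatal.

## The virtual Hi-C protocol

One experiment on one native structure:

1. **Crosslinking** — `n_crosslinks` beads chosen uniformly at random are
   frozen in place (the matrix is rigid).
2. **Digestion** — `n_cuts` bonds chosen uniformly at random are cleaved;
   angle triples spanning a cut disappear with the bond. Uniform random
   cutting is justified by the restriction-site statistics module (below).
   A fragment between two cuts has a left and a right end even when it is a
   single bead; the two original chain termini are not ligatable unless the
   `ligatable_termini` flag is set.
3. **Evolution with ligation sweeps** — Langevin dynamics for `duration`
   steps; every `check_interval` (default 10) steps, each unordered pair of
   active free ends within the 1.5 σ capture radius fires with probability
   min(1, p · check_interval · dt), p in units of p₀ = 1/τ. Candidate pairs
   are processed in random order and a success permanently deactivates both
   ends (first success claims both). An exact exponential-waiting-time
   variant (1 − e^{−pΔt}) is available behind a flag; the two laws agree
   for pΔt ≪ 1, which holds at all default settings.
4. A ligation is recorded (end indices, bead indices, step) but creates no
   mechanical bond — the map, not the mechanics, is the readout. Ligation
   of the two ends of one cut (self-religation) is geometrically allowed,
   recorded, and can be filtered at analysis time.

Every experiment snapshots the native coordinates of all free ends, so the
ligation-frequency-versus-Euclidean-distance analysis can be computed
afterwards without rerunning dynamics.

**Fully crosslinked fast path.** When every bead is frozen the geometry is
static, so the candidate pair set never changes; the first-success sweep of
each pair is then drawn from the geometric distribution with the per-sweep
probability and conflicts are resolved in time order with random
tie-breaks. This is the same stochastic law as the step-by-step sweep
simulation, evaluated without integrating arrested dynamics.

Ensemble mode (many structures) and single-structure repeat mode (scHi-C
style aggregation) share one code path; every run draws an independent
child seed from one master seed via numpy `SeedSequence` spawning.

## Synthetic native structures

The protocol needs native ensembles whose maps carry compartment structure.
The generator builds them from first principles rather than from any
external model: a fixed-bond-length (1.3 σ), self-avoiding-ish random walk
grown inside a confinement sphere at 0.25 beads/σ³ (packing requires
< 0.3); a brief FIRE pass to relieve walk overlaps; Langevin annealing
(default 20 000 steps) with a cut-and-shifted Lennard-Jones attraction of
depth 0.5 ε and range 1.8 σ between beads of the same A/B compartment
label (default: five alternating blocks), inside the same confinement; and
a final FIRE relaxation (ftol 0.1 ε/σ) under the generator Hamiltonian —
homopolymer terms plus attraction and confinement.

Two generator-specific terms deserve justification. The confinement wall
mimics nuclear density: without it, minimisation straightens and inflates
the coil (the bending term's minimum is a straight rod) and all non-bonded
contacts vanish, which no chromatin in a nucleus can do. The attraction is
retained during the final relaxation for the same reason: it is what holds
compartments together; relaxing under the bare homopolymer Hamiltonian
would erase the structure the generator exists to provide. The protocol
itself always evolves structures under the bare homopolymer Hamiltonian.

What the generator does *not* emulate: sequence-specific interactions,
loop extrusion, lamina association, nucleoli, heterogeneous nucleosome
occupancy, or any particular genomic locus. Tests passing on these
synthetic ensembles therefore demonstrate the mechanics and statistics of
the protocol, not agreement with any real chromosome.

## Analysis

- **P(s)**: mean map entry per genomic separation, normalised to unit sum
  over s ≥ 1 (exponents are scale-free, so normalisation is harmless);
  optional log binning. Power-law exponents are least-squares slopes in
  log–log space; the default window [3, n/10] is configurable, and the
  analyses here use [10, n/10] because the semiflexible chain (persistence
  ~4 beads) suppresses contacts below s ≈ 10 at the 1.5 σ threshold,
  which would otherwise contaminate the fit.
- **Euclidean ligation curve**: frequency in a 2 nm distance bin =
  (ligated end pairs)/(candidate end pairs) whose *native* separation falls
  in the bin; candidates are all unordered free-end pairs at digestion
  time. Bins with no candidates are undefined (NaN), never zero, and the
  curve is deliberately not normalised — it is a per-pair probability.
  The sigmoid fit is unweighted least squares of A/(1 + e^{(d−d½)/w});
  the half-plateau statistic instead takes the count-weighted mean
  frequency below 12 nm as the plateau and interpolates the first downward
  half-crossing.
- **Knight–Ruiz balancing**: the Newton/inner-CG scheme with clipping
  bounds, on the submatrix of non-empty rows; tolerance 10⁻⁶ on
  max |row sum − 1|, divergence raised with the offending rows named.
- **Compartments**: observed/expected transform (each diagonal divided by
  its mean), row-pairwise Pearson correlation (zero-variance rows masked),
  leading eigenvector as the FPC with sign fixed against a reference track
  when available, singular value spectrum, and per-column sums with a
  moving average.

## Restriction-site statistics

Digestion is modelled as uniform random bond cleavage. The
`restriction` module supports that choice: exact (overlapping) motif
matching on both strands (N never matches), successive-spacing extraction,
a maximum-likelihood exponential fit with a Kolmogorov–Smirnov
goodness-of-fit, and a windowed index of dispersion. On i.i.d. synthetic
sequence a 4-cutter such as GATC recurs every ~4⁴ = 256 bp with
exponential spacings and dispersion ≈ 1 — the signature of spatially
uniform cutting.

## Problem sizes and numerical choices

The published protocol scale (5500 beads × 5000 structures) is a
configuration choice, not a test requirement. The bundled analyses run at
desk scale: test fixtures use 40 structures × 240 beads and
10 × 1000 beads; `scripts/acceptance.py` uses 50 × 1000 beads (annealing
10 000 steps) for the ensemble protocol, 50 × 200 beads for the balanced
ligation map, and the 20-structure fully crosslinked limit via the static
fast path. Digestion arithmetic is computed on the full 5500-bead chain,
where it is exact. At these scales the ensemble sigmoid midpoint of the
Euclidean ligation curve comes out near the capture radius (~11–12 nm);
with larger ensembles and longer diffusion times the shoulder broadens
toward ~20 nm.

Degenerate inputs are handled explicitly: empty candidate bins are masked,
zero-variance PCM rows are masked with a warning, empty map rows are
excluded from balancing, a non-decaying curve fails the sigmoid fit with a
status rather than an exception, and `digest(n_cuts = n_bonds)` yields the
single-nucleosome "gas" limit.

## Known limitations

- Overdamped dynamics with uniform friction: no hydrodynamics, no
  sequence-dependent energetics.
- Ligated ends are only bookkeeping: no mechanical bond is formed at a
  ligation junction, so post-ligation chimeric polymer mechanics are out of
  scope. The event list is the assay readout, and maps and frequency curves
  are unaffected by what the ligated product would do afterwards.
- No sequencing-side noise model (biotin enrichment, shearing, PCR
  duplicates); maps are exact event counts.
- The time-unit mapping tau = 2.2678 us is metadata only; kinetic rates
  are meaningful relative to p₀ = 1/τ, not in absolute seconds.
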