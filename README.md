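# virtualhic

In-silico DNA-DNA proximity ligation (virtual Hi-C) on nucleosome-resolution
chromatin polymer models.

Hi-C and its relatives read out 3D genome organisation by crosslinking
chromatin, digesting the DNA, and ligating fragment ends that happen to lie
close in space; the sequenced ligation junctions populate a contact ("ligation")
map. Many knobs of that protocol — crosslinking efficiency, digestion depth,
ligation kinetics — are hard to isolate at the bench. `virtualhic` runs the
whole experiment inside a molecular-dynamics simulation, where every knob is
explicit, so you can ask how each step shapes the final map. It is aimed at
computational chromatin biologists and polymer physicists who want a
controlled, reproducible stand-in for the assay.

## Model

A chromatin fibre is a bead-spring chain, one bead per nucleosome (200 bp;
sigma = 10 nm, epsilon = k_B T). The Hamiltonian is

    U = Σ_bonds U_FENE(r) + Σ_pairs U_hc(r) + Σ_angles U_angle(θ)

with shifted FENE bonds

    U_FENE(r) = −(k_b R₀²/2) ln[1 − ((r − R_s)/R₀)²],  R_s ≤ r < R_s + R₀
    (zero below R_s);  k_b = 30 ε/σ², R₀ = R_s = 1.5 σ

purely repulsive truncated Lennard-Jones (WCA) excluded volume between all
bead pairs (cutoff 2^{1/6} σ), and harmonic bending U = (k_a/2)(θ − π)² with
k_a = 4 ε. Dynamics are overdamped Langevin (dt = 10⁻⁴ τ, γ = 1); the
protocol freezes matrix-crosslinked beads in place, cleaves random bonds,
and every 10 steps lets each pair of active free ends within the 1.5 σ
(15 nm) capture radius ligate with probability p·Δt, where the rate p is
measured in units of p₀ = 1/τ. Downstream analysis covers ligation maps at
any binning, contact probability P(s) with power-law exponent fits, ligation
frequency versus native Euclidean distance with logistic (sigmoid) fits,
Knight–Ruiz matrix balancing, and compartment detection via the first
principal component of the observed/expected Pearson correlation matrix.

Native input ensembles are produced by the built-in generator: confined
self-avoiding walks annealed as block copolymers (like-compartment
attraction) and FIRE-relaxed, which yields compact structures with
checkerboard A/B compartment signal.

## Worked example

```python
import numpy as np
import virtualhic as vh
from virtualhic.synthetic import CompartmentTrack, generate_native_ensemble

track = CompartmentTrack.blocks(1000, 5)
natives, track, _ = generate_native_ensemble(10, 1000, track, seed=77,
                                             anneal_steps=10000)
topo = vh.Topology.linear(1000)
proto = vh.ProtocolParams(n_crosslinks=100, n_cuts=200, ligation_rate=1.0,
                          duration=100_000, seed=303)
results = vh.run_ensemble(natives, topo, proto=proto, seed=303)
print("ligations:", sum(len(r.events) for r in results))

lig = vh.aggregate_maps([vh.ligation_map(r.event_array(), 1000)
                         for r in results], how="sum")
exp, se = vh.fit_power_exponent(vh.ps_curve(lig), (10, 100))
print(f"P(s) exponent: {exp:.2f} +- {se:.2f}")

curve = vh.euclidean_ligation_curve(results, bin_width_nm=2.0)
fit = vh.fit_sigmoid(curve)
print(f"ligation length scale: {fit.midpoint:.1f} nm (width {fit.width:.1f})")
```

Output from this exact script:

```
ligations: 1631
P(s) exponent: -0.81 +- 0.10
ligation length scale: 10.7 nm (width 3.9)
```

1631 end pairs ligated across the ten structures; their genomic-distance
scaling mirrors the native ensemble's contact decay, and the probability of
ligating falls to half its short-range value once two ends start more than
~11 nm apart in the native structure — ligation is local, on the scale of
the 15 nm capture radius.

The same pipeline is scriptable from the shell (`virtualhic generate`,
`run`, `aggregate`, `maps`, `analyze`, `balance`, `restriction`; see
`virtualhic --help`).

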