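"""Crosslinking, digestion and ligation mechanics of the virtual assay."""
import numpy as np
import pytest
from scipy.spatial.distance import cdist

import virtualhic as vh
from virtualhic.protocol import FreeEnd, attempt_ligations
from virtualhic.synthetic import generate_initial_walk

from conftest import make_chain


def test_crosslink_selection_counts_and_errors():
    rng = np.random.default_rng(0)
    assert vh.select_crosslinks(5500, 0, rng).sum() == 0
    assert vh.select_crosslinks(5500, 5500, rng).all()
    mask = vh.select_crosslinks(5500, 5000, rng)
    assert mask.sum() == 5000
    assert mask.mean() * 100 == pytest.approx(90.909, abs=0.001)
    with pytest.raises(vh.ParameterError):
        vh.select_crosslinks(10, 11, rng)


@pytest.mark.parametrize("n_cuts,expect_mean", [
    (0, 5500.0), (500, 5500 / 501), (5499, 1.0)])
def test_digestion_fragment_arithmetic(n_cuts, expect_mean):
    topo = vh.Topology.linear(5500)
    rng = np.random.default_rng(1)
    new_topo, frags, ends = vh.digest(topo, n_cuts, rng)
    assert frags.n_fragments == n_cuts + 1
    assert frags.sizes.sum() == 5500
    assert frags.sizes.mean() == pytest.approx(expect_mean)
    assert len(ends) == 2 * n_cuts          # termini inactive by default
    assert new_topo.n_bonds == 5499 - n_cuts


def test_digestion_termini_flag_and_single_bead_fragments():
    topo = vh.Topology.linear(6)
    rng = np.random.default_rng(3)
    _, frags, ends = vh.digest(topo, 5, rng, ligatable_termini=True)
    assert all(s == 1 for s in frags.sizes)
    # every fragment of size one still carries two distinct ends
    assert len(ends) == 12


def test_mean_fragment_size_over_replicates():
    topo = vh.Topology.linear(500)
    rng = np.random.default_rng(5)
    sizes = []
    for _ in range(200):
        _, frags, _ = vh.digest(topo, 45, rng)
        sizes.append(frags.sizes.mean())
    assert np.mean(sizes) == pytest.approx(500 / 46, rel=1e-12)


def _two_end_setup(separation):
    pos = np.array([[0.0, 0, 0], [separation, 0, 0]])
    ends = [FreeEnd(bead=0, fragment=0, side="right"),
            FreeEnd(bead=1, fragment=1, side="left")]
    return pos, ends


def test_ligation_respects_capture_radius_and_rate():
    proto = vh.ProtocolParams(ligation_rate=1e6, check_interval=1)
    rng = np.random.default_rng(0)
    pos, ends = _two_end_setup(1.6)
    assert attempt_ligations(pos, ends, proto, 1e-4, rng) == []
    pos, ends = _two_end_setup(1.4)
    events = attempt_ligations(pos, ends, proto, 1e-4, rng)  # p dt >= 1
    assert len(events) == 1 and not ends[0].active and not ends[1].active
    # a consumed end never fires again
    assert attempt_ligations(pos, ends, proto, 1e-4, rng) == []
    pos, ends = _two_end_setup(1.0)
    zero = vh.ProtocolParams(ligation_rate=0.0)
    assert attempt_ligations(pos, ends, zero, 1e-4, rng) == []


def test_no_cuts_means_no_events():
    pos = make_chain(50, seed=2)
    topo = vh.Topology.linear(50)
    proto = vh.ProtocolParams(n_crosslinks=5, n_cuts=0, ligation_rate=1.0,
                              duration=2000, seed=1)
    res = vh.run_experiment(pos, topo, proto=proto)
    assert res.events == [] and len(res.end_beads) == 0


def test_frozen_limit_events_match_static_geometry_oracle():
    """All-crosslinked: ligatable pairs are exactly the static close pairs."""
    conf = generate_initial_walk(120, rng=np.random.default_rng(12))
    topo = vh.Topology.linear(120)
    proto = vh.ProtocolParams(n_crosslinks=120, n_cuts=40, ligation_rate=1e-1,
                              duration=500000, seed=42)
    res = vh.run_experiment(conf, topo, proto=proto)
    # independent oracle: brute-force end-pair distances in the native frame
    d = cdist(res.end_native_positions, res.end_native_positions)
    allowed = {(min(a, b), max(a, b))
               for a in range(len(res.end_beads))
               for b in range(a + 1, len(res.end_beads))
               if d[a, b] <= proto.capture_radius}
    fired = {(min(e.end_a, e.end_b), max(e.end_a, e.end_b))
             for e in res.events}
    assert fired <= allowed
    assert len(res.events) > 0
    ends_used = [e for ev in res.events for e in (ev.end_a, ev.end_b)]
    assert len(ends_used) == len(set(ends_used))   # one ligation per end


def test_experiment_is_deterministic_given_seed():
    pos = make_chain(80, seed=9)
    topo = vh.Topology.linear(80)
    proto = vh.ProtocolParams(n_crosslinks=10, n_cuts=20, ligation_rate=1.0,
                              duration=2000, seed=31)
    a = vh.run_experiment(pos, topo, proto=proto)
    b = vh.run_experiment(pos, topo, proto=proto)
    assert [(e.bead_a, e.bead_b, e.time) for e in a.events] == \
        [(e.bead_a, e.bead_b, e.time) for e in b.events]


def test_expected_ligations_monotone_in_rate_and_duration():
    conf = generate_initial_walk(150, rng=np.random.default_rng(4))
    topo = vh.Topology.linear(150)

    def mean_total(rate, duration):
        totals = []
        for seed in range(20):
            proto = vh.ProtocolParams(n_crosslinks=150, n_cuts=50,
                                      ligation_rate=rate, duration=duration,
                                      seed=seed)
            totals.append(len(vh.run_experiment(conf, topo, proto=proto).events))
        return np.mean(totals)

    by_rate = [mean_total(r, 20000) for r in (1e-3, 1e-2, 1e-1, 1.0)]
    assert all(a <= b for a, b in zip(by_rate, by_rate[1:]))
    by_time = [mean_total(1e-3, d) for d in (10000, 100000, 1000000)]
    assert all(a <= b for a, b in zip(by_time, by_time[1:]))


def test_single_run_ensemble_equals_run_experiment():
    pos = make_chain(60, seed=14)
    topo = vh.Topology.linear(60)
    proto = vh.ProtocolParams(n_crosslinks=6, n_cuts=15, ligation_rate=1.0,
                              duration=1500, seed=5)
    ens = vh.run_ensemble([pos], topo, proto=proto, seed=5)
    child = np.random.SeedSequence(5).spawn(1)[0]
    direct = vh.run_experiment(pos, topo, proto=proto,
                               rng=np.random.default_rng(child))
    assert [(e.bead_a, e.bead_b, e.time) for e in ens[0].events] == \
        [(e.bead_a, e.bead_b, e.time) for e in direct.events]


def test_repeat_runs_sample_independently():
    conf = generate_initial_walk(150, rng=np.random.default_rng(6))
    topo = vh.Topology.linear(150)
    proto = vh.ProtocolParams(n_crosslinks=150, n_cuts=50, ligation_rate=1e-2,
                              duration=100000)
    results = vh.run_ensemble([conf], topo, proto=proto, n_repeats=12, seed=8)
    keys = [tuple(sorted((e.bead_a, e.bead_b) for e in r.events))
            for r in results]
    counts = [len(r.events) for r in results]
    assert len(set(keys)) > 1 and np.std(counts) > 0
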