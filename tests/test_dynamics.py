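"""Langevin integration and FIRE relaxation behaviour."""
import numpy as np
import pytest

import virtualhic as vh
from virtualhic.dynamics import IntegratorSettings, fire_minimize, \
    langevin_step, run_trajectory

from conftest import make_chain


def test_fully_frozen_chain_never_moves():
    pos = make_chain(30, seed=1)
    topo = vh.Topology.linear(30)
    frozen = np.ones(30, dtype=bool)
    out = langevin_step(pos, topo, frozen=frozen,
                        rng=np.random.default_rng(0))
    assert np.array_equal(out.positions, pos)


def test_frozen_subset_is_bit_identical_while_free_beads_move():
    pos = make_chain(40, seed=2)
    topo = vh.Topology.linear(40)
    rng = np.random.default_rng(5)
    frozen = rng.random(40) < 0.4
    out = run_trajectory(pos, topo, frozen=frozen, n_steps=500,
                         rng=np.random.default_rng(9))
    assert np.array_equal(out.positions[frozen], pos[frozen])
    assert not np.allclose(out.positions[~frozen], pos[~frozen])


def test_athermal_isolated_bead_stays_put():
    pos = np.zeros((1, 3))
    topo = vh.Topology(1, np.zeros(0, dtype=bool))
    out = langevin_step(pos, topo,
                        settings=IntegratorSettings(kT=0.0),
                        rng=np.random.default_rng(0))
    assert np.array_equal(out.positions, pos)


def test_free_particle_diffusion_matches_einstein_relation():
    """MSD of non-interacting beads follows 6 (kT/gamma) t within 5%."""
    n = 10000
    side = int(round(n ** (1 / 3))) + 1
    g = np.arange(side) * 5.0
    grid = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T[:n].copy()
    topo = vh.Topology(n, np.zeros(n - 1, dtype=bool))
    settings = IntegratorSettings(dt=1e-3)
    steps = 200
    out = run_trajectory(grid, topo, settings=settings, n_steps=steps,
                         observe_every=steps, rng=np.random.default_rng(11))
    msd = ((out.positions - grid) ** 2).sum(axis=1).mean()
    expected = 6.0 * settings.kT / settings.gamma * steps * settings.dt
    assert msd == pytest.approx(expected, rel=0.05)


def test_chain_centre_of_mass_diffuses_monomers_subdiffuse():
    n = 200
    pos = make_chain(n, seed=8)
    topo = vh.Topology.linear(n)
    settings = IntegratorSettings(dt=2e-4)
    frames = []
    run_trajectory(pos, topo, settings=settings, n_steps=60000,
                   observe_every=600, rng=np.random.default_rng(21),
                   observers=[lambda step, p: frames.append(p)])
    traj = np.stack(frames)                        # (frames, beads, 3)
    com = traj.mean(axis=1)
    lags = np.arange(1, 12)

    def tamsd(x, lag):                             # time-averaged MSD
        d = x[lag:] - x[:-lag]
        return (d ** 2).sum(axis=-1).mean()

    mono_msd = [np.mean([tamsd(traj[:, b], lag) for b in range(0, 200, 5)])
                for lag in lags]
    com_msd = [tamsd(com, lag) for lag in lags]
    lt = np.log(lags)
    mono = np.polyfit(lt, np.log(mono_msd), 1)[0]
    com_slope = np.polyfit(lt, np.log(com_msd), 1)[0]
    assert mono < 0.95          # subdiffusive at intermediate times
    assert com_slope > mono     # centre of mass closer to free diffusion
    assert 0.6 < com_slope < 1.4


def test_trajectory_is_deterministic_and_zero_steps_is_identity():
    pos = make_chain(25, seed=4)
    topo = vh.Topology.linear(25)
    same = run_trajectory(pos, topo, n_steps=0,
                          rng=np.random.default_rng(1))
    assert np.array_equal(same.positions, pos)
    a = run_trajectory(pos, topo, n_steps=300, rng=np.random.default_rng(7))
    b = run_trajectory(pos, topo, n_steps=300, rng=np.random.default_rng(7))
    assert np.array_equal(a.positions, b.positions)


def test_step_rejection_reports_unstable_bond():
    pos = np.array([[0.0, 0, 0], [2.999, 0, 0], [6.0, 0, 0]])
    topo = vh.Topology.linear(3)
    with pytest.raises(vh.FeneDomainError):
        run_trajectory(pos, topo, n_steps=5, rng=np.random.default_rng(0))


def test_fire_fixed_point_dimer():
    # bonded pair inside the zero-force band of FENE + WCA
    pos = np.array([[0.0, 0, 0], [1.3, 0, 0]])
    topo = vh.Topology.linear(2)
    e0 = vh.total_energy(pos, topo)
    res = fire_minimize(pos, topo, ftol=1e-4)
    assert res.converged and res.n_iter == 0
    assert abs(res.energy - e0) < 1e-8


def test_fire_immediate_convergence_on_symmetric_minimum():
    pos = np.zeros((3, 3))
    pos[:, 0] = [0.0, 1.3, 2.6]       # straight, bonds at force balance
    topo = vh.Topology.linear(3)
    res = fire_minimize(pos, topo, ftol=1e-6)
    assert res.n_iter == 0 and res.max_force <= 1e-6


def test_fire_descends_on_perturbed_chain():
    rng = np.random.default_rng(13)
    pos = make_chain(50, seed=6) + rng.normal(scale=0.08, size=(50, 3))
    topo = vh.Topology.linear(50)
    e0 = vh.total_energy(pos, topo)
    res = fire_minimize(pos, topo, ftol=1e-3, max_iter=4000)
    assert res.energy < e0
    assert res.max_force <= max(1e-3, res.max_force if not res.converged else 1e-3)
    # relaxed bonds stay within the FENE domain
    bl = np.linalg.norm(np.diff(res.conformation.positions, axis=0), axis=1)
    assert bl.max() < 3.0
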