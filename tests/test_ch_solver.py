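"""Time stepper: stationarity, conservation, symmetry, granule pinning."""

import numpy as np
import pytest

from chmito import ch_solver as cs
from chmito.energetics import PhaseField, total_free_energy, total_mass
from chmito.geometry import interval_domain


class TestInitializeRandom:
    def test_deterministic_given_seed(self, small_disk):
        a = cs.initialize_random(small_disk, 0.0, 0.05, seed=42)
        b = cs.initialize_random(small_disk, 0.0, 0.05, seed=42)
        assert np.array_equal(a.values, b.values)
        c = cs.initialize_random(small_disk, 0.0, 0.05, seed=43)
        assert not np.array_equal(a.values, c.values)

    def test_zero_amplitude_gives_uniform(self, small_disk):
        f = cs.initialize_random(small_disk, 0.3, 0.0, seed=0)
        assert np.all(f.values == 0.3)

    def test_out_of_range_rejected(self, small_disk):
        with pytest.raises(ValueError):
            cs.initialize_random(small_disk, 0.97, 0.05, seed=0)

    def test_sample_mean_within_four_standard_errors(self, small_disk):
        amp = 0.05
        f = cs.initialize_random(small_disk, 0.0, amp, seed=7)
        se = amp / np.sqrt(3.0 * small_disk.n_nodes)
        assert abs(f.values.mean()) < 4.0 * se

    def test_granule_nodes_pinned_at_init(self, disk_with_granule):
        f = cs.initialize_random(disk_with_granule, 0.0, 0.05, seed=0)
        pin_idx, pin_val = disk_with_granule.pinned
        assert np.array_equal(f.values[pin_idx], pin_val)


@pytest.mark.parametrize("value", [1.0, -1.0, 0.0])
def test_uniform_states_are_stationary(small_disk, value):
    """Ψ ≡ ±1 (pure phases) and Ψ ≡ 0 (trivial state) do not move."""
    cfg = cs.SolverConfig()
    state = cs.prepare_state(small_disk, np.full(small_disk.n_nodes, value), cfg)
    for _ in range(5):
        state = cs.theta_step(small_disk, state, cfg)
    assert np.max(np.abs(state.psi.values - value)) < 1e-12


def test_phase_swap_trajectory_symmetry(small_disk):
    """Granule-free dynamics are odd: stepping −Ψ₀ negates stepping Ψ₀."""
    cfg = cs.SolverConfig(dt=1e-3)
    psi0 = cs.initialize_random(small_disk, 0.0, 0.05, seed=5).values
    sa = cs.prepare_state(small_disk, psi0, cfg)
    sb = cs.prepare_state(small_disk, -psi0, cfg)
    for _ in range(20):
        sa = cs.theta_step(small_disk, sa, cfg)
        sb = cs.theta_step(small_disk, sb, cfg)
    assert np.max(np.abs(sa.psi.values + sb.psi.values)) < 1e-12


def test_mass_conserved_and_energy_decays(small_disk):
    cfg = cs.SolverConfig(dt=1e-3, record_every=10)
    psi0 = cs.initialize_random(small_disk, 0.1, 0.05, seed=2)
    state, records = cs.run_simulation(small_disk, psi0, cfg, 100)
    masses = np.array([r.mass for r in records])
    assert np.max(np.abs(masses - masses[0])) / small_disk.measure() < 1e-10
    energies = np.array([r.F_total for r in records])
    assert np.all(np.diff(energies) <= 1e-10)
    assert all(r.dissipation <= 0.0 for r in records)


def test_record_count_and_schedule(small_disk):
    cfg = cs.SolverConfig(dt=1e-3, record_every=5)
    psi0 = cs.initialize_random(small_disk, seed=0)
    _, records = cs.run_simulation(small_disk, psi0, cfg, 20)
    assert [r.step for r in records] == [0, 5, 10, 15, 20]
    assert records[-1].time == pytest.approx(0.02)


def test_final_step_always_recorded(small_disk):
    cfg = cs.SolverConfig(dt=1e-3, record_every=250)
    psi0 = cs.initialize_random(small_disk, seed=0)
    _, records = cs.run_simulation(small_disk, psi0, cfg, 7)
    assert [r.step for r in records] == [0, 7]


class TestGranulePinning:
    def test_residual_zero_after_step(self, disk_with_granule):
        cfg = cs.SolverConfig(dt=1e-3)
        psi0 = cs.initialize_random(disk_with_granule, 0.0, 0.05, seed=0)
        state = cs.prepare_state(disk_with_granule, psi0, cfg)
        state = cs.theta_step(disk_with_granule, state, cfg)
        assert cs.granule_constraint_residual(disk_with_granule, state.psi) == 0.0

    def test_manually_pinned_field_has_zero_residual(self, disk_with_granule):
        v = np.full(disk_with_granule.n_nodes, -0.4)
        pin_idx, pin_val = disk_with_granule.pinned
        v[pin_idx] = pin_val
        assert cs.granule_constraint_residual(disk_with_granule, v) == 0.0

    def test_requires_granules(self, small_disk):
        with pytest.raises(cs.NoGranulesError):
            cs.granule_constraint_residual(small_disk, np.zeros(small_disk.n_nodes))


def test_newton_failure_reports_residual(small_disk):
    cfg = cs.SolverConfig(dt=50.0, newton_max_iter=1)
    psi0 = cs.initialize_random(small_disk, 0.0, 0.5, seed=3)
    state = cs.prepare_state(small_disk, psi0, cfg)
    with pytest.raises(cs.NewtonConvergenceError) as err:
        cs.theta_step(small_disk, state, cfg)
    assert err.value.residual > 0


def test_solver_config_validation():
    with pytest.raises(ValueError):
        cs.SolverConfig(theta=1.5)
    with pytest.raises(ValueError):
        cs.SolverConfig(dt=-1.0)
    with pytest.raises(ValueError):
        cs.SolverConfig(newton_max_iter=0)


def test_overshoot_stays_bounded_1d():
    """No spurious over/undershoot beyond 5% of the well minima."""
    d = interval_domain(4 * np.pi, 0.2, periodic=True)
    x = d.nodes[:, 0]
    cfg = cs.SolverConfig(dt=1e-3)
    state = cs.prepare_state(d, PhaseField(0.5 * np.sin(0.5 * x), d), cfg)
    for _ in range(200):
        state = cs.theta_step(d, state, cfg)
    assert np.max(np.abs(state.psi.values)) <= 1.05
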