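"""Morphometrics: fractions, interfaces, components, pattern length, halos."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chmito import morphometry as mo
from chmito.geometry import GranuleSpec, build_domain, rectangle_domain
from chmito.io import make_fixture
from chmito.morphometry import (EmptyShellError, SpectrumUndefinedError,
                                characteristic_length,
                                characteristic_length_of_field,
                                count_phase_components, granule_halo_mean,
                                granule_halo_membrane_fraction,
                                interface_measure, phase_fractions)


class TestPhaseFractions:
    def test_uniform_fields(self, small_disk):
        n = small_disk.n_nodes
        assert phase_fractions(small_disk, np.ones(n)) == (1.0, 0.0)
        assert phase_fractions(small_disk, -np.ones(n)) == (0.0, 1.0)

    def test_halfplane_interface_splits_evenly(self):
        d, psi = make_fixture("tanh_strip", width=8.0, height=4.0, h=0.2)
        mf, bf = phase_fractions(d, psi)
        assert mf == pytest.approx(0.5, abs=0.01)
        assert bf == pytest.approx(0.5, abs=0.01)

    def test_partition_of_unity(self, small_disk, rng):
        for _ in range(5):
            psi = rng.uniform(-1, 1, small_disk.n_nodes)
            mf, bf = phase_fractions(small_disk, psi)
            assert mf + bf == pytest.approx(1.0, abs=1e-12)
            assert 0.0 <= mf <= 1.0 and 0.0 <= bf <= 1.0

    def test_threshold_shifts_split(self, small_disk):
        psi = np.full(small_disk.n_nodes, 0.4)
        assert phase_fractions(small_disk, psi, threshold=0.5) == (0.0, 1.0)
        assert phase_fractions(small_disk, psi, threshold=0.3) == (1.0, 0.0)


@given(st.integers(0, 2**32 - 1))
@settings(deadline=None, derandomize=True, max_examples=25)
def test_positive_fraction_partition_property(seed):
    """Clipping fractions of ψ and −ψ partition every simplex exactly."""
    rng = np.random.default_rng(seed)
    vals = rng.uniform(-1, 1, (40, 3))
    pos = mo._positive_fraction(vals, 2)
    neg = mo._positive_fraction(-vals, 2)
    assert np.all(pos >= 0) and np.all(pos <= 1)
    np.testing.assert_allclose(pos + neg, 1.0, atol=1e-9)


class TestInterfaceMeasure:
    def test_uniform_field_has_no_interface(self, small_disk):
        assert interface_measure(small_disk, np.ones(small_disk.n_nodes)) == 0.0

    def test_straight_interface_across_square(self):
        d = rectangle_domain(2.0, 2.0, 0.2)
        psi = d.nodes[:, 0] - 0.137  # vertical line x = 0.137
        assert interface_measure(d, psi) == pytest.approx(2.0, rel=1e-9)

    def test_circular_interface_converges_first_order(self):
        errors = []
        for h in (0.2, 0.1):
            d, psi = make_fixture("circular_interface", R=2.0, r=1.0, h=h)
            errors.append(abs(interface_measure(d, psi) - 2.0 * np.pi))
        assert errors[0] < 0.02 * 2.0 * np.pi
        assert errors[1] < errors[0]

    def test_tetrahedral_interface_area(self):
        """Plane z = 0 cut through a coarse sphere ≈ equatorial disk area."""
        d = build_domain("sphere", [1.5], h_target=0.35)
        psi = d.nodes[:, 2]
        assert interface_measure(d, psi) == pytest.approx(np.pi * 1.5**2, rel=0.05)


class TestComponents:
    def test_uniform_membrane_is_one_component(self, small_disk):
        assert count_phase_components(small_disk, -np.ones(small_disk.n_nodes),
                                      "membrane") == 1
        assert count_phase_components(small_disk, np.ones(small_disk.n_nodes),
                                      "membrane") == 0

    def test_two_blobs(self):
        d, psi = make_fixture("two_blobs")
        assert count_phase_components(d, psi, "membrane") == 2
        assert count_phase_components(d, psi, "matrix") == 1

    def test_invalid_phase_name(self, small_disk):
        with pytest.raises(ValueError):
            count_phase_components(small_disk, np.ones(small_disk.n_nodes), "lumen")


class TestCharacteristicLength:
    @pytest.mark.parametrize("k", [1.0, 2.0])
    def test_single_mode_recovers_wavelength(self, k):
        d, psi = make_fixture("sinusoid_mode", k=k)
        assert characteristic_length_of_field(d, psi) == pytest.approx(
            2.0 * np.pi / k, rel=0.05)

    def test_uniform_field_undefined(self, small_disk):
        with pytest.raises(SpectrumUndefinedError):
            characteristic_length_of_field(small_disk, np.ones(small_disk.n_nodes))

    def test_finer_pattern_has_shorter_length(self):
        d1, p1 = make_fixture("sinusoid_mode", k=1.0)
        d2, p2 = make_fixture("sinusoid_mode", k=2.0)
        assert (characteristic_length_of_field(d2, p2)
                < characteristic_length_of_field(d1, p1))

    def test_direct_grid_api(self):
        x = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        grid = np.sin(3.0 * x)[:, None] * np.ones((1, 64))
        assert characteristic_length(grid, [x[1] - x[0], 1.0]) == pytest.approx(
            2.0 * np.pi / 3.0, rel=0.05)


class TestGranuleHalo:
    def test_constant_field_gives_constant(self, disk_with_granule):
        g = disk_with_granule.granules[0]
        v = np.full(disk_with_granule.n_nodes, 0.37)
        assert granule_halo_mean(disk_with_granule, v, g, 0.5) == pytest.approx(0.37)
        assert granule_halo_membrane_fraction(disk_with_granule, v, g, 0.5) == 0.0

    def test_noise_mean_near_zero(self, disk_with_granule, rng):
        g = disk_with_granule.granules[0]
        amp = 0.05
        v = rng.uniform(-amp, amp, disk_with_granule.n_nodes)
        sel = mo._shell_elements(disk_with_granule, g, 0.5)
        se = amp / np.sqrt(3.0 * sel.sum())
        assert abs(granule_halo_mean(disk_with_granule, v, g, 0.5)) < 6.0 * se

    def test_empty_shell_rejected(self, disk_with_granule):
        g = disk_with_granule.granules[0]
        with pytest.raises(EmptyShellError):
            granule_halo_mean(disk_with_granule, np.ones(disk_with_granule.n_nodes),
                              g, 1e-6)


def test_full_report(disk_with_granule, rng):
    psi = rng.uniform(-0.5, 0.5, disk_with_granule.n_nodes)
    rep = mo.morphometry_report(disk_with_granule, psi)
    assert rep.matrix_fraction + rep.membrane_fraction + rep.interface_band_residual \
        == pytest.approx(1.0, abs=1e-12)
    assert rep.interface_measure > 0
    assert len(rep.granule_halo_means) == 1
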