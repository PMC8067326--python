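"""Free energy, mass and dissipation functionals.

The key check is an independent brute-force quadrature oracle: every
element is mapped to the unit square/cube by a Duffy transform and
integrated with a dense tensor Gauss–Legendre rule, sharing no code with
the closed-form simplex quadrature used by the implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chmito import energetics, geometry
from chmito.energetics import (DomainMismatchError, PhaseField,
                               bulk_energy_density, dissipation_rate,
                               total_free_energy, total_mass)


# ---------------------------------------------------------------------------
# brute-force quadrature oracle (Duffy transform + tensor Gauss-Legendre)
# ---------------------------------------------------------------------------

def _oracle_integrate_triangles(domain, func_of_linear_field, values, n_gauss=8):
    """∫ g(ψ) over a triangle mesh with ψ the P1 interpolant of `values`."""
    x, w = np.polynomial.legendre.leggauss(n_gauss)
    u = 0.5 * (x + 1.0)
    wu = 0.5 * w
    total = 0.0
    for elem, coords in zip(domain.elements, domain.element_coords):
        v = values[elem]
        for a, wa in zip(u, wu):
            for b, wb in zip(u, wu):
                # Duffy: (a, b) in unit square -> (l1, l2) = (a(1-b), ab)
                l1, l2 = a * (1.0 - b), a * b
                l0 = 1.0 - l1 - l2
                psi = l0 * v[0] + l1 * v[1] + l2 * v[2]
                jac = a  # Duffy Jacobian on the reference triangle
                total += 2.0 * _area(coords) * wa * wb * jac * func_of_linear_field(psi)
    return total


def _area(coords):
    e1 = coords[1] - coords[0]
    e2 = coords[2] - coords[0]
    return 0.5 * abs(e1[0] * e2[1] - e1[1] * e2[0])


# ---------------------------------------------------------------------------


@pytest.mark.parametrize("psi,expected", [
    (1.0, 0.0), (-1.0, 0.0), (0.0, 0.25), (0.5, 0.140625), (-0.5, 0.140625),
])
def test_bulk_energy_density_values(psi, expected):
    assert bulk_energy_density(psi) == pytest.approx(expected, abs=1e-15)


@given(st.floats(-1.2, 1.2))
@settings(deadline=None, derandomize=True)
def test_bulk_energy_density_even_and_nonnegative(psi):
    assert bulk_energy_density(psi) >= 0.0
    assert bulk_energy_density(psi) == bulk_energy_density(-psi)


def test_uniform_fields_free_energy(small_disk):
    area = small_disk.measure()
    for val, expected in [(1.0, 0.0), (-1.0, 0.0), (0.0, 0.25 * area)]:
        rep = total_free_energy(small_disk, np.full(small_disk.n_nodes, val), gamma=1.0)
        assert rep.gradient_part == pytest.approx(0.0, abs=1e-12)
        assert rep.total == pytest.approx(expected, rel=1e-12, abs=1e-12)


def test_free_energy_zero_only_at_pure_phases(small_disk, rng):
    """F > 0 for any field that is not uniformly ±1."""
    psi = np.full(small_disk.n_nodes, 1.0)
    psi[:10] = 0.9
    assert total_free_energy(small_disk, psi, 1.0).total > 0
    noisy = rng.uniform(-0.3, 0.3, small_disk.n_nodes)
    assert total_free_energy(small_disk, noisy, 1.0).total > 0


def test_free_energy_phase_swap_symmetry(small_disk, rng):
    psi = rng.uniform(-1, 1, small_disk.n_nodes)
    a = total_free_energy(small_disk, psi, 1.3)
    b = total_free_energy(small_disk, -psi, 1.3)
    assert a.total == b.total  # exact at quadrature level
    assert a.bulk_part == b.bulk_part


def test_quadrature_against_bruteforce_oracle(tiny_mesh, rng):
    """Closed-form simplex quadrature vs dense Duffy/Gauss oracle, 1e-12 rel."""
    psi = rng.uniform(-1, 1, tiny_mesh.n_nodes)
    F = total_free_energy(tiny_mesh, psi, gamma=0.7)
    oracle_bulk = _oracle_integrate_triangles(tiny_mesh, bulk_energy_density, psi)
    assert F.bulk_part == pytest.approx(oracle_bulk, rel=1e-12)
    mass = total_mass(tiny_mesh, psi)
    oracle_mass = _oracle_integrate_triangles(tiny_mesh, lambda p: p, psi)
    assert mass == pytest.approx(oracle_mass, rel=1e-12, abs=1e-12)


def test_total_mass_examples(small_disk):
    area = small_disk.measure()
    assert total_mass(small_disk, np.ones(small_disk.n_nodes)) == pytest.approx(area)
    assert total_mass(small_disk, np.zeros(small_disk.n_nodes)) == 0.0
    # odd field on a centered disk integrates to ~0
    psi_x = small_disk.nodes[:, 0]
    assert abs(total_mass(small_disk, psi_x)) < 1e-6 * area


def test_tanh_interface_energy_per_cross_section():
    """Strip with Ψ = tanh(x/√2): F per unit height ≈ (2/3)√2."""
    from chmito.io import make_fixture
    d, psi = make_fixture("tanh_strip", gamma=1.0, width=20.0, height=1.0, h=0.05)
    rep = total_free_energy(d, psi, gamma=1.0)
    assert rep.total == pytest.approx(2.0 * np.sqrt(2.0) / 3.0, rel=0.01)


def test_dissipation_rate(tiny_mesh, rng):
    assert dissipation_rate(tiny_mesh, np.ones(tiny_mesh.n_nodes)) == pytest.approx(0.0)
    # μ = x on a 2 x 1 rectangle: ∫|∇μ|² = area = 2
    mu_x = tiny_mesh.nodes[:, 0]
    assert dissipation_rate(tiny_mesh, mu_x) == pytest.approx(-2.0, rel=1e-10)
    assert dissipation_rate(tiny_mesh, rng.normal(size=tiny_mesh.n_nodes)) <= 0.0


def test_domain_mismatch_rejected(small_disk, tiny_mesh):
    psi = PhaseField(np.zeros(small_disk.n_nodes), small_disk)
    with pytest.raises(DomainMismatchError):
        total_free_energy(tiny_mesh, psi, 1.0)
    with pytest.raises(DomainMismatchError):
        PhaseField(np.zeros(3), small_disk)
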