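"""Closed-form linear stability results and 1D interface identities.

Linearizing the conserved dynamics ∂Ψ/∂t = (1/2)∇²(Ψ³ − Ψ − γ∇²Ψ) about the
homogeneous state Ψ = 0 with Ψ ∝ e^{ωt}e^{ik·r} gives the dispersion relation

    ω(k) = (1/2)(k² − γk⁴),

positive (growing) exactly for 0 < k < 1/√γ.  The 1D standing interface of
the double-well functional is Ψ(x) = tanh(x/√(2γ)) with excess free energy
(2/3)√(2γ) per unit cross-section.

``measure_growth_rate_1d`` is a deliberately independent numerical oracle:
a uniform periodic finite-difference grid with a standard second-difference
Laplacian and semi-implicit stepping, sharing no code with the finite
element solver, so that a disagreement between the two localizes a bug.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


class NonlinearContaminationError(RuntimeError):
    """Log-amplitude trajectory not exponential; reduce the amplitude."""


@dataclass(frozen=True)
class DispersionQuery:
    """One point of the dispersion relation: mode k at parameter γ.

    ``amplitude`` is the perturbation size used for a numerical measurement
    (must stay ≤ 1e−3 for linear-regime validity); ``omega`` is ω(k).
    """

    k: float
    gamma: float = 1.0
    amplitude: float = 1e-4
    omega: float = None

    def __post_init__(self):
        if self.k < 0 or self.gamma <= 0:
            raise ValueError("need k ≥ 0 and gamma > 0")
        if self.amplitude > 1e-3:
            raise ValueError("amplitude must be ≤ 1e-3 for linear-regime validity")
        if self.omega is None:
            object.__setattr__(self, "omega", dispersion_rate(self.k, self.gamma))


def dispersion_rate(k: float, gamma: float = 1.0):
    """Growth rate ω(k) = (1/2)(k² − γk⁴) of an infinitesimal k-mode."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("wavenumber must be nonnegative")
    out = 0.5 * (k**2 - gamma * k**4)
    return float(out) if out.ndim == 0 else out


def critical_wavenumber(gamma: float) -> float:
    """Zero crossing 1/√γ of the dispersion relation; k below it grow."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return 1.0 / np.sqrt(gamma)


def fastest_growing_wavenumber(gamma: float) -> float:
    """argmax of ω(k): 1/√(2γ); sets the emerging pattern scale."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return 1.0 / np.sqrt(2.0 * gamma)


def equilibrium_profile(x, gamma: float = 1.0):
    """1D standing interface tanh(x/√(2γ)) between the two pure phases."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    out = np.tanh(np.asarray(x, dtype=float) / np.sqrt(2.0 * gamma))
    return float(out) if out.ndim == 0 else out


def interface_energy(gamma: float) -> float:
    """Excess free energy (2/3)√(2γ) of the tanh interface, per unit measure."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return (2.0 / 3.0) * np.sqrt(2.0 * gamma)


def _fit_rate(times: np.ndarray, amplitudes: np.ndarray, skip: int) -> tuple:
    """Least-squares slope of log|a| vs t, with R² of the fit."""
    t = times[skip:]
    a = amplitudes[skip:]
    if np.any(a <= 0):
        raise NonlinearContaminationError("mode amplitude vanished during the fit window")
    y = np.log(a)
    A = np.column_stack([t, np.ones_like(t)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(res[0]) if len(res) else float(np.sum((A @ coef - y) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(coef[0]), r2


def measure_growth_rate_1d(k: float, gamma: float = 1.0, amplitude: float = 1e-4,
                           n_steps: int = 500, dt: float = 1e-3,
                           nodes_per_wavelength: int = 64, skip: int = 10) -> float:
    """Numerically measured growth rate of a single k-mode (FD oracle).

    Integrates the full nonlinear equation on one period of a uniform
    periodic grid from Ψ = amplitude·cos(kx), treating the linear part of
    the chemical potential implicitly and the cubic term explicitly, and
    fits an exponential to the FFT amplitude of the seeded mode.
    """
    if k <= 0:
        raise ValueError("k must be positive for a measurable mode")
    if amplitude > 1e-3:
        raise ValueError("amplitude must be ≤ 1e-3 for linear-regime validity")
    if abs(dispersion_rate(k, gamma)) * dt > 0.01:
        raise ValueError("dt too large: |ω(k)|·dt must be ≤ 0.01")

    n = int(nodes_per_wavelength)
    L = 2.0 * np.pi / k
    dx = L / n
    x = dx * np.arange(n)

    # standard periodic second-difference Laplacian
    main = -2.0 * np.ones(n)
    off = np.ones(n - 1)
    lap = sp.diags([main, off, off, [1.0], [1.0]], [0, 1, -1, n - 1, -(n - 1)],
                   format="csc") / dx**2
    ident = sp.identity(n, format="csc")
    # semi-implicit: (I − dt·A)ψ⁺ = ψ + (dt/2)·Lap(ψ³),  A = (1/2)Lap(−I − γ·Lap)
    A = 0.5 * (lap @ (-ident - gamma * lap))
    solve = spla.factorized((ident - dt * A).tocsc())

    psi = amplitude * np.cos(k * x)
    amps = np.empty(n_steps + 1)
    amps[0] = 2.0 * np.abs(np.fft.rfft(psi)[1]) / n
    for step in range(1, n_steps + 1):
        psi = solve(psi + 0.5 * dt * (lap @ psi**3))
        amps[step] = 2.0 * np.abs(np.fft.rfft(psi)[1]) / n

    times = dt * np.arange(n_steps + 1)
    rate, r2 = _fit_rate(times, amps, skip)
    if r2 < 0.999:
        raise NonlinearContaminationError(
            f"log-linear fit R²={r2:.6f} < 0.999; reduce the perturbation amplitude")
    return rate


def measure_growth_rate_fem(k: float, gamma: float = 1.0, amplitude: float = 1e-4,
                            n_steps: int = 500, dt: float = 1e-3,
                            nodes_per_wavelength: int = 64, skip: int = 10,
                            base_value: float = 0.0, theta: float = 0.5) -> float:
    """Growth rate of a seeded k-mode measured with the finite element solver.

    Runs the actual mixed-formulation theta scheme on a periodic 1D mesh
    (one period of the mode) superposed on a uniform base state, and fits
    the exponential rate of the mode amplitude.  Cross-checking this
    against :func:`dispersion_rate` and :func:`measure_growth_rate_1d`
    validates the solver's linear regime.
    """
    from . import ch_solver
    from .energetics import PhaseField
    from .geometry import interval_domain

    if k <= 0:
        raise ValueError("k must be positive for a measurable mode")
    if amplitude > 1e-3:
        raise ValueError("amplitude must be ≤ 1e-3 for linear-regime validity")

    n = int(nodes_per_wavelength)
    L = 2.0 * np.pi / k
    d = interval_domain(L, L / n, periodic=True, x0=0.0)
    x = d.nodes[:, 0]
    cfg = ch_solver.SolverConfig(gamma=gamma, dt=dt, theta=theta)
    state = ch_solver.prepare_state(d, PhaseField(base_value + amplitude * np.cos(k * x), d), cfg)

    n_nodes = d.n_nodes
    amps = np.empty(n_steps + 1)
    amps[0] = 2.0 * np.abs(np.fft.rfft(state.psi.values - base_value)[1]) / n_nodes
    for step in range(1, n_steps + 1):
        state = ch_solver.theta_step(d, state, cfg)
        amps[step] = 2.0 * np.abs(np.fft.rfft(state.psi.values - base_value)[1]) / n_nodes

    times = dt * np.arange(n_steps + 1)
    rate, r2 = _fit_rate(times, amps, skip)
    if r2 < 0.999:
        raise NonlinearContaminationError(
            f"log-linear fit R²={r2:.6f} < 0.999; reduce the perturbation amplitude")
    return rate


def mode_growth_ratio(base_value: float, k: float, gamma: float = 1.0,
                      amplitude: float = 1e-4, max_steps: int = 30000,
                      dt: float = 1e-3, nodes_per_wavelength: int = 64,
                      grow_factor: float = 10.0, decay_factor: float = 0.1) -> tuple:
    """Amplitude ratio of a k-mode perturbation on a uniform base state.

    Evolves Ψ = base + amplitude·cos(kx) with the finite element solver on a
    periodic 1D mesh until the seeded mode's amplitude has grown by
    ``grow_factor``, decayed by ``decay_factor``, or ``max_steps`` elapsed.
    Returns ``(ratio, steps_run)``.  Discriminates the linearly unstable
    uniform state (Ψ=0 grows for k < 1/√γ) from the stable phases Ψ = ±1.
    """
    from . import ch_solver
    from .energetics import PhaseField
    from .geometry import interval_domain

    n = int(nodes_per_wavelength)
    L = 2.0 * np.pi / k
    d = interval_domain(L, L / n, periodic=True, x0=0.0)
    x = d.nodes[:, 0]
    cfg = ch_solver.SolverConfig(gamma=gamma, dt=dt)
    state = ch_solver.prepare_state(d, PhaseField(base_value + amplitude * np.cos(k * x), d), cfg)

    n_nodes = d.n_nodes
    a0 = 2.0 * np.abs(np.fft.rfft(state.psi.values - base_value)[1]) / n_nodes
    ratio = 1.0
    step = 0
    for step in range(1, max_steps + 1):
        state = ch_solver.theta_step(d, state, cfg)
        a = 2.0 * np.abs(np.fft.rfft(state.psi.values - base_value)[1]) / n_nodes
        ratio = a / a0
        if ratio >= grow_factor or ratio <= decay_factor:
            break
    return float(ratio), step
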