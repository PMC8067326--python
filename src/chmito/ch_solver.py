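"""Mixed-formulation Cahn–Hilliard time stepper.

The fourth-order equation ∂Ψ/∂t = M∇²μ, μ = Ψ³ − Ψ − γ∇²Ψ (M = 1/2 in the
dimensionless model) is advanced as two coupled second-order equations in
(Ψ, μ) with P1 elements and the theta method:

    (Ψⁿ⁺¹ − Ψⁿ, u) + Δt·M·a(μ_{n+θ}, u) = 0
    (μⁿ⁺¹, v) − (f′(Ψⁿ⁺¹), v) − γ·a(Ψⁿ⁺¹, v) = 0

with μ_{n+θ} = (1−θ)μⁿ⁺¹ + θμⁿ and a(u, v) = (∇u, ∇v).  Zero-flux outer
boundary conditions on both fields are natural in this weak form; on
granule boundaries Ψ is pinned to the granule constant C by row
elimination while μ keeps its natural zero-flux condition.

The nonlinear system per step is solved by Newton's method on the coupled
two-field unknown, with the Jacobian factorized once per step and
refreshed only if the residual stalls (the cubic block changes little
within one Δt at the model's time steps).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .energetics import ChemicalPotentialField, PhaseField, _values
from .geometry import Domain


class NewtonConvergenceError(RuntimeError):
    """Newton failed within max_iter; Δt too large or mesh too coarse."""

    def __init__(self, message: str, residual: float, step: int = None):
        super().__init__(message)
        self.residual = residual
        self.step = step


class NoGranulesError(ValueError):
    """Operation requires a domain with at least one granule."""


@dataclass(frozen=True)
class SolverConfig:
    """All scheme parameters of one simulation.

    gamma     – transition-region length parameter γ of the model
    dt        – time step Δt
    theta     – theta-method blend; 0.5 (trapezoidal) by default
    mobility  – coefficient M of ∇μ in the flux J = −M∇μ (1/2 in the model)
    """

    gamma: float = 1.0
    dt: float = 1e-3
    theta: float = 0.5
    mobility: float = 0.5
    newton_abs_tol: float = 1e-10
    newton_rel_tol: float = 1e-8
    newton_max_iter: int = 25
    seed: int = 0
    record_every: int = 250
    init_mean: float = 0.0
    init_amplitude: float = 0.05

    def __post_init__(self):
        if self.gamma <= 0 or self.dt <= 0 or self.mobility <= 0:
            raise ValueError("gamma, dt and mobility must be positive")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.newton_abs_tol <= 0 or self.newton_rel_tol <= 0:
            raise ValueError("Newton tolerances must be positive")
        if self.newton_max_iter < 1 or self.record_every < 1:
            raise ValueError("newton_max_iter and record_every must be ≥ 1")


@dataclass
class SimulationState:
    step: int
    time: float
    psi: PhaseField
    mu: ChemicalPotentialField

    def copy(self) -> "SimulationState":
        return SimulationState(self.step, self.time, self.psi.copy(), self.mu.copy())


def initialize_random(d: Domain, mean: float = 0.0, amplitude: float = 0.05,
                      seed: int = 0) -> PhaseField:
    """I.i.d. uniform noise on [mean−amplitude, mean+amplitude] at the nodes.

    Granule boundary nodes are overwritten with their pinned constants so
    the initial state already satisfies the granule condition.
    """
    if abs(mean) + amplitude > 1.0:
        raise ValueError("|mean| + amplitude must be ≤ 1 (inside the double-well range)")
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    rng = np.random.default_rng(seed)
    values = mean + amplitude * rng.uniform(-1.0, 1.0, d.n_nodes)
    pin_idx, pin_val = d.pinned
    values[pin_idx] = pin_val
    return PhaseField(values, d)


def mu_from_psi(d: Domain, psi, gamma: float) -> ChemicalPotentialField:
    """Consistent discrete chemical potential: solve (μ,v) = (f′(Ψ),v) + γa(Ψ,v)."""
    v = _values(psi, d)
    rhs = d.fem.cubic_term(v) + gamma * (d.fem.stiffness @ v)
    mu = spla.spsolve(d.fem.mass.tocsc(), rhs)
    return ChemicalPotentialField(mu, d)


def prepare_state(d: Domain, initial, cfg: SolverConfig) -> SimulationState:
    """Initial SimulationState with pins enforced and μ solved consistently."""
    psi = PhaseField(_values(initial, d).copy(), d)
    pin_idx, pin_val = d.pinned
    psi.values[pin_idx] = pin_val
    return SimulationState(step=0, time=0.0, psi=psi, mu=mu_from_psi(d, psi, cfg.gamma))


def _free_selector(d: Domain) -> sp.csr_matrix:
    """Diagonal selector zeroing granule-pinned Ψ rows (row elimination)."""
    diag = np.ones(d.n_nodes)
    pin_idx, _ = d.pinned
    diag[pin_idx] = 0.0
    return sp.diags(diag).tocsr()


def _static_blocks(d: Domain, cfg: SolverConfig):
    """Blocks of residual/Jacobian that do not depend on the state."""
    key = (cfg.gamma, cfg.dt, cfg.theta, cfg.mobility)
    cache = getattr(d, "_solver_cache", None)
    if cache is not None and cache[0] == key:
        return cache[1]
    fem = d.fem
    M = fem.mass
    K = fem.stiffness
    S = _free_selector(d)
    pin_idx, pin_val = d.pinned
    pin_diag = sp.diags((np.ones(d.n_nodes) - S.diagonal())).tocsr()
    A11 = (S @ M + pin_diag).tocsr()
    A12 = (S @ (cfg.dt * cfg.mobility * (1.0 - cfg.theta) * K)).tocsr()
    blocks = {"M": M, "K": K, "S": S, "A11": A11, "A12": A12,
              "pin_idx": pin_idx, "pin_val": pin_val}
    d._solver_cache = (key, blocks)
    return blocks


def theta_step(d: Domain, state: SimulationState, cfg: SolverConfig) -> SimulationState:
    """Advance one Δt, solving the coupled (Ψ, μ) system by Newton iteration."""
    fem = d.fem
    B = _static_blocks(d, cfg)
    M, K, S = B["M"], B["K"], B["S"]
    pin_idx, pin_val = B["pin_idx"], B["pin_val"]
    psin = state.psi.values
    mun = state.mu.values
    n = d.n_nodes
    dtM = cfg.dt * cfg.mobility

    psi = psin.copy()
    mu = mun.copy()

    def residual(psi, mu):
        r1 = M @ (psi - psin) + dtM * (K @ ((1.0 - cfg.theta) * mu + cfg.theta * mun))
        r1[pin_idx] = psi[pin_idx] - pin_val
        r2 = M @ mu - fem.cubic_term(psi) - cfg.gamma * (K @ psi)
        return np.concatenate([r1, r2])

    def jacobian(psi):
        A21 = (-fem.cubic_jacobian(psi) - cfg.gamma * K).tocsr()
        return sp.bmat([[B["A11"], B["A12"]], [A21, M]], format="csc")

    R = residual(psi, mu)
    rnorm = np.linalg.norm(R)
    tol = max(cfg.newton_abs_tol, cfg.newton_rel_tol * rnorm)
    if rnorm < tol:
        return SimulationState(state.step + 1, state.time + cfg.dt,
                               PhaseField(psi, d), ChemicalPotentialField(mu, d))

    lu = spla.splu(jacobian(psi))
    fresh = True
    for _ in range(cfg.newton_max_iter):
        dx = lu.solve(-R)
        psi = psi + dx[:n]
        mu = mu + dx[n:]
        R = residual(psi, mu)
        rnew = np.linalg.norm(R)
        if rnew < tol:
            return SimulationState(state.step + 1, state.time + cfg.dt,
                                   PhaseField(psi, d), ChemicalPotentialField(mu, d))
        if rnew > 0.1 * rnorm and not fresh:
            lu = spla.splu(jacobian(psi))
            fresh = True
        else:
            fresh = False
        rnorm = rnew
    raise NewtonConvergenceError(
        f"Newton did not converge in {cfg.newton_max_iter} iterations "
        f"(residual {rnorm:.3e}); reduce Δt or refine the mesh",
        residual=float(rnorm), step=state.step + 1)


def granule_constraint_residual(d: Domain, psi) -> float:
    """max |Ψ − C| over granule boundary nodes; 0 for any post-step state."""
    if not d.granules:
        raise NoGranulesError("domain has no granules")
    v = _values(psi, d)
    pin_idx, pin_val = d.pinned
    return float(np.max(np.abs(v[pin_idx] - pin_val)))


def _record(d: Domain, state: SimulationState, cfg: SolverConfig, halo_shell: float):
    from . import morphometry
    from .energetics import total_free_energy, total_mass
    from .records import TimeSeriesRecord

    rep = total_free_energy(d, state.psi, cfg.gamma, mu=state.mu)
    mass = total_mass(d, state.psi)
    if d.dimension >= 2:
        mf, bf = morphometry.phase_fractions(d, state.psi)
        iface = morphometry.interface_measure(d, state.psi)
        ncomp = morphometry.count_phase_components(d, state.psi, "membrane")
        try:
            clen = morphometry.characteristic_length_of_field(d, state.psi)
        except morphometry.SpectrumUndefinedError:
            clen = float("nan")
        halo = tuple(
            morphometry.granule_halo_mean(d, state.psi, g, halo_shell)
            for g in d.granules)
    else:
        mf = bf = iface = clen = float("nan")
        ncomp = -1
        halo = ()
    return TimeSeriesRecord(
        step=state.step, time=state.time, mass=mass,
        F_bulk=rep.bulk_part, F_grad=rep.gradient_part, F_total=rep.total,
        dissipation=rep.dissipation, matrix_fraction=mf, membrane_fraction=bf,
        interface_measure=iface, n_membrane_components=ncomp,
        characteristic_length=clen, granule_halo_means=halo)


def run_simulation(d: Domain, initial, cfg: SolverConfig, n_steps: int,
                   sinks=(), halo_shell: float = 0.5):
    """Advance ``n_steps`` from ``initial``, recording diagnostics.

    Diagnostics (mass, free energy split, dissipation, morphometrics) are
    recorded at step 0 and every ``cfg.record_every`` steps; each recorded
    state is also passed to every callback in ``sinks`` as ``sink(state, d)``.
    Returns ``(final_state, records)``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be ≥ 1")
    state = prepare_state(d, initial, cfg)
    records = [_record(d, state, cfg, halo_shell)]
    for sink in sinks:
        sink(state, d)
    for _ in range(n_steps):
        try:
            state = theta_step(d, state, cfg)
        except NewtonConvergenceError as err:
            raise NewtonConvergenceError(
                f"step {err.step}: {err}", residual=err.residual, step=err.step) from None
        if state.step % cfg.record_every == 0 or state.step == n_steps:
            records.append(_record(d, state, cfg, halo_shell))
            for sink in sinks:
                sink(state, d)
    return state, records
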