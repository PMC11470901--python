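"""Lagrangian densities, actions, Euler-Lagrange residuals and symmetries.

The field equations of every family in this package extremize an action
S = integral of L over space-time with density

    L = |d_t phi|^2 - c^2 |grad phi|^2 - V(phi, phi*)

for a registry of real potentials V:

* ``kg``          V = m^2 c^4 |phi|^2
* ``quartic``     V = c0 |phi|^2 plus the extra gradient term a3 |Lap phi|^2
                  (and the a2 |grad phi|^2 term in place of c^2)
* ``multilayer``  V = phi^dag (I + A1) phi per site, A2 as the gradient
                  coefficient (fields stacked over layers)
* ``tessellated`` sum of per-tile densities minus phi^dag G phi (the G term
                  enters the action with opposite sign to a potential, so
                  the Euler-Lagrange equation gains +G phi)

Extremizing gives d2phi/dt2 - c^2 Lap(phi) + dV/dphi* = 0, whose residual
along simulated trajectories is the master cross-module consistency check.
Every registry density is exactly invariant under the global phase map
phi -> e^{i alpha} phi (U(1)); the decoupled multilayer density is further
invariant under unitary layer rotations (U(N)), broken exactly when A1 does
not commute with the rotation.  The discrete translation/reflection
symmetries of a modulated long-range G are checked by permutation.

The registry is closed (no user callables), so realness and phase
invariance hold by construction.  The discrete energy uses the same spatial
stencil as the integrators; evaluated in the staggered (consecutive
snapshot) form it is the leapfrog scheme's shadow invariant and is
conserved to roundoff for the linear families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from cortifield.dynamics import (
    KGParams,
    MultilayerParams,
    MultilayerState,
    QuarticParams,
    _stacked_laplacian,
)
from cortifield.errors import SymmetryError
from cortifield.grid_fields import (
    FieldState,
    GridSpec,
    Trajectory,
    gradient_array,
    laplacian_array,
)

__all__ = [
    "LagrangianSpec",
    "lagrangian_density",
    "action",
    "euler_lagrange_residual",
    "energy",
    "energy_drift",
    "check_un_invariance",
    "check_discrete_symmetry",
]

_KINDS = ("kg", "quartic", "multilayer", "tessellated")


@dataclass(frozen=True)
class LagrangianSpec:
    """A density from the closed registry, bound to model coefficients.

    kind="kg"          params: KGParams
    kind="quartic"     params: QuarticParams
    kind="multilayer"  params: MultilayerParams
    kind="tessellated" params: KGParams (per-tile local dynamics) + G matrix
    """

    kind: str
    params: object
    G: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown Lagrangian kind {self.kind!r}")
        if self.kind == "tessellated" and self.G is None:
            raise ValueError("tessellated spec requires G")


def _grad_sq(arr: np.ndarray, grid: GridSpec) -> np.ndarray:
    gx, gy = gradient_array(arr, grid)
    return np.abs(gx) ** 2 + np.abs(gy) ** 2


def _stacked_grad_sq(arr: np.ndarray, grid: GridSpec) -> np.ndarray:
    total = np.zeros(arr.shape, dtype=float)
    for i in range(arr.shape[0]):
        total[i] = _grad_sq(arr[i], grid)
    return total


def lagrangian_density(state: Union[FieldState, MultilayerState],
                       spec: LagrangianSpec) -> np.ndarray:
    """Real density lattice; exactly U(1)-invariant for every registry kind."""
    if spec.kind == "kg":
        p: KGParams = spec.params
        kinetic = np.abs(state.phi_dot) ** 2
        grad = p.c**2 * _grad_sq(state.phi, state.grid)
        V = p.m**2 * p.c**4 * np.abs(state.phi) ** 2
        return kinetic - grad - V
    if spec.kind == "quartic":
        q: QuarticParams = spec.params
        kinetic = np.abs(state.phi_dot) ** 2
        grad = q.a2 * _grad_sq(state.phi, state.grid)
        curv = q.a3 * np.abs(laplacian_array(state.phi, state.grid)) ** 2
        V = q.c0 * np.abs(state.phi) ** 2
        return kinetic - grad - curv - V
    if spec.kind == "multilayer":
        m: MultilayerParams = spec.params
        phi = state.phi  # (layers, nx, ny)
        kinetic = np.sum(np.abs(state.phi_dot) ** 2, axis=0)
        grad = m.A2 * np.sum(_stacked_grad_sq(phi, state.grid), axis=0)
        I_plus_A1 = np.eye(m.n_layers) + m.A1
        V = np.einsum("axy,ab,bxy->xy", phi.conj(), I_plus_A1, phi).real
        return kinetic - grad - V
    if spec.kind == "tessellated":
        p = spec.params
        phi = state.phi
        kinetic = np.sum(np.abs(state.phi_dot) ** 2, axis=0)
        grad = p.c**2 * np.sum(_stacked_grad_sq(phi, state.grid), axis=0)
        V = p.m**2 * p.c**4 * np.sum(np.abs(phi) ** 2, axis=0)
        Gterm = np.einsum("axy,ab,bxy->xy", phi.conj(),
                          np.asarray(spec.G), phi).real
        return kinetic - grad - V + Gterm
    raise ValueError(spec.kind)


def action(traj: Trajectory, spec: LagrangianSpec) -> float:
    """Trapezoidal space-time integral of the density over the trajectory."""
    grid = traj[0].grid
    dens = [float(np.sum(lagrangian_density(s, spec))) * grid.dx * grid.dy
            for s in traj.states]
    return float(np.trapezoid(dens, traj.times))


def _rhs(spec: LagrangianSpec, phi: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Euler-Lagrange right-hand side d2phi/dt2 = rhs for the spec."""
    if spec.kind == "kg":
        p = spec.params
        return p.c**2 * laplacian_array(phi, grid) - p.m**2 * p.c**4 * phi
    if spec.kind == "quartic":
        q = spec.params
        lap = laplacian_array(phi, grid)
        return -q.c0 * phi + q.a2 * lap - q.a3 * laplacian_array(lap, grid)
    if spec.kind == "multilayer":
        m = spec.params
        I_plus_A1 = np.eye(m.n_layers) + m.A1
        return (m.A2 * _stacked_laplacian(phi, grid)
                - np.einsum("ab,bxy->axy", I_plus_A1, phi))
    if spec.kind == "tessellated":
        p = spec.params
        loc = (p.c**2 * _stacked_laplacian(phi, grid)
               - p.m**2 * p.c**4 * phi)
        return loc + np.einsum("ab,bxy->axy", np.asarray(spec.G, complex), phi)
    raise ValueError(spec.kind)


def euler_lagrange_residual(traj: Trajectory, spec: LagrangianSpec) -> float:
    """Max-norm residual of the field equation along the trajectory.

    d2phi/dt2 is the central second difference of consecutive snapshots;
    the right-hand side is evaluated analytically from the registry.  Small
    for trajectories produced by the matching integrator, converging to
    zero at second order in dt; large for a mismatched spec (that mismatch
    is the diagnostic, not an error).
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 snapshots")
    grid = traj[0].grid
    h = traj.dt * traj.stride
    worst = 0.0
    for n in range(1, len(traj) - 1):
        phi_tt = (traj[n + 1].phi - 2 * traj[n].phi + traj[n - 1].phi) / h**2
        res = phi_tt - _rhs(spec, traj[n].phi, grid)
        worst = max(worst, float(np.max(np.abs(res))))
    return worst


def energy(state: Union[FieldState, MultilayerState],
           spec: LagrangianSpec) -> float:
    """Instantaneous energy: sum over sites of (|phi_dot|^2 + gradient terms + V).

    The Legendre transform of the registry density; the gradient terms use
    the same stencils as the integrators.
    """
    grid = state.grid
    kin_plus = (2 * np.sum(np.abs(state.phi_dot) ** 2)
                - np.sum(lagrangian_density(state, spec)))
    return float(kin_plus) * grid.dx * grid.dy


def energy_drift(traj: Trajectory, spec: LagrangianSpec,
                 staggered: bool = True) -> float:
    """Max relative deviation of the discrete energy over the trajectory.

    With ``staggered=True`` (default, requires stride 1) the energy is
    evaluated in the leapfrog scheme's shadow form

        E_{n+1/2} = ||(phi_{n+1} - phi_n)/dt||^2 + Re<phi_{n+1}, A phi_n>

    (A the linear operator of the spec), which the scheme conserves to
    roundoff for the linear families.  With ``staggered=False`` the
    instantaneous :func:`energy` is used, which oscillates at O(dt^2).
    """
    grid = traj[0].grid
    cell = grid.dx * grid.dy
    if staggered:
        if traj.stride != 1:
            raise ValueError("staggered energy needs stride-1 snapshots")
        h = traj.dt
        vals = []
        for n in range(len(traj) - 1):
            a, b = traj[n].phi, traj[n + 1].phi
            kin = np.sum(np.abs((b - a) / h) ** 2)
            pot = -np.sum((b.conj() * _rhs(spec, a, grid)).real)
            vals.append((kin + pot) * cell)
        vals = np.asarray(vals)
    else:
        vals = np.array([energy(s, spec) for s in traj.states])
    scale = max(abs(float(vals[0])), 1e-300)
    return float(np.max(np.abs(vals - vals[0])) / scale)


@dataclass
class UNInvarianceReport:
    """Density change under a unitary layer rotation."""

    max_density_difference: float
    invariant: bool
    commutes: bool


def check_un_invariance(mstate: MultilayerState, spec: LagrangianSpec,
                        U: np.ndarray, tol: float = 1e-9) -> UNInvarianceReport:
    """Compare the multilayer density before/after the layer rotation U.

    Scalar A1 (or any A1 commuting with U) leaves the density invariant;
    a generic non-commuting A1 breaks the U(N) symmetry and the report
    shows a nonzero difference.
    """
    U = np.asarray(U)
    if not np.allclose(U @ U.conj().T, np.eye(U.shape[0]), atol=1e-9):
        raise ValueError("U must be unitary")
    if spec.kind != "multilayer":
        raise ValueError("U(N) check applies to the multilayer spec")
    rotated = mstate.copy()
    rotated.phi = np.einsum("ab,bxy->axy", U, mstate.phi)
    rotated.phi_dot = np.einsum("ab,bxy->axy", U, mstate.phi_dot)
    d0 = lagrangian_density(mstate, spec)
    d1 = lagrangian_density(rotated, spec)
    diff = float(np.max(np.abs(d1 - d0)))
    A = np.asarray(spec.params.A1)
    commutes = bool(np.allclose(U @ A, A @ U, atol=1e-9))
    return UNInvarianceReport(max_density_difference=diff,
                              invariant=diff < tol, commutes=commutes)


def check_discrete_symmetry(G: np.ndarray, transform: np.ndarray,
                            tol: float = 1e-10) -> bool:
    """True iff the tile permutation leaves G invariant: G[p][:, p] == G.

    ``transform`` is a permutation array p of tile indices.  Translations
    of a periodically modulated G are symmetries on a periodic tiling but
    are broken by an open boundary; central reflections survive both.
    """
    p = np.asarray(transform)
    n = G.shape[0]
    if sorted(p.tolist()) != list(range(n)):
        raise ValueError("transform must be a permutation of tile indices")
    return bool(np.allclose(G[np.ix_(p, p)], G, atol=tol))
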