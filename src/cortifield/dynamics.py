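"""Explicit leapfrog time integrators for the cortical field equations.

Four PDE families share one Stormer-Verlet (velocity-Verlet) scheme on
``(phi, phi_dot)``:

* Klein-Gordon:      d2phi/dt2 = c^2 Lap(phi) - m^2 c^4 phi
* quartic:           d2phi/dt2 = -(a0^2+a1) phi + a2 Lap(phi) - a3 LapLap(phi)
* limit cycle:       d2phi/dt2 = -phi + c1 Lap(phi) - i (c2 phi + c3 phi |phi|^2)
* multilayer:        d2phi/dt2 = -(I + A1) phi + A2 Lap(phi)   (layer-coupled)
* tessellated:       d2phi/dt2 = L(phi) + G phi                (tile-coupled)

The scheme is second order and symplectic for the linear/Hamiltonian cases,
so the discrete energy tracked by the symmetry module is a shadow invariant.
The first-order complex form (intrinsic rotation -i*phi) is not a separate
integrator; it is recovered as the c=0 Klein-Gordon limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
import warnings

from cortifield.errors import (
    DivergenceError,
    StabilityError,
    SymmetryError,
)
from cortifield.grid_fields import (
    FieldState,
    GridSpec,
    IntegrityError,
    Trajectory,
    laplacian_array,
    max_laplacian_eigenvalue,
)

__all__ = [
    "KGParams",
    "QuarticParams",
    "LimitCycleParams",
    "MultilayerParams",
    "MultilayerState",
    "stable_dt",
    "integrate_kg",
    "integrate_quartic",
    "integrate_limit_cycle",
    "integrate_multilayer",
    "integrate_tessellated",
]

SAFETY_FACTOR = 0.5
#: fallback step for free fields (no restoring or propagating terms at all)
FREE_FIELD_DT = 1.0
#: |phi| beyond which the nonlinear integrator declares blow-up
DIVERGENCE_THRESHOLD = 1.0e6


@dataclass(frozen=True)
class KGParams:
    """Klein-Gordon coefficients: wave speed c and mass term m.

    The composite constants of the underlying expansion are absorbed:
    c^2 = -2iBa1 (required negative-imaginary, hence real c^2 > 0) and
    m^2 c^4 = 1 + 2iAa1 (required >= 0); only the derived (c, m) pair is
    exposed.
    """

    c: float = 1.0
    m: float = 0.0

    def __post_init__(self):
        if self.c < 0 or self.m < 0:
            raise ValueError("c and m must be nonnegative")


@dataclass(frozen=True)
class QuarticParams:
    """Coefficients of the quartic-spatial-order field equation.

    d2phi/dt2 = -(a0^2+a1) phi + a2 Lap(phi) - a3 LapLap(phi).
    ``c0`` is the constant restoring term a0^2+a1 (alias C0); a2, a3 alias
    C1, C2.  a2, a3 >= 0 keeps omega^2 >= 0 at all k.
    """

    c0: float = 1.0
    a2: float = 1.0
    a3: float = 0.0

    def __post_init__(self):
        if self.a2 < 0 or self.a3 < 0:
            raise ValueError("a2 and a3 must be nonnegative for omega^2 >= 0")

    # aliases matching the C-naming of the dispersion relation
    @property
    def C0(self) -> float:
        return self.c0

    @property
    def C1(self) -> float:
        return self.a2

    @property
    def C2(self) -> float:
        return self.a3


@dataclass(frozen=True)
class LimitCycleParams:
    """Coefficients of the cubic limit-cycle field equation.

    d2phi/dt2 = -phi + c1 Lap(phi) - i (c2 phi + c3 phi |phi|^2).
    A finite limit-cycle radius sqrt(-c2/c3) requires c2/c3 < 0; the
    constructor warns (not errors) otherwise so the quiescent regime can
    still be explored.
    """

    c1: float = 1.0
    c2: float = -1.0
    c3: float = 1.0

    def __post_init__(self):
        if self.c1 < 0:
            raise ValueError("spatial coupling c1 must be nonnegative")
        if self.c3 != 0 and self.c2 / self.c3 >= 0:
            warnings.warn(
                "c2/c3 >= 0: no finite-radius limit cycle exists", stacklevel=2
            )


class MultilayerParams:
    """Layer-coupled wave field: d2phi/dt2 = -(I + A1) phi + A2 Lap(phi).

    A1 is the intrinsic (mass-like) layer-coupling matrix; A2 a nonnegative
    scalar within-layer spatial coupling.  When A1 is Hermitian the system
    decouples through a unitary U with U^dag (I + A1) U = diag(D), D real.
    """

    def __init__(self, A1: np.ndarray, A2: float = 1.0):
        A1 = np.atleast_2d(np.asarray(A1, dtype=np.complex128))
        if A1.shape[0] != A1.shape[1]:
            raise ValueError("A1 must be square")
        if A2 < 0:
            raise ValueError("A2 must be nonnegative")
        self.A1 = A1
        self.A2 = float(A2)
        self.n_layers = A1.shape[0]
        self._U: Optional[np.ndarray] = None
        self._D: Optional[np.ndarray] = None

    @property
    def is_hermitian(self) -> bool:
        return bool(np.allclose(self.A1, self.A1.conj().T, atol=1e-12))

    def diagonalize(self) -> Tuple[np.ndarray, np.ndarray]:
        """Return (U, D) with U^dag (I + A1) U = diag(D), D real ascending."""
        if not self.is_hermitian:
            raise SymmetryError("A1 must be Hermitian to diagonalize")
        if self._U is None:
            D, U = np.linalg.eigh(np.eye(self.n_layers) + self.A1)
            self._U, self._D = U, D
        return self._U, self._D

    @property
    def U(self) -> np.ndarray:
        return self.diagonalize()[0]

    @property
    def D(self) -> np.ndarray:
        return self.diagonalize()[1]


@dataclass
class MultilayerState:
    """Stacked per-layer complex fields; layer index first: (n_layers, nx, ny)."""

    grid: GridSpec
    phi: np.ndarray
    phi_dot: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=np.complex128)
        self.phi_dot = np.asarray(self.phi_dot, dtype=np.complex128)
        expected_tail = self.grid.shape
        if self.phi.ndim != 3 or self.phi.shape[1:] != expected_tail:
            raise IntegrityError(
                f"phi shape {self.phi.shape} incompatible with grid {expected_tail}"
            )
        if self.phi_dot.shape != self.phi.shape:
            raise IntegrityError("phi_dot shape differs from phi shape")

    @property
    def n_layers(self) -> int:
        return self.phi.shape[0]

    def layer(self, i: int) -> FieldState:
        return FieldState(self.grid, self.phi[i].copy(), self.phi_dot[i].copy(), self.t)

    def copy(self) -> "MultilayerState":
        return MultilayerState(self.grid, self.phi.copy(), self.phi_dot.copy(), self.t)


def _stacked_laplacian(arr: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Laplacian over the trailing two axes of an (n, nx, ny) stack."""
    if grid.boundary == "periodic":
        p = np.pad(arr, ((0, 0), (1, 1), (1, 1)), mode="wrap")
    else:
        p = np.pad(arr, ((0, 0), (1, 1), (1, 1)), mode="reflect")
    core = p[:, 1:-1, 1:-1]
    return (p[:, 2:, 1:-1] - 2.0 * core + p[:, :-2, 1:-1]) / grid.dx**2 + (
        p[:, 1:-1, 2:] - 2.0 * core + p[:, 1:-1, :-2]
    ) / grid.dy**2


# ---------------------------------------------------------------------------
# Stability


def _omega_max_sq(params, grid: GridSpec, G: Optional[np.ndarray] = None) -> float:
    """Upper bound on omega^2 over the grid's representable wavenumbers."""
    lam = max_laplacian_eigenvalue(grid)  # max eigenvalue of -Laplacian
    if isinstance(params, KGParams):
        return params.c**2 * lam + params.m**2 * params.c**4
    if isinstance(params, QuarticParams):
        return abs(params.c0) + params.a2 * lam + params.a3 * lam**2
    if isinstance(params, LimitCycleParams):
        # linearization around amplitudes up to the limit-cycle radius
        amp2 = -params.c2 / params.c3 if (params.c3 != 0 and params.c2 / params.c3 < 0) else 1.0
        return 1.0 + params.c1 * lam + abs(params.c2) + 3.0 * abs(params.c3) * amp2
    if isinstance(params, MultilayerParams):
        I_plus_A1 = np.eye(params.n_layers) + params.A1
        mu = float(np.max(np.abs(np.linalg.eigvals(I_plus_A1))))
        w2 = params.A2 * lam + mu
    else:
        raise TypeError(f"unsupported params type {type(params)!r}")
    return w2


def stable_dt(params, grid: GridSpec, G: Optional[np.ndarray] = None) -> float:
    """Largest linearly stable explicit step, times the safety factor.

    Leapfrog on d2q/dt2 = -omega^2 q is stable for dt*omega <= 2, so the
    bound is ``SAFETY_FACTOR * 2 / omega_max`` with omega_max taken over the
    grid's representable wavenumbers (and, for tessellated runs, shifted by
    the spectral norm of G).
    """
    w2 = _omega_max_sq(params, grid)
    if G is not None:
        w2 += float(np.linalg.norm(np.asarray(G), 2))
    if w2 <= 0.0:
        return FREE_FIELD_DT
    return SAFETY_FACTOR * 2.0 / np.sqrt(w2)


def _check_dt(dt: float, params, grid: GridSpec, G=None) -> None:
    limit = stable_dt(params, grid, G) / SAFETY_FACTOR  # raw CFL bound
    if dt > limit * (1.0 + 1e-12):
        raise StabilityError(
            f"dt={dt:g} exceeds the stability bound {limit:g} for this model/grid"
        )


# ---------------------------------------------------------------------------
# Generic leapfrog driver


def _leapfrog(state, rhs: Callable, dt: float, n_steps: int, stride: int,
              divergence_check: bool = False) -> list:
    """Velocity-Verlet on (phi, phi_dot); returns snapshots every `stride` steps."""
    phi = state.phi.copy()
    phi_dot = state.phi_dot.copy()
    t = state.t
    snapshots = [state.copy()]
    acc = rhs(phi)
    for step in range(1, n_steps + 1):
        phi_dot_half = phi_dot + 0.5 * dt * acc
        phi = phi + dt * phi_dot_half
        acc = rhs(phi)
        phi_dot = phi_dot_half + 0.5 * dt * acc
        t = state.t + step * dt
        if divergence_check and not np.all(np.abs(phi) < DIVERGENCE_THRESHOLD):
            raise DivergenceError(f"|phi| exceeded {DIVERGENCE_THRESHOLD:g} at t={t:g}",
                                  t_blowup=t)
        if step % stride == 0:
            snap = state.copy()
            snap.phi = phi.copy()
            snap.phi_dot = phi_dot.copy()
            snap.t = t
            snapshots.append(snap)
    return snapshots


# ---------------------------------------------------------------------------
# Integrators


def integrate_kg(state: FieldState, params: KGParams, dt: float, n_steps: int,
                 stride: int = 1) -> Trajectory:
    """Integrate the Klein-Gordon field d2phi/dt2 = c^2 Lap(phi) - m^2 c^4 phi."""
    _check_dt(dt, params, state.grid)
    c2 = params.c**2
    m2c4 = params.m**2 * params.c**4
    grid = state.grid

    def rhs(phi):
        return c2 * laplacian_array(phi, grid) - m2c4 * phi

    return Trajectory(_leapfrog(state, rhs, dt, n_steps, stride), dt, stride)


def integrate_quartic(state: FieldState, params: QuarticParams, dt: float,
                      n_steps: int, stride: int = 1) -> Trajectory:
    """Integrate the quartic-order field equation.

    With a3 = 0 this is bit-compatible with :func:`integrate_kg` at
    c^2 = a2, m^2 c^4 = c0 (the Laplacian term is computed identically and
    the biharmonic term is skipped entirely).
    """
    _check_dt(dt, params, state.grid)
    grid = state.grid
    c0, a2, a3 = params.c0, params.a2, params.a3

    if a3 == 0.0:
        def rhs(phi):
            return a2 * laplacian_array(phi, grid) - c0 * phi
    else:
        def rhs(phi):
            lap = laplacian_array(phi, grid)
            return -c0 * phi + a2 * lap - a3 * laplacian_array(lap, grid)

    return Trajectory(_leapfrog(state, rhs, dt, n_steps, stride), dt, stride)


def integrate_limit_cycle(state: FieldState, params: LimitCycleParams, dt: float,
                          n_steps: int, stride: int = 1) -> Trajectory:
    """Integrate the nonlinear limit-cycle field.

    d2phi/dt2 = -phi + c1 Lap(phi) - i (c2 phi + c3 phi |phi|^2).
    Every right-hand-side term carries exactly one factor of phi, so the
    dynamics are U(1)-equivariant: rotating the initial condition by a
    global phase rotates the whole trajectory.  The cubic term is evaluated
    explicitly; blow-up raises :class:`DivergenceError` with the first
    blow-up time.
    """
    _check_dt(dt, params, state.grid)
    grid = state.grid
    c1, c2, c3 = params.c1, params.c2, params.c3

    def rhs(phi):
        return (-phi + c1 * laplacian_array(phi, grid)
                - 1j * (c2 * phi + c3 * phi * np.abs(phi) ** 2))

    return Trajectory(
        _leapfrog(state, rhs, dt, n_steps, stride, divergence_check=True), dt, stride
    )


def integrate_multilayer(state: MultilayerState, params: MultilayerParams, dt: float,
                         n_steps: int, stride: int = 1,
                         mode: str = "direct") -> Trajectory:
    """Integrate the layer-coupled wave field.

    mode="direct" evolves d2phi/dt2 = -(I + A1) phi + A2 Lap(phi) with the
    layer coupling applied at every step.  mode="diagonalized" transforms to
    the eigenbasis of I + A1 (requires Hermitian A1), evolves the decoupled
    scalar fields d2phi'/dt2 = A2 Lap(phi') - D phi', and transforms back;
    snapshots are reported in the original layer basis in both modes.
    """
    if state.n_layers != params.n_layers:
        raise IntegrityError(
            f"state has {state.n_layers} layers, params expect {params.n_layers}"
        )
    _check_dt(dt, params, state.grid)
    grid = state.grid
    A2 = params.A2

    if mode == "direct":
        I_plus_A1 = np.eye(params.n_layers) + params.A1

        def rhs(phi):
            return (A2 * _stacked_laplacian(phi, grid)
                    - np.einsum("ab,bxy->axy", I_plus_A1, phi))

        return Trajectory(_leapfrog(state, rhs, dt, n_steps, stride), dt, stride)

    if mode == "diagonalized":
        U, D = params.diagonalize()  # SymmetryError if A1 not Hermitian
        Udag = U.conj().T
        prime = state.copy()
        prime.phi = np.einsum("ab,bxy->axy", Udag, state.phi)
        prime.phi_dot = np.einsum("ab,bxy->axy", Udag, state.phi_dot)

        def rhs_prime(phi):
            return A2 * _stacked_laplacian(phi, grid) - D[:, None, None] * phi

        snaps = _leapfrog(prime, rhs_prime, dt, n_steps, stride)
        for s in snaps:
            s.phi = np.einsum("ab,bxy->axy", U, s.phi)
            s.phi_dot = np.einsum("ab,bxy->axy", U, s.phi_dot)
        return Trajectory(snaps, dt, stride)

    raise ValueError(f"unknown mode {mode!r}")


LocalOp = Union[KGParams, QuarticParams]


def _local_rhs(local_op: LocalOp, grid: GridSpec) -> Callable:
    """Stacked right-hand side of a linear local operator (KG or quartic)."""
    if isinstance(local_op, KGParams):
        c2 = local_op.c**2
        m2c4 = local_op.m**2 * local_op.c**4

        def rhs(phi):
            return c2 * _stacked_laplacian(phi, grid) - m2c4 * phi

        return rhs
    if isinstance(local_op, QuarticParams):
        c0, a2, a3 = local_op.c0, local_op.a2, local_op.a3

        def rhs(phi):
            lap = _stacked_laplacian(phi, grid)
            out = -c0 * phi + a2 * lap
            if a3 != 0.0:
                out -= a3 * _stacked_laplacian(lap, grid)
            return out

        return rhs
    raise TypeError("local_op must be KGParams or QuarticParams")


def integrate_tessellated(states: Sequence[FieldState], local_op: LocalOp,
                          G: np.ndarray, dt: float, n_steps: int,
                          stride: int = 1) -> Trajectory:
    """Integrate tile fields coupled through the long-range matrix G.

    d2phi_a/dt2 = L(phi_a) + sum_b G[a,b] phi_b, where L is the shared
    linear local operator and G acts on the tile index, identity on lattice
    sites.  All tiles must share one GridSpec; G must be n_tiles x n_tiles.
    Snapshots are :class:`MultilayerState` stacks with layer = tile.
    """
    G = np.asarray(G)
    n_tiles = len(states)
    if G.shape != (n_tiles, n_tiles):
        raise IntegrityError(f"G shape {G.shape} != ({n_tiles}, {n_tiles})")
    grid = states[0].grid
    for s in states[1:]:
        if s.grid != grid:
            raise IntegrityError("all tiles must share one GridSpec")
    _check_dt(dt, local_op, grid, G=G)
    stacked = MultilayerState(
        grid,
        np.stack([s.phi for s in states]),
        np.stack([s.phi_dot for s in states]),
        t=states[0].t,
    )
    local = _local_rhs(local_op, grid)
    Gc = G.astype(np.complex128)

    def rhs(phi):
        return local(phi) + np.einsum("ab,bxy->axy", Gc, phi)

    return Trajectory(_leapfrog(stacked, rhs, dt, n_steps, stride), dt, stride)
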