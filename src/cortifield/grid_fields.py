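"""Lattice and field containers, spatial stencils, and HDF5 state I/O.

Conventions used throughout the package:

* A field array has shape ``(nx, ny)``; axis 0 is x, axis 1 is y.
* Site ``(i, j)`` sits at ``origin + (i*dx, j*dy)``; 0-based, row-major.
* All quantities are nondimensional (model units); the spectra module owns
  the optional mapping of model frequency to Hz.
* ``Re(phi)`` is excitatory activity, ``Im(phi)`` inhibitory activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Literal, Tuple

import h5py
import numpy as np

from cortifield.errors import FormatError, IntegrityError

Boundary = Literal["periodic", "reflecting"]

__all__ = [
    "GridSpec",
    "FieldState",
    "Trajectory",
    "laplacian",
    "laplacian_array",
    "biharmonic",
    "gradient_array",
    "max_laplacian_eigenvalue",
    "save_state",
    "load_state",
    "save_trajectory",
    "load_trajectory",
]


@dataclass(frozen=True)
class GridSpec:
    """Uniform rectangular lattice on the flat cortical sheet.

    Parameters
    ----------
    nx, ny : int
        Lattice extents; at least 3 so stencils have interior points.
    dx, dy : float
        Positive lattice spacings (nondimensional length units).
    boundary : {"periodic", "reflecting"}
        Boundary handling for the spatial stencils.  Periodic matches the
        plane-wave analysis; reflecting (zero-flux mirror) is available for
        front experiments.
    origin : (float, float)
        Physical coordinates of site (0, 0).
    """

    nx: int
    ny: int
    dx: float = 1.0
    dy: float = 1.0
    boundary: Boundary = "periodic"
    origin: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.nx < 3 or self.ny < 3:
            raise ValueError(f"grid must be at least 3x3, got {self.nx}x{self.ny}")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("dx and dy must be positive")
        if self.boundary not in ("periodic", "reflecting"):
            raise ValueError(f"unknown boundary {self.boundary!r}")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.nx, self.ny)

    def coords(self) -> Tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (x, y) of site coordinates, shape (nx, ny)."""
        x = self.origin[0] + self.dx * np.arange(self.nx)
        y = self.origin[1] + self.dy * np.arange(self.ny)
        return np.meshgrid(x, y, indexing="ij")


@dataclass
class FieldState:
    """Complex field phi and its time derivative on a grid at time t.

    All governing equations are second order in time, so the state carries
    both ``phi`` and ``phi_dot``.
    """

    grid: GridSpec
    phi: np.ndarray
    phi_dot: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=np.complex128)
        self.phi_dot = np.asarray(self.phi_dot, dtype=np.complex128)
        if self.phi.shape != self.grid.shape:
            raise IntegrityError(
                f"phi shape {self.phi.shape} != grid shape {self.grid.shape}"
            )
        if self.phi_dot.shape != self.grid.shape:
            raise IntegrityError(
                f"phi_dot shape {self.phi_dot.shape} != grid shape {self.grid.shape}"
            )
        if not (np.all(np.isfinite(self.phi)) and np.all(np.isfinite(self.phi_dot))):
            raise ValueError("phi/phi_dot must be finite everywhere")

    @property
    def u_e(self) -> np.ndarray:
        """Excitatory activity (real part of phi)."""
        return self.phi.real

    @property
    def u_i(self) -> np.ndarray:
        """Inhibitory activity (imaginary part of phi)."""
        return self.phi.imag

    def copy(self) -> "FieldState":
        return FieldState(self.grid, self.phi.copy(), self.phi_dot.copy(), self.t)


@dataclass
class Trajectory:
    """Time-ordered field snapshots recorded at a uniform stride.

    ``states[n].t == states[0].t + n * dt * stride`` up to roundoff.
    """

    states: List
    dt: float
    stride: int = 1

    def __post_init__(self):
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        times = self.times
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("snapshot times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i):
        return self.states[i]


# ---------------------------------------------------------------------------
# Spatial stencils


def _pad(arr: np.ndarray, boundary: Boundary) -> np.ndarray:
    if boundary == "periodic":
        return np.pad(arr, 1, mode="wrap")
    # zero-flux mirror: ghost equals the first interior neighbour
    return np.pad(arr, 1, mode="reflect")


def laplacian_array(arr: np.ndarray, grid: GridSpec) -> np.ndarray:
    """5-point discrete Laplacian of an (nx, ny) array under grid's boundary."""
    p = _pad(arr, grid.boundary)
    core = p[1:-1, 1:-1]
    return (p[2:, 1:-1] - 2.0 * core + p[:-2, 1:-1]) / grid.dx**2 + (
        p[1:-1, 2:] - 2.0 * core + p[1:-1, :-2]
    ) / grid.dy**2


def laplacian(state: FieldState) -> np.ndarray:
    """Discrete Laplacian of the state's phi (5-point stencil)."""
    return laplacian_array(state.phi, state.grid)


def biharmonic(state: FieldState) -> np.ndarray:
    """Discrete biharmonic: the 5-point Laplacian applied twice."""
    return laplacian_array(laplacian(state), state.grid)


def gradient_array(arr: np.ndarray, grid: GridSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient (d/dx, d/dy) under the grid's boundary."""
    p = _pad(arr, grid.boundary)
    gx = (p[2:, 1:-1] - p[:-2, 1:-1]) / (2.0 * grid.dx)
    gy = (p[1:-1, 2:] - p[1:-1, :-2]) / (2.0 * grid.dy)
    return gx, gy


def max_laplacian_eigenvalue(grid: GridSpec) -> float:
    """Largest eigenvalue magnitude of -Laplacian on this grid.

    For the 5-point stencil the spectrum of -Delta is bounded by
    4/dx^2 + 4/dy^2 (attained at the checkerboard mode on periodic grids);
    used by the CFL bound.
    """
    return 4.0 / grid.dx**2 + 4.0 / grid.dy**2


# ---------------------------------------------------------------------------
# HDF5 I/O

_STATE_DATASETS = ("phi_real", "phi_imag", "phi_dot_real", "phi_dot_imag")


def _write_state_group(g, state: FieldState) -> None:
    # track_times=False keeps the container byte-deterministic across runs
    g.create_dataset("phi_real", data=state.phi.real, track_times=False)
    g.create_dataset("phi_imag", data=state.phi.imag, track_times=False)
    g.create_dataset("phi_dot_real", data=state.phi_dot.real, track_times=False)
    g.create_dataset("phi_dot_imag", data=state.phi_dot.imag, track_times=False)
    g.attrs["nx"] = state.grid.nx
    g.attrs["ny"] = state.grid.ny
    g.attrs["dx"] = state.grid.dx
    g.attrs["dy"] = state.grid.dy
    g.attrs["boundary"] = state.grid.boundary
    g.attrs["origin"] = list(state.grid.origin)
    g.attrs["t"] = state.t


def _read_state_group(g) -> FieldState:
    for name in _STATE_DATASETS:
        if name not in g:
            raise FormatError(f"missing dataset {name!r}")
    for attr in ("nx", "ny", "dx", "dy", "boundary", "origin", "t"):
        if attr not in g.attrs:
            raise FormatError(f"missing attribute {attr!r}")
    grid = GridSpec(
        nx=int(g.attrs["nx"]),
        ny=int(g.attrs["ny"]),
        dx=float(g.attrs["dx"]),
        dy=float(g.attrs["dy"]),
        boundary=str(g.attrs["boundary"]),
        origin=tuple(float(v) for v in g.attrs["origin"]),
    )
    arrs = {}
    for name in _STATE_DATASETS:
        a = np.asarray(g[name])
        if a.shape != grid.shape:
            raise IntegrityError(
                f"dataset {name!r} has shape {a.shape}, grid attributes say {grid.shape}"
            )
        arrs[name] = a
    phi = arrs["phi_real"] + 1j * arrs["phi_imag"]
    phi_dot = arrs["phi_dot_real"] + 1j * arrs["phi_dot_imag"]
    return FieldState(grid, phi, phi_dot, t=float(g.attrs["t"]))


def save_state(state: FieldState, path) -> None:
    """Write a FieldState to an HDF5 file (bit-exact round trip)."""
    with h5py.File(path, "w") as f:
        _write_state_group(f, state)


def load_state(path) -> FieldState:
    """Read a FieldState written by :func:`save_state`."""
    with h5py.File(path, "r") as f:
        return _read_state_group(f)


def save_trajectory(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["dt"] = traj.dt
        f.attrs["stride"] = traj.stride
        f.attrs["n_states"] = len(traj)
        for n, s in enumerate(traj.states):
            _write_state_group(f.create_group(f"state_{n:06d}"), s)


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        if "n_states" not in f.attrs:
            raise FormatError("missing attribute 'n_states'")
        n_states = int(f.attrs["n_states"])
        states = [_read_state_group(f[f"state_{n:06d}"]) for n in range(n_states)]
        return Trajectory(states, dt=float(f.attrs["dt"]), stride=int(f.attrs["stride"]))
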