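"""Polar-coordinate analysis of the limit-cycle field.

Writing phi = r e^{i theta} turns the cubic field equation

    d2phi/dt2 = -phi + c1 Lap(phi) - i (c2 phi + c3 phi |phi|^2)

into two real equations (the amplitude/phase cross terms carry a factor 2,
as the polar expansion of the complex Laplacian and second time derivative
requires),

    r th_tt + 2 r_t th_t = c1 (r Lap(th) + 2 grad r . grad th) - (c2 r + c3 r^3)
    -r th_t^2 + r_tt     = -r + c1 (-r |grad th|^2 + Lap r)

When the bracketed amplitude term vanishes (r = sqrt(-c2/c3), the limit-cycle
radius) the phase obeys a wave equation th_tt = c1 Lap(th) together with the
eikonal constraint -1 = th_t^2 - c1 |grad th|^2.  Plane-slope solutions
th_p = b1 (t-t0) + b2 (x-x0) + b3 (y-y0) satisfy both when
b1 = +-sqrt(1 + c1 (b2^2 + b3^2)); harmonic plane waves with
omega^2 = c1 |k|^2 can be superposed on top.  The phase-front speed of the
slope solution is |b| / sqrt(1 + c1 |b|^2), bounded by 1/sqrt(c1).

A caution on stability, established numerically in this package: the
second-order field equation above does *not* attract perturbed states back
to the limit-cycle radius — the homogeneous cycle has a linearly unstable
breathing mode (the collapse to a purely imaginary nonlinear coefficient
drops the contracting terms of the underlying first-order flow).
:func:`probe_stability` measures the actual growth/decay rate instead of
assuming decay; analysis windows elsewhere are kept short.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from cortifield.dynamics import LimitCycleParams, integrate_limit_cycle, stable_dt
from cortifield.errors import (
    ConstraintError,
    DivergenceError,
    NoLimitCycleError,
)
from cortifield.grid_fields import (
    FieldState,
    GridSpec,
    Trajectory,
    gradient_array,
    laplacian_array,
)

__all__ = [
    "PolarField",
    "PhasePlaneWave",
    "Harmonic",
    "StabilityProbe",
    "to_polar",
    "from_polar",
    "steady_radius",
    "build_phase_solution",
    "phase_front_speed",
    "render_phase_field",
    "polar_residuals",
    "probe_stability",
]

#: sites with amplitude below eps_frac * (typical radius) carry a masked phase
EPS_FRAC = 1e-6


@dataclass
class PolarField:
    """Amplitude r and unwrapped phase theta lattices (plus time derivatives).

    ``mask`` is True where the amplitude was too small for the phase to be
    meaningful; theta is NaN there.
    """

    grid: GridSpec
    r: np.ndarray
    theta: np.ndarray
    r_dot: np.ndarray
    theta_dot: np.ndarray
    t: float = 0.0
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        if np.any(self.r[~np.isnan(self.r)] < 0):
            raise ValueError("amplitude r must be nonnegative")


def _unwrap2d(angle: np.ndarray) -> np.ndarray:
    """Row-then-column 1D unwrap; valid for smooth (long-wavelength) phases."""
    return np.unwrap(np.unwrap(angle, axis=0), axis=1)


def to_polar(state: FieldState, eps: Optional[float] = None) -> PolarField:
    """Convert phi = r e^{i theta} with spatial phase unwrapping.

    Sites with |phi| <= eps (default ``EPS_FRAC`` times the median amplitude)
    get a masked (NaN) phase; no error is raised.
    """
    r = np.abs(state.phi)
    if eps is None:
        eps = EPS_FRAC * max(float(np.median(r)), 1e-300)
    mask = r <= eps
    theta = _unwrap2d(np.angle(state.phi))
    # phi_dot = (r_dot + i r theta_dot) e^{i theta}
    w = state.phi_dot * np.exp(-1j * theta)
    r_dot = w.real
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_dot = np.where(mask, np.nan, w.imag / np.where(mask, 1.0, r))
    theta = np.where(mask, np.nan, theta)
    return PolarField(state.grid, r, theta, r_dot, theta_dot, t=state.t, mask=mask)


def from_polar(p: PolarField) -> FieldState:
    """Inverse of :func:`to_polar` wherever the phase is unmasked."""
    theta = np.where(np.isnan(p.theta), 0.0, p.theta)
    theta_dot = np.where(np.isnan(p.theta_dot), 0.0, p.theta_dot)
    phase = np.exp(1j * theta)
    phi = p.r * phase
    phi_dot = (p.r_dot + 1j * p.r * theta_dot) * phase
    return FieldState(p.grid, phi, phi_dot, t=p.t)


def steady_radius(params: LimitCycleParams) -> float:
    """Limit-cycle radius sqrt(-c2/c3); errors when c2/c3 >= 0."""
    if params.c3 == 0 or params.c2 / params.c3 >= 0:
        raise NoLimitCycleError(
            f"c2/c3 must be negative for a finite limit cycle, got c2={params.c2}, "
            f"c3={params.c3}"
        )
    return float(np.sqrt(-params.c2 / params.c3))


@dataclass(frozen=True)
class Harmonic:
    """One plane-wave phase component A0 cos(omega t - k.r + phase0).

    Must satisfy the phase wave equation's dispersion omega^2 = c1 |k|^2.
    """

    A0: float
    omega: float
    kx: float
    ky: float
    phase0: float = 0.0


@dataclass
class PhasePlaneWave:
    """Phase solution th = th_p + sum of harmonics.

    th_p = b1 (t-t0) + b2 (x-x0) + b3 (y-y0) with b1 fixed by the eikonal
    constraint b1^2 = 1 + c1 (b2^2 + b3^2) (branch sign selectable).
    """

    b1: float
    b2: float
    b3: float
    c1: float
    t0: float = 0.0
    x0: float = 0.0
    y0: float = 0.0
    harmonics: List[Harmonic] = field(default_factory=list)

    def theta(self, grid: GridSpec, t: float) -> np.ndarray:
        x, y = grid.coords()
        th = (self.b1 * (t - self.t0) + self.b2 * (x - self.x0)
              + self.b3 * (y - self.y0))
        for h in self.harmonics:
            th = th + h.A0 * np.cos(h.omega * t - h.kx * x - h.ky * y + h.phase0)
        return th

    def theta_dot(self, grid: GridSpec, t: float) -> np.ndarray:
        x, y = grid.coords()
        thd = np.full(grid.shape, self.b1, dtype=float)
        for h in self.harmonics:
            thd = thd - h.A0 * h.omega * np.sin(
                h.omega * t - h.kx * x - h.ky * y + h.phase0
            )
        return thd


def build_phase_solution(b2: float, b3: float,
                         harmonics: Sequence[Harmonic] = (),
                         params: Optional[LimitCycleParams] = None,
                         branch: int = +1,
                         dispersion_rtol: float = 1e-9,
                         **offsets) -> PhasePlaneWave:
    """Construct a phase solution with b1 from the eikonal constraint.

    Each harmonic must satisfy omega^2 = c1 |k|^2 to relative tolerance
    ``dispersion_rtol`` or a :class:`ConstraintError` is raised.  ``branch``
    selects the sign of b1 (default +).
    """
    c1 = params.c1 if params is not None else 1.0
    if branch not in (+1, -1):
        raise ValueError("branch must be +1 or -1")
    for h in harmonics:
        lhs, rhs = h.omega**2, c1 * (h.kx**2 + h.ky**2)
        scale = max(abs(lhs), abs(rhs), 1e-300)
        if abs(lhs - rhs) > dispersion_rtol * scale:
            raise ConstraintError(
                f"harmonic omega^2={lhs:g} != c1|k|^2={rhs:g}"
            )
    b1 = branch * float(np.sqrt(1.0 + c1 * (b2**2 + b3**2)))
    return PhasePlaneWave(b1=b1, b2=b2, b3=b3, c1=c1,
                          harmonics=list(harmonics), **offsets)


def phase_front_speed(b2: float, b3: float, params: LimitCycleParams) -> float:
    """Speed |b| / sqrt(1 + c1 |b|^2) of the plane-slope phase front.

    Monotone increasing in |b| = sqrt(b2^2+b3^2) and bounded above by
    1/sqrt(c1).  Undefined (error) for zero spatial slope.
    """
    b_sq = b2**2 + b3**2
    if b_sq == 0:
        raise ValueError("front speed undefined for zero spatial slope")
    return float(np.sqrt(b_sq) / np.sqrt(1.0 + params.c1 * b_sq))


def render_phase_field(sol: PhasePlaneWave, grid: GridSpec, t: float = 0.0,
                       radius: float = 1.0) -> FieldState:
    """Field phi = radius * e^{i theta(sol)} with the matching phi_dot."""
    th = sol.theta(grid, t)
    thd = sol.theta_dot(grid, t)
    phi = radius * np.exp(1j * th)
    return FieldState(grid, phi, 1j * thd * phi, t=t)


def polar_residuals(traj: Trajectory, params: LimitCycleParams,
                    eps: Optional[float] = None
                    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise residuals of the two polar equations along a trajectory.

    Time derivatives are central differences over consecutive snapshots
    (stride times dt apart); spatial derivatives use the module stencils.
    Residuals are reported on the interior lattice only (the boundary ring
    is excluded so that phase unwinding across periodic seams cannot
    contaminate them): arrays of shape (T-2, nx-2, ny-2), plus the matching
    snapshot times.  Small residuals certify the polar <-> Cartesian
    equivalence of the simulated dynamics; they shrink at the scheme's
    order (~4x per resolution doubling).
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 snapshots for central differences")
    grid = traj[0].grid
    h = traj.dt * traj.stride
    c1, c2, c3 = params.c1, params.c2, params.c3

    r_stack = np.array([np.abs(s.phi) for s in traj.states])
    if eps is None:
        eps = EPS_FRAC * max(float(np.median(r_stack)), 1e-300)
    if np.any(r_stack <= eps):
        import warnings

        warnings.warn("amplitude fell below eps inside the analysis window; "
                      "affected sites are NaN-masked", stacklevel=2)
    # temporally consistent phase per site; spatially consistent per snapshot
    ang = np.array([np.angle(s.phi) for s in traj.states])
    th_time = np.unwrap(ang, axis=0)

    res1, res2 = [], []
    inner = (slice(1, -1), slice(1, -1))
    for n in range(1, len(traj) - 1):
        r = r_stack[n]
        th = _unwrap2d(ang[n])
        r_t = (r_stack[n + 1] - r_stack[n - 1]) / (2 * h)
        r_tt = (r_stack[n + 1] - 2 * r + r_stack[n - 1]) / h**2
        th_t = (th_time[n + 1] - th_time[n - 1]) / (2 * h)
        th_tt = (th_time[n + 1] - 2 * th_time[n] + th_time[n - 1]) / h**2
        lap_r = laplacian_array(r, grid)
        lap_th = laplacian_array(th, grid)
        gr_x, gr_y = gradient_array(r, grid)
        gth_x, gth_y = gradient_array(th, grid)
        bad = r_stack[n] <= eps
        # factor 2 on both cross terms: Im(e^{-i th} * d2phi/dt2) = r th_tt
        # + 2 r_t th_t and Im(e^{-i th} Lap phi) = r Lap th + 2 grad r.grad th
        e1 = (r * th_tt + 2.0 * r_t * th_t
              - c1 * (r * lap_th + 2.0 * (gr_x * gth_x + gr_y * gth_y))
              + (c2 * r + c3 * r**3))
        e2 = (-r * th_t**2 + r_tt + r
              - c1 * (-r * (gth_x**2 + gth_y**2) + lap_r))
        e1 = np.where(bad, np.nan, e1)
        e2 = np.where(bad, np.nan, e2)
        res1.append(e1[inner])
        res2.append(e2[inner])
    times = traj.times[1:-1]
    return np.array(res1), np.array(res2), times


@dataclass
class StabilityProbe:
    """Result of an empirical limit-cycle stability probe.

    rate > 0 means the perturbation grows.  ``conclusive`` is False when the
    exponential fit explains the data poorly.
    """

    rate: float
    fit_residual: float
    conclusive: bool


def probe_stability(params: LimitCycleParams,
                    k: Tuple[float, float] = (0.0, 0.0),
                    kind: str = "radial",
                    rel_amp: float = 1e-6,
                    grid: Optional[GridSpec] = None,
                    n_cycles: float = 3.0,
                    rotation_sign: float = +1.0) -> StabilityProbe:
    """Fit an exponential rate to a small perturbation of the homogeneous cycle.

    The homogeneous cycle phi = r_lc e^{i Omega t} (Omega = rotation_sign) is
    perturbed by a radial and/or phase plane wave of wavevector ``k`` and
    relative amplitude ``rel_amp``; the perturbation norm (RMS deviation of
    |phi| from r_lc, or of the phase from uniform) is tracked over about
    ``n_cycles`` rotations and log-fitted per-cycle.  Negative rate = stable.
    A run that blows up mid-probe reports rate = +inf (conclusively
    unstable).
    """
    if kind not in ("radial", "phase"):
        raise ValueError("kind must be 'radial' or 'phase'")
    r_lc = steady_radius(params)
    if grid is None:
        grid = GridSpec(16, 16, dx=1.0, dy=1.0, boundary="periodic")
    x, y = grid.coords()
    wave = np.cos(k[0] * x + k[1] * y)
    if kind == "radial":
        r0 = r_lc * (1.0 + rel_amp * wave)
        phi0 = r0.astype(complex)
    else:
        phi0 = r_lc * np.exp(1j * rel_amp * wave)
    state = FieldState(grid, phi0, 1j * rotation_sign * phi0, t=0.0)

    period = 2 * np.pi  # |theta_dot| = 1 on the homogeneous cycle
    dt = stable_dt(params, grid) / 4.0
    steps_per_cycle = max(int(np.ceil(period / dt)), 16)
    dt = period / steps_per_cycle
    total = int(steps_per_cycle * n_cycles)
    stride = max(steps_per_cycle // 8, 1)  # ~8 samples per cycle

    def deviation(s: FieldState) -> float:
        if kind == "radial":
            return float(np.sqrt(np.mean((np.abs(s.phi) - r_lc) ** 2)))
        ang = np.angle(s.phi * np.exp(-1j * np.angle(np.mean(s.phi))))
        return float(np.sqrt(np.mean(ang**2)))

    if deviation(state) < 1e-12 * r_lc:
        return StabilityProbe(rate=0.0, fit_residual=0.0, conclusive=True)

    try:
        traj = integrate_limit_cycle(state, params, dt, total, stride=stride)
    except DivergenceError:
        return StabilityProbe(rate=np.inf, fit_residual=0.0, conclusive=True)

    devs = np.array([deviation(s) for s in traj.states])
    times = traj.times
    # aggregate to per-cycle RMS: averages out the breathing oscillation
    n_groups = max(int(round(n_cycles)), 2)
    edges = np.linspace(times[0], times[-1], n_groups + 1)
    t_c, d_c = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (times >= lo) & (times <= hi)
        if m.sum() and np.any(devs[m] > 0):
            t_c.append(0.5 * (lo + hi))
            d_c.append(np.sqrt(np.mean(devs[m] ** 2)))
    if len(t_c) < 2:
        return StabilityProbe(rate=np.inf, fit_residual=0.0, conclusive=True)
    coeff = np.polyfit(t_c, np.log(d_c), 1)
    rate = float(coeff[0])
    pred = np.polyval(coeff, t_c)
    fit_residual = float(np.sqrt(np.mean((np.log(d_c) - pred) ** 2)))
    return StabilityProbe(rate=rate, fit_residual=fit_residual,
                          conclusive=fit_residual < 1.0)
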