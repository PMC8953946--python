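"""Explicit finite-difference solver for the dimensionless bioheat equation.

The heterogeneous dimensionless heat equation

    d theta / d tau = d/dx( k* d theta/dx ) + d/dy( k* d theta/dy ) + Phi_m

is integrated on the rectangle ``x_bar in [0, 2], y_bar in [0, 1]`` (domain
width W = 2H) with

* ``theta = (T - T_inf) / (Tc - T_inf)`` (0 = ambient, 1 = body core),
* core boundary ``theta(y=0) = 1`` (Dirichlet),
* insulated lateral sides (zero normal gradient),
* a heated surface patch ``d theta/dy = f*`` for ``tau <= tau_app`` on the
  central fifth of the surface, and Robin convective exchange
  ``d theta/dy = Bi (theta_inf - theta)`` elsewhere and afterwards.

The scheme is an explicit conservative (flux-form) update on the grid
nodes, with harmonic-mean face conductivities (flux continuity across layer
interfaces) and half-cell dual volumes at the boundaries, which makes the
discrete heat content exactly conserved under insulated boundaries and the
Neumann/Robin conditions second-order accurate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .medium import TissueProperties

__all__ = [
    "ThermalProblem",
    "TemperatureField",
    "SimulationResult",
    "nondimensionalize",
    "stable_timestep",
    "apply_boundaries",
    "step_explicit",
    "simulate",
    "redimensionalize",
]


@dataclass(frozen=True)
class ThermalProblem:
    """Dimensionless transient problem on the 2:1 tissue rectangle.

    ``patch`` is the heated x_bar interval on the surface; ``grid`` is
    (nx, ny) node counts along x_bar in [0, 2] and y_bar in [0, 1].
    ``dirichlet_bottom=False`` insulates the core boundary instead (used for
    conservation checks, not a physiological scenario).
    """

    H: float = 0.03
    biot: float = 5.0 * 0.03 / 0.293
    phi_m: float = 0.0942
    f_star: float = 1.7065
    theta_inf: float = 0.0
    tau_app: float = 0.09
    tau_end: float = 0.5
    patch: tuple[float, float] = (0.8, 1.2)
    grid: tuple[int, int] = (201, 101)
    safety: float = 0.9
    Tc: float = 37.0
    T_inf: float = 25.0
    alpha: float = field(default=TissueProperties().diffusivity, compare=False)
    dirichlet_bottom: bool = True

    def __post_init__(self) -> None:
        if self.theta_inf != 0.0:
            raise ValueError("theta_inf must be 0 in the chosen scaling")
        if not 0.0 <= self.patch[0] < self.patch[1] <= 2.0:
            raise ValueError(f"patch must lie within [0, 2], got {self.patch}")
        if self.tau_app >= self.tau_end:
            raise ValueError("tau_app must precede tau_end")
        if min(self.grid) < 3:
            raise ValueError("grid needs at least 3 nodes per direction")

    @property
    def W(self) -> float:
        return 2.0 * self.H

    @property
    def dx(self) -> float:
        return 2.0 / (self.grid[0] - 1)

    @property
    def dy(self) -> float:
        return 1.0 / (self.grid[1] - 1)

    @property
    def x_nodes(self) -> np.ndarray:
        return np.linspace(0.0, 2.0, self.grid[0])

    @property
    def y_nodes(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.grid[1])

    def patch_mask(self) -> np.ndarray:
        x = self.x_nodes
        return (x >= self.patch[0] - 1e-12) & (x <= self.patch[1] + 1e-12)


@dataclass(frozen=True)
class TemperatureField:
    """Dimensionless temperature ``theta`` on the grid at time ``tau``."""

    theta: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("temperature field contains non-finite values")


def nondimensionalize(
    tissue: TissueProperties,
    H: float = 0.03,
    h: float = 5.0,
    q_applied: float = 200.0,
    Tc: float = 37.0,
    T_inf: float = 25.0,
    tau_app: float = 0.09,
    tau_end: float = 0.5,
    grid: tuple[int, int] = (201, 101),
    patch: tuple[float, float] = (0.8, 1.2),
) -> ThermalProblem:
    """Build the dimensionless problem from physical parameters.

    ``Bi = h H / k_t``, ``Phi_m = q_m H^2 / (k_t (Tc - T_inf))`` and
    ``f* = H q_app / (k_t (Tc - T_inf))``; the default H = 0.03 m makes
    ``Phi_m ~ 0.094`` with the standard tissue properties.
    """
    dT = Tc - T_inf
    if dT == 0:
        raise ValueError("Tc and T_inf must differ to define the scale")
    kt = tissue.conductivity
    return ThermalProblem(
        H=H,
        biot=h * H / kt,
        phi_m=tissue.metabolic_heat * H**2 / (kt * dT),
        f_star=H * q_applied / (kt * dT),
        tau_app=tau_app,
        tau_end=tau_end,
        grid=grid,
        patch=patch,
        Tc=Tc,
        T_inf=T_inf,
        alpha=tissue.diffusivity,
    )


def stable_timestep(
    etc_values: np.ndarray, dx: float, dy: float, safety: float = 0.9
) -> float:
    """Explicit-diffusion stability bound for the heterogeneous grid.

    ``dtau = safety / (2 max(k*) (1/dx^2 + 1/dy^2))``; ``safety < 1``
    guards the bound against the boundary half-cells.
    """
    etc_values = np.asarray(etc_values)
    if etc_values.size == 0:
        raise ValueError("empty conductivity field")
    kmax = float(etc_values.max())
    if kmax <= 0:
        raise ValueError("maximum conductivity must be positive")
    return safety / (2.0 * kmax * (1.0 / dx**2 + 1.0 / dy**2))


def _harmonic_faces(k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Harmonic-mean conductivities on x- and y-faces between nodes."""
    kx = 2.0 * k[:, 1:] * k[:, :-1] / (k[:, 1:] + k[:, :-1])
    ky = 2.0 * k[1:, :] * k[:-1, :] / (k[1:, :] + k[:-1, :])
    return kx, ky


def _surface_gradient(
    theta_top: np.ndarray, problem: ThermalProblem, tau: float
) -> np.ndarray:
    """Prescribed d theta/dy on the surface row at time ``tau``."""
    g = problem.biot * (problem.theta_inf - theta_top)
    # heating while the step *starts* before tau_app: total heated time == tau_app
    if tau < problem.tau_app - 1e-12:
        mask = problem.patch_mask()
        g = np.where(mask, problem.f_star, g)
    return g


def apply_boundaries(
    theta: TemperatureField, problem: ThermalProblem, tau: float | None = None
) -> TemperatureField:
    """Re-impose the Dirichlet core boundary ``theta(y=0) = 1``.

    The Neumann/Robin conditions (insulated sides, heated patch, convective
    surface) are flux conditions and enter :func:`step_explicit` through the
    boundary face fluxes rather than by overwriting node values.
    """
    out = theta.theta.copy()
    if problem.dirichlet_bottom:
        out[0, :] = 1.0
    return TemperatureField(theta=out, tau=theta.tau if tau is None else tau)


def step_explicit(
    theta: TemperatureField,
    etc_values: np.ndarray,
    problem: ThermalProblem,
    dtau: float,
    faces: tuple[np.ndarray, np.ndarray] | None = None,
) -> TemperatureField:
    """One explicit conservative update of the temperature field.

    Face fluxes ``F = k_face * d theta / d normal`` are differenced over the
    dual cell of each node (half cells at boundaries).  Lateral boundary
    faces carry zero flux; the surface face carries the prescribed patch or
    Robin flux; the core row is re-imposed afterwards when Dirichlet.
    Raises if the update produces non-finite values (instability).
    """
    t = theta.theta
    ny, nx = t.shape
    dx, dy = problem.dx, problem.dy
    kx, ky = _harmonic_faces(etc_values) if faces is None else faces

    fx = np.zeros((ny, nx + 1))
    fx[:, 1:-1] = kx * (t[:, 1:] - t[:, :-1]) / dx
    wx = np.full(nx, dx)
    wx[0] = wx[-1] = dx / 2.0

    fy = np.zeros((ny + 1, nx))
    fy[1:-1, :] = ky * (t[1:, :] - t[:-1, :]) / dy
    k_surf = etc_values[-1, :]
    fy[-1, :] = k_surf * _surface_gradient(t[-1, :], problem, theta.tau)

    div = (fx[:, 1:] - fx[:, :-1]) / wx[None, :]
    wy = np.full(ny, dy)
    wy[0] = wy[-1] = dy / 2.0
    div += (fy[1:, :] - fy[:-1, :]) / wy[:, None]

    new = t + dtau * (div + problem.phi_m)
    tau_new = theta.tau + dtau
    if problem.dirichlet_bottom:
        new[0, :] = 1.0
    if not np.all(np.isfinite(new)):
        bad = np.argwhere(~np.isfinite(new))[0]
        raise FloatingPointError(
            f"unstable update: non-finite theta at node (y={bad[0]}, x={bad[1]}) "
            f"at tau={tau_new:.6g}; reduce dtau"
        )
    return TemperatureField(theta=new, tau=tau_new)


@dataclass
class SimulationResult:
    """Trajectory of a bioheat run: snapshots, probe series and extrema."""

    snapshots: dict[float, np.ndarray]
    probe_points: list[tuple[float, float]]
    probe_taus: np.ndarray
    probe_theta: np.ndarray  # shape (n_probes, n_times)
    max_theta: float
    final: TemperatureField
    dtau: float

    def max_temperature(self, problem: ThermalProblem) -> float:
        """Global maximum dimensional temperature (°C) over the whole run."""
        return problem.T_inf + self.max_theta * (problem.Tc - problem.T_inf)


def simulate(
    problem: ThermalProblem,
    etc_values: np.ndarray,
    snapshot_times: list[float] | None = None,
    probes: list[tuple[float, float]] | None = None,
    theta0: np.ndarray | None = None,
    probe_stride: int = 10,
    dtau_max: float | None = None,
) -> SimulationResult:
    """Integrate the bioheat problem to ``tau_end``.

    The time step is the stability bound shrunk so that the heating switch
    time ``tau_app`` falls on a step boundary.  ``snapshot_times`` are
    rounded to the nearest step; ``probes`` are (x_bar, y_bar) points
    sampled every ``probe_stride`` steps.  ``dtau_max`` caps the step below
    the stability bound (e.g. to run two fields with identical steps).
    """
    ny_nx = (problem.grid[1], problem.grid[0])
    if etc_values.shape != ny_nx:
        raise ValueError(
            f"conductivity field shape {etc_values.shape} does not match "
            f"grid (ny, nx) = {ny_nx}"
        )
    snapshot_times = sorted(snapshot_times or [])
    probes = probes or [(1.0, 1.0)]

    dtau = stable_timestep(etc_values, problem.dx, problem.dy, problem.safety)
    if dtau_max is not None:
        dtau = min(dtau, dtau_max)
    n_app = max(1, math.ceil(problem.tau_app / dtau))
    dtau = problem.tau_app / n_app
    n_steps = math.ceil(problem.tau_end / dtau - 1e-12)

    snap_steps = {min(max(round(t / dtau), 0), n_steps): t for t in snapshot_times}
    ix = [int(round(x / problem.dx)) for x, _ in probes]
    iy = [int(round(y / problem.dy)) for _, y in probes]

    if theta0 is None:
        theta0 = np.ones(ny_nx)
    state = apply_boundaries(TemperatureField(theta=theta0.copy(), tau=0.0), problem)
    faces = _harmonic_faces(etc_values)

    snapshots: dict[float, np.ndarray] = {}
    taus, series = [], []
    max_theta = float(state.theta.max())
    if 0 in snap_steps:
        snapshots[snap_steps[0]] = state.theta.copy()
    for step in range(1, n_steps + 1):
        state = step_explicit(state, etc_values, problem, dtau, faces=faces)
        m = float(state.theta.max())
        if m > max_theta:
            max_theta = m
        if step in snap_steps:
            snapshots[snap_steps[step]] = state.theta.copy()
        if step % probe_stride == 0 or step == n_steps:
            taus.append(state.tau)
            series.append([state.theta[j, i] for i, j in zip(ix, iy)])
    return SimulationResult(
        snapshots=snapshots,
        probe_points=list(probes),
        probe_taus=np.asarray(taus),
        probe_theta=np.asarray(series).T if series else np.empty((len(probes), 0)),
        max_theta=max_theta,
        final=state,
        dtau=dtau,
    )


def redimensionalize(
    theta: np.ndarray | TemperatureField, problem: ThermalProblem
) -> np.ndarray:
    """Convert dimensionless ``theta`` to °C: ``T = T_inf + theta (Tc - T_inf)``."""
    arr = theta.theta if isinstance(theta, TemperatureField) else np.asarray(theta)
    return problem.T_inf + arr * (problem.Tc - problem.T_inf)


def dimensional_time(tau, problem: ThermalProblem) -> float | np.ndarray:
    """Convert dimensionless time to seconds: ``t = tau H^2 / alpha``."""
    return np.asarray(tau) * problem.H**2 / problem.alpha
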