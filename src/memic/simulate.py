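"""1D diffusion–consumption model of metabolite gradients in the chamber.

A monolayer of cells on the chamber floor consumes a metabolite (e.g. oxygen)
that diffuses in from the well-mixed reservoir at the opening. Averaging over
the medium column of height h reduces the problem to one dimension along the
chamber axis x (opening at x = 0, sealed wall at x = L):

    ∂c/∂t = D ∂²c/∂x² − (ρ q / h) u(c),   c(0, t) = c0,   ∂c/∂x(L, t) = 0,

with uptake u(c) = c / (c + Km) (Michaelis–Menten) or, for Km = 0,
zeroth-order consumption u = 1 wherever c > 0 with a free boundary at c = 0.
Because the reservoir clamps c(0) = c0 at the coverslip edge, the opening
width w never enters the equations — gradient shape is independent of w,
while cell density ρ and chamber height h set the gradient's position and
steepness. In the Km = 0 regime the steady state has the closed form

    c(x) = c0 − (ρ q / (2 D h)) · x (2 x* − x)  on [0, x*],  c = 0 beyond,
    x*   = min(L, sqrt(2 D h c0 / (ρ q)))        (the anoxic front).

A threshold-type reporter (Hill activation below a critical concentration,
first-order maturation lag) models the digital hypoxia response of
HIF-driven transcription: HIF1α is degraded above an oxygen threshold and
stabilized below it, so a smooth oxygen gradient produces a sharp spatial
step in reporter signal.

This is a deliberate minimal reconstruction; only gradient shapes and
parameter orderings are claimed, not absolute calibration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "ChamberSpec",
    "ReporterSpec",
    "SweepResult",
    "steady_state",
    "closed_form_steady_state",
    "anoxic_front",
    "time_course",
    "reporter_profile",
    "predict_effects",
]


@dataclass(frozen=True)
class ChamberSpec:
    """Chamber geometry, kinetics and numerical grid.

    length : chamber length L, µm (opening at x=0, sealed wall at x=L).
    medium_height : height h of the medium column above the monolayer, µm.
    opening_width : opening width w, µm — documented no-op on gradient shape.
    reservoir_concentration : c0 at the opening (normalized to 1 by default).
    diffusivity : D, µm²/s (default 2000, oxygen-like in medium).
    per_cell_consumption : q, amount/cell/s in c0 units · µm³.
    cell_density : ρ, cells/µm² of chamber floor.
    km : Michaelis constant (concentration units); 0 selects zeroth-order
        consumption with a hard floor at c = 0.
    dx : grid spacing, µm (must resolve the chamber: dx < L/10).
    duration : simulated time span for time courses, s.
    dt : time step, s (None = auto: stable for the explicit scheme).
    scheme : "implicit" (backward Euler, default — L-stable and monotone at
        the consumption front), "cn" (Crank–Nicolson, second order in time
        but prone to undamped oscillation at the front) or "explicit"
        (forward Euler, kept as an independent cross-check; enforces the
        stability bound D·dt/dx² <= 0.5).
    """

    length: float = 5000.0
    medium_height: float = 100.0
    opening_width: float = 1000.0
    reservoir_concentration: float = 1.0
    diffusivity: float = 2000.0
    per_cell_consumption: float = 50.0
    cell_density: float = 0.002
    km: float = 0.0
    dx: float = 10.0
    duration: float = 24 * 3600.0
    dt: float | None = None
    scheme: str = "implicit"

    def __post_init__(self) -> None:
        if min(self.length, self.medium_height, self.diffusivity,
               self.reservoir_concentration) <= 0:
            raise ValueError("length, medium_height, diffusivity and "
                             "reservoir_concentration must be positive")
        if min(self.cell_density, self.per_cell_consumption, self.km) < 0:
            raise ValueError("cell_density, per_cell_consumption and km must be >= 0")
        if not 0 < self.dx < self.length / 10:
            raise ValueError("require 0 < dx < length/10")
        if self.scheme not in ("implicit", "cn", "explicit"):
            raise ValueError("scheme must be 'implicit', 'cn' or 'explicit'")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.scheme == "explicit":
            dt = self.dt if self.dt is not None else self.stable_dt
            if self.diffusivity * dt / self.dx**2 > 0.5:
                raise ValueError("explicit scheme unstable: D*dt/dx² must be <= 0.5")

    @property
    def grid(self) -> np.ndarray:
        """Node positions 0, dx, …, L (inclusive)."""
        n = int(round(self.length / self.dx))
        return np.linspace(0.0, self.length, n + 1)

    @property
    def sink_rate(self) -> float:
        """Maximal volumetric consumption ρ q / h (concentration/s)."""
        return self.cell_density * self.per_cell_consumption / self.medium_height

    @property
    def stable_dt(self) -> float:
        """Largest forward-Euler-stable step, 0.5 dx²/D."""
        return 0.5 * self.dx**2 / self.diffusivity


@dataclass(frozen=True)
class ReporterSpec:
    """Threshold-type hypoxia reporter.

    hypoxia_threshold : critical concentration c* below which the reporter
        activates (in c0 units).
    hill_n : Hill coefficient of the activation a = 1 / (1 + (c/c*)^n);
        ``np.inf`` gives a hard step (a = 1 iff c < c*).
    maturation_delay : first-order low-pass time constant τ, hours
        (fluorophore maturation / protein turnover); 0 = instantaneous.
    """

    hypoxia_threshold: float = 0.1
    hill_n: float = 8.0
    maturation_delay: float = 1.0

    def __post_init__(self) -> None:
        if self.hypoxia_threshold <= 0:
            raise ValueError("hypoxia_threshold must be positive")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")
        if self.maturation_delay < 0:
            raise ValueError("maturation_delay must be >= 0")


def _uptake(c: np.ndarray, km: float) -> np.ndarray:
    if km == 0:
        return (c > 0).astype(float)
    return c / (c + km)


def closed_form_steady_state(spec: ChamberSpec) -> np.ndarray:
    """Analytic steady state for the zeroth-order (Km = 0) regime.

    c(x) = c0 − (ρq/(2Dh)) x (2x* − x) for x <= x*, 0 beyond, with the
    anoxic front x* = min(L, sqrt(2 D h c0 / (ρ q))). Requires km == 0.
    """
    if spec.km != 0:
        raise ValueError("closed form applies to km=0 only")
    x = spec.grid
    c0, a = spec.reservoir_concentration, spec.sink_rate
    if a == 0:
        return np.full_like(x, c0)
    xs = anoxic_front(spec)
    c = c0 - a / (2 * spec.diffusivity) * x * (2 * xs - x)
    return np.where(x <= xs, np.maximum(c, 0.0), 0.0)


def anoxic_front(spec: ChamberSpec) -> float:
    """Position x* beyond which steady-state concentration is zero (Km = 0).

    x* = sqrt(2 D h c0 / (ρ q)), capped at the chamber length. Infinite when
    there is no consumption.
    """
    a = spec.sink_rate
    if a == 0:
        return np.inf
    xs = np.sqrt(2 * spec.diffusivity * spec.reservoir_concentration / a)
    return float(min(xs, spec.length))


def _step_matrix(n: int, r: float) -> np.ndarray:
    """Banded (I + r·A) for the implicit side; A is the 1D Laplacian with a
    Dirichlet node at 0 and a mirrored (zero-flux) node at n-1."""
    ab = np.zeros((3, n))
    ab[0, 2:] = -r  # upper diagonal
    ab[1, :] = 1 + 2 * r
    ab[1, 0] = 1.0  # Dirichlet row
    ab[0, 1] = 0.0
    ab[2, :-1] = -r  # lower diagonal
    ab[2, n - 2] = -2 * r  # Neumann: ghost node mirrors interior neighbour
    return ab


def _laplacian_times(c: np.ndarray, c0: float) -> np.ndarray:
    """(dx²/1)·c″ with c(0)=c0 Dirichlet and zero flux at the far wall."""
    out = np.empty_like(c)
    out[0] = 0.0
    out[1:-1] = c[:-2] - 2 * c[1:-1] + c[2:]
    out[-1] = 2 * (c[-2] - c[-1])
    return out


def _banded_matvec(ab: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Product of a (1,1)-banded matrix in solve_banded layout with c."""
    out = ab[1] * c
    out[:-1] += ab[0, 1:] * c[1:]
    out[1:] += ab[2, :-1] * c[:-1]
    return out


def _constrained_solve(ab: np.ndarray, rhs: np.ndarray, clamped: np.ndarray) -> np.ndarray:
    """Solve the banded system with the clamped nodes pinned to zero."""
    if clamped.any():
        ab = ab.copy()
        rhs = np.where(clamped, 0.0, rhs)
        ab[1] = np.where(clamped, 1.0, ab[1])
        ab[0, 1:] = np.where(clamped[:-1] | clamped[1:], 0.0, ab[0, 1:])
        ab[2, :-1] = np.where(clamped[:-1] | clamped[1:], 0.0, ab[2, :-1])
    return solve_banded((1, 1), ab, rhs)


def _advance(c: np.ndarray, spec: ChamberSpec, dt: float, theta: float) -> np.ndarray:
    """One θ-scheme step (θ=1 backward Euler, θ=0.5 Crank–Nicolson, θ=0
    explicit) with the consumption term evaluated at the old time level.

    The c >= 0 constraint (the Km = 0 free boundary) is imposed per step as a
    linear complementarity problem, solved by active-set iteration on the
    tridiagonal system; a plain post-step clip would bias the front position
    by O(dt·sink).
    """
    c0 = spec.reservoir_concentration
    r = spec.diffusivity * dt / spec.dx**2
    sink = dt * spec.sink_rate * _uptake(c, spec.km)
    sink[0] = 0.0
    rhs = c + (1 - theta) * r * _laplacian_times(c, c0) - sink
    rhs[0] = c0
    if theta == 0:
        return np.clip(rhs, 0.0, c0)

    ab = _step_matrix(len(c), theta * r)
    clamped = np.zeros(len(c), dtype=bool)
    for _ in range(100):
        new = _constrained_solve(ab, rhs, clamped)
        violate = (new < -1e-13 * c0) & ~clamped
        if clamped.any():
            # release clamped nodes whose constraint force became attractive
            lam = _banded_matvec(ab, np.maximum(new, 0.0)) - rhs
            release = clamped & (lam < -1e-13 * c0)
        else:
            release = np.zeros_like(clamped)
        if not violate.any() and not release.any():
            break
        clamped = (clamped | violate) & ~release
    return np.clip(new, 0.0, c0)


def _psor_obstacle(spec: ChamberSpec, tol: float, max_sweeps: int) -> np.ndarray:
    """Projected red-black SOR for the Km = 0 steady state.

    D c″ = A on {c > 0} with c >= 0 is a linear complementarity (obstacle)
    problem; projected SOR converges monotonically for this M-matrix system
    and captures the free boundary without smoothing.
    """
    x = spec.grid
    n = len(x)
    c0 = spec.reservoir_concentration
    b = spec.sink_rate * spec.dx**2 / (2 * spec.diffusivity)
    omega = 2.0 / (1.0 + np.sin(np.pi / n))
    c = np.full(n, c0)
    idx = np.arange(n)
    for _ in range(max_sweeps):
        prev = c.copy()
        for parity in (1, 0):
            sel = idx[(idx % 2 == parity) & (idx > 0)]
            interior = sel[sel < n - 1]
            gs = 0.5 * (c[interior - 1] + c[interior + 1]) - b
            c[interior] = np.maximum(0.0, c[interior] + omega * (gs - c[interior]))
            if (n - 1) % 2 == parity:  # zero-flux wall node
                gs_last = c[n - 2] - b
                c[n - 1] = max(0.0, c[n - 1] + omega * (gs_last - c[n - 1]))
        if np.abs(c - prev).max() < tol * c0:
            return c
    raise RuntimeError("projected SOR did not converge")


def steady_state(spec: ChamberSpec, tol: float = 1e-12, max_sweeps: int = 200_000) -> np.ndarray:
    """Steady-state concentration profile c(x) on ``spec.grid``.

    Solves D c″ = (ρq/h) u(c) with c(0) = c0 and zero flux at x = L.
    For Km = 0 the free boundary at c = 0 makes this an obstacle problem,
    solved by projected SOR. For Km > 0 the Michaelis–Menten uptake keeps
    c positive and the nonlinearity is handled by a damped lagged-uptake
    tridiagonal iteration. Iterates until the per-sweep change falls below
    ``tol``·c0; raises on non-convergence.
    """
    c0 = spec.reservoir_concentration
    c = np.full(spec.grid.shape, c0)
    if spec.sink_rate == 0:
        return c
    if spec.km == 0:
        return _psor_obstacle(spec, tol, max_sweeps)

    # Km > 0: solve D c″ = A·c/(c+Km) by freezing the uptake at the previous
    # iterate and solving the resulting linear BVP exactly, with damping.
    n = len(c)
    r = 1.0  # the tridiagonal solve below is scaled so r is arbitrary
    dt_eq = spec.dx**2 / spec.diffusivity  # scale making the system O(1)
    for _ in range(max_sweeps):
        sink = spec.sink_rate * dt_eq * _uptake(c, spec.km)
        sink[0] = 0.0
        rhs = c - 1e3 * sink  # large pseudo-step: near-direct solve
        rhs[0] = c0
        new = solve_banded((1, 1), _step_matrix(n, 1e3 * r), rhs)
        new = np.clip(new, 0.0, c0)
        new = 0.5 * (new + c)  # damping stabilizes the lagged uptake
        if np.abs(new - c).max() < tol * c0:
            return new
        c = new
    raise RuntimeError("steady state did not converge")


def time_course(
    spec: ChamberSpec,
    times: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Transient solution c(x, t) starting from a freshly filled chamber.

    Initial condition c(x, 0) = c0 everywhere; the same boundary conditions
    as :func:`steady_state`. Returns ``(x, t, C)`` with ``C[k]`` the profile
    at ``t[k]`` (snapshot times rounded down to whole steps; ``times``
    defaults to 25 evenly spaced points over ``spec.duration``). At every
    position the concentration decreases monotonically toward steady state.
    """
    x = spec.grid
    c0 = spec.reservoir_concentration
    if times is None:
        times = np.linspace(0.0, spec.duration, 25)
    times = np.asarray(sorted(times), dtype=float)
    if times[0] < 0:
        raise ValueError("snapshot times must be >= 0")
    if spec.sink_rate == 0:
        # nothing is consumed: the uniform initial state solves the PDE exactly
        return x, times, np.full((len(times), len(x)), c0)
    dt = spec.dt if spec.dt is not None else (
        spec.stable_dt if spec.scheme == "explicit" else min(60.0, spec.duration / 100)
    )
    theta = {"explicit": 0.0, "cn": 0.5, "implicit": 1.0}[spec.scheme]

    c = np.full_like(x, c0)
    out = np.empty((len(times), len(x)))
    t_now, k = 0.0, 0
    while k < len(times) and times[k] <= t_now + 1e-12:
        out[k] = c
        k += 1
    while k < len(times):
        c = _advance(c, spec, dt, theta)
        t_now += dt
        while k < len(times) and times[k] <= t_now + 1e-12:
            out[k] = c
            k += 1
    return x, times, out


def reporter_profile(
    c: np.ndarray,
    rep: ReporterSpec,
    times: Sequence[float] | None = None,
) -> np.ndarray:
    """Reporter signal s ∈ [0, 1] for a concentration field.

    Instantaneous activation a = c*ⁿ / (c*ⁿ + cⁿ) (a hard step a = 1 iff
    c < c* when ``hill_n`` is infinite). For a time-resolved field ``c`` of
    shape (n_times, n_x) with matching ``times`` (s), the signal is the
    activation passed through a first-order low-pass of time constant
    ``maturation_delay`` (hours), starting dark: ds/dt = (a − s)/τ. For a
    steady-state 1D field (or τ = 0) the signal equals the activation.
    """
    c = np.asarray(c, dtype=float)
    cs = rep.hypoxia_threshold
    if np.isinf(rep.hill_n):
        a = (c < cs).astype(float)
    else:
        with np.errstate(over="ignore"):
            a = 1.0 / (1.0 + (c / cs) ** rep.hill_n)
    tau_s = rep.maturation_delay * 3600.0
    if c.ndim == 1 or tau_s == 0:
        return a
    if times is None:
        raise ValueError("times required for a time-resolved field with τ > 0")
    times = np.asarray(times, dtype=float)
    if len(times) != c.shape[0]:
        raise ValueError("times length must match the field's time axis")
    s = np.zeros_like(a)
    for k in range(1, len(times)):
        decay = np.exp(-(times[k] - times[k - 1]) / tau_s)
        s[k] = a[k - 1] + (s[k - 1] - a[k - 1]) * decay
    return s


@dataclass(frozen=True)
class SweepResult:
    """Profiles and reporter half-max positions across a parameter sweep."""

    parameter: str
    values: tuple[float, ...]
    x: np.ndarray
    concentration: np.ndarray  # (n_values, n_x)
    reporter: np.ndarray  # (n_values, n_x)
    half_max_um: tuple[float | None, ...]  # None = silent reporter


_SWEEPABLE = {"cell_density", "medium_height", "opening_width"}


def _reporter_half_max(x: np.ndarray, s: np.ndarray, silent_level: float = 0.01) -> float | None:
    if s.max() < silent_level:
        return None
    t = s.min() + 0.5 * (s.max() - s.min())
    for i in range(len(x) - 1):
        if s[i] == t:
            return float(x[i])
        if (s[i] - t) * (s[i + 1] - t) < 0:
            return float(x[i] + (t - s[i]) / (s[i + 1] - s[i]) * (x[i + 1] - x[i]))
    return float(x[-1]) if s[-1] == t else None


def predict_effects(
    spec: ChamberSpec,
    sweep: str,
    values: Sequence[float],
    rep: ReporterSpec | None = None,
) -> SweepResult:
    """Steady-state gradient and reporter response across a parameter sweep.

    Sweeps ``cell_density`` (ρ), ``medium_height`` (h) or ``opening_width``
    (w) and reports, per value, the concentration profile, the steady-state
    reporter activation and its half-max position (None when the reporter is
    silent chamber-wide, i.e. the sub-threshold density regime). Expected
    orderings: increasing ρ pulls the half-max toward the opening, increasing
    h pushes it away, and w leaves every profile bit-identical because it
    does not appear in the transport equations.
    """
    if sweep not in _SWEEPABLE:
        raise ValueError(f"sweep must be one of {sorted(_SWEEPABLE)}")
    rep = rep or ReporterSpec()
    profiles, reporters, half_max = [], [], []
    x = spec.grid
    for v in values:
        sub = dataclasses.replace(spec, **{sweep: float(v)})
        c = steady_state(sub)
        s = reporter_profile(c, rep)
        profiles.append(c)
        reporters.append(s)
        half_max.append(_reporter_half_max(x, s))
    return SweepResult(
        parameter=sweep,
        values=tuple(float(v) for v in values),
        x=x,
        concentration=np.array(profiles),
        reporter=np.array(reporters),
        half_max_um=tuple(half_max),
    )
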