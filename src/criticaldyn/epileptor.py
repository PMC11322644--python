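"""Five-dimensional Epileptor neural-mass model with stimulation.

The Epileptor couples a fast discharge subsystem (x1, y1), a slower
spike-wave subsystem (x2, y2) and a very slow permittivity variable z that
drives switching between interictal and ictal regimes through a fold
(saddle-node) bifurcation.  The excitability parameter ``x0`` sets the
distance to the critical point: for sufficiently negative ``x0`` the system
rests on a stable non-ictal fixed point, and as ``x0`` rises the fixed
point approaches the fold and eventually disappears, producing spontaneous
seizures.

An auxiliary variable g implements the exponentially weighted integral of
x1 feeding the slow subsystem as the linear filter ``dg/dt = x1 - gamma*g``.

One model time unit corresponds to 10 ms of real time.  Integration runs
internally on a finer grid (default 0.1 model units = 1 ms) so that 3 ms
stimulation pulses are resolved, and trajectories are decimated back to the
10 ms grid on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from numpy.typing import NDArray
from scipy import optimize

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


MS_PER_MODEL_UNIT = 10.0
#: internal integration step in model time units (0.1 => 1 ms of real time)
DEFAULT_DT_INTERNAL = 0.1

STATE_NAMES = ("x1", "y1", "z", "x2", "y2", "g")


@dataclass(frozen=True)
class EpileptorParams:
    """Parameters of the Epileptor vector field and its integration.

    Defaults follow the standard parameterisation with a long permittivity
    timescale (tau0 = 20000) giving realistic interictal durations.  Noise
    variances are per unit model time and enter only stochastic runs.
    """

    x0: float = -2.25
    y0: float = 1.0
    tau0: float = 20000.0
    tau2: float = 10.0
    I1_base: float = 3.1
    I2_base: float = 0.45
    gamma: float = 0.01
    noise_var_x1: float = 0.005
    noise_var_x2: float = 0.0001
    noise_var_y2: float = 0.0001
    stim_amp_1: float = 2.0
    stim_amp_2: float = 5.0
    dt: float = DEFAULT_DT_INTERNAL
    ms_per_step: float = MS_PER_MODEL_UNIT

    def __post_init__(self) -> None:
        if self.tau0 <= 0 or self.tau2 <= 0 or self.gamma <= 0:
            raise ValueError("tau0, tau2 and gamma must be positive")
        if min(self.noise_var_x1, self.noise_var_x2, self.noise_var_y2) < 0:
            raise ValueError("noise variances must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def with_(self, **kwargs) -> "EpileptorParams":
        return replace(self, **kwargs)

    def to_vector(self) -> NDArray[np.float64]:
        return np.array(
            [self.x0, self.y0, self.tau0, self.tau2, self.I1_base,
             self.I2_base, self.gamma, self.stim_amp_1, self.stim_amp_2],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class EpileptorState:
    """A point of the extended (5+1)-dimensional state space."""

    x1: float
    y1: float
    z: float
    x2: float
    y2: float
    g: float
    t: float = 0.0

    def to_vector(self) -> NDArray[np.float64]:
        return np.array(
            [self.x1, self.y1, self.z, self.x2, self.y2, self.g], dtype=float
        )

    @classmethod
    def from_vector(cls, v: Sequence[float], t: float = 0.0) -> "EpileptorState":
        x1, y1, z, x2, y2, g = (float(c) for c in v)
        return cls(x1, y1, z, x2, y2, g, t)


@dataclass(frozen=True)
class StimulusTrain:
    """Pulse onsets (real ms) with a common width and amplitude scale."""

    pulse_onsets_ms: NDArray[np.float64]
    pulse_width_ms: float = 3.0
    amplitude_scale: float = 1.0
    label: str = "single-pulse"
    #: optional per-pulse multiplier on top of amplitude_scale
    per_pulse_scales: NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        onsets = np.asarray(self.pulse_onsets_ms, dtype=float)
        object.__setattr__(self, "pulse_onsets_ms", onsets)
        if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("pulse onsets must be strictly increasing")
        if self.pulse_width_ms <= 0:
            raise ValueError("pulse_width_ms must be positive")
        if self.amplitude_scale < 0:
            raise ValueError("amplitude_scale must be non-negative")
        if self.per_pulse_scales is not None:
            scales = np.asarray(self.per_pulse_scales, dtype=float)
            if scales.shape != onsets.shape:
                raise ValueError("per_pulse_scales must match pulse count")
            object.__setattr__(self, "per_pulse_scales", scales)

    @classmethod
    def empty(cls) -> "StimulusTrain":
        return cls(np.empty(0), label="none")


@dataclass
class SimulationResult:
    """Trajectory on the canonical 10 ms output grid."""

    time_ms: NDArray[np.float64]
    states: NDArray[np.float64]  # (n_out, 6) columns per STATE_NAMES
    ieeg_proxy: NDArray[np.float64]
    stim_trace: NDArray[np.float64]
    params: EpileptorParams
    seed: int | None = None
    seizure_onset_ms: float | None = field(default=None)
    #: proxy at the native integration step (for resolution-sensitive metrics)
    fine_proxy: NDArray[np.float64] | None = field(default=None, repr=False)
    fine_step_ms: float | None = None

    def __post_init__(self) -> None:
        n = len(self.time_ms)
        if not (len(self.states) == len(self.ieeg_proxy) == len(self.stim_trace) == n):
            raise ValueError("trace lengths differ")

    @property
    def sampling_rate_hz(self) -> float:
        return 1000.0 / (self.time_ms[1] - self.time_ms[0])

    def state_at(self, index: int) -> EpileptorState:
        return EpileptorState.from_vector(self.states[index], t=self.time_ms[index])

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "t_ms", self.time_ms)
        df["ieeg_proxy"] = self.ieeg_proxy
        df["stim"] = self.stim_trace
        return df


class BlowupError(RuntimeError):
    """State magnitude exceeded the divergence guard (|state| > 1e6)."""


@njit(cache=False)
def _rhs(y, x0, y0, tau0, tau2, I1, I2, gamma, out):
    x1, y1, z, x2, y2, g = y[0], y[1], y[2], y[3], y[4], y[5]
    if x1 < 0.0:
        f1 = x1 * x1 * x1 - 3.0 * x1 * x1
    else:
        f1 = (x2 - 0.6 * (z - 4.0) * (z - 4.0)) * x1
    if x2 < -0.25:
        f2 = 0.0
    else:
        f2 = 6.0 * (x2 + 0.25)
    out[0] = y1 - f1 - z + I1
    out[1] = y0 - 5.0 * x1 * x1 - y1
    out[2] = (4.0 * (x1 - x0) - z) / tau0
    out[3] = -y2 + x2 - x2 * x2 * x2 + I2 + 0.002 * g - 0.3 * (z - 3.5)
    out[4] = (-y2 + f2) / tau2
    out[5] = x1 - gamma * g


@njit(cache=False)
def _integrate_kernel(y_init, p, stim_on, n_steps, dt, decim,
                      noise_std, stochastic, seed):
    """Fixed-step integration; RK4 when deterministic, Heun when stochastic.

    stim_on holds the amplitude scale per internal step (0 outside pulses).
    Noise stds are per sqrt(model time); the increment is std*sqrt(dt)*N(0,1)
    added to (x1, x2, y2).  Returns decimated (states, stim) including the
    initial condition as sample 0.
    """
    n_out = n_steps // decim + 1
    out = np.empty((n_out, 6))
    stim_out = np.zeros(n_out)
    proxy_fine = np.empty(n_steps + 1)
    y = y_init.copy()
    proxy_fine[0] = y[0] + y[3]
    k1 = np.empty(6)
    k2 = np.empty(6)
    k3 = np.empty(6)
    k4 = np.empty(6)
    ytmp = np.empty(6)
    out[0] = y
    if stochastic:
        np.random.seed(seed)
    sdt = np.sqrt(dt)
    x0, y0, tau0, tau2 = p[0], p[1], p[2], p[3]
    I1b, I2b, gamma, amp1, amp2 = p[4], p[5], p[6], p[7], p[8]
    j = 0
    for i in range(n_steps):
        scale = stim_on[i]
        I1 = I1b + amp1 * scale
        I2 = I2b + amp2 * scale
        _rhs(y, x0, y0, tau0, tau2, I1, I2, gamma, k1)
        if stochastic:
            w0 = noise_std[0] * sdt * np.random.normal()
            w1 = noise_std[1] * sdt * np.random.normal()
            w2 = noise_std[2] * sdt * np.random.normal()
            # stochastic Heun (predictor-corrector, additive noise)
            for c in range(6):
                ytmp[c] = y[c] + dt * k1[c]
            ytmp[0] += w0
            ytmp[3] += w1
            ytmp[4] += w2
            _rhs(ytmp, x0, y0, tau0, tau2, I1, I2, gamma, k2)
            for c in range(6):
                y[c] = y[c] + 0.5 * dt * (k1[c] + k2[c])
            y[0] += w0
            y[3] += w1
            y[4] += w2
        else:
            for c in range(6):
                ytmp[c] = y[c] + 0.5 * dt * k1[c]
            _rhs(ytmp, x0, y0, tau0, tau2, I1, I2, gamma, k2)
            for c in range(6):
                ytmp[c] = y[c] + 0.5 * dt * k2[c]
            _rhs(ytmp, x0, y0, tau0, tau2, I1, I2, gamma, k3)
            for c in range(6):
                ytmp[c] = y[c] + dt * k3[c]
            _rhs(ytmp, x0, y0, tau0, tau2, I1, I2, gamma, k4)
            for c in range(6):
                y[c] = y[c] + dt / 6.0 * (k1[c] + 2.0 * k2[c] + 2.0 * k3[c] + k4[c])
        for c in range(6):
            if not np.isfinite(y[c]) or np.abs(y[c]) > 1e6:
                return out[: j + 1], stim_out[: j + 1], proxy_fine[: i + 1], i + 1
        proxy_fine[i + 1] = y[0] + y[3]
        if (i + 1) % decim == 0:
            j += 1
            out[j] = y
            stim_out[j] = scale
    return out, stim_out, proxy_fine, -1


def epileptor_derivative(
    state: EpileptorState,
    params: EpileptorParams,
    istim1: float = 0.0,
    istim2: float = 0.0,
) -> NDArray[np.float64]:
    """Right-hand side of the deterministic Epileptor, plus dg/dt.

    ``istim1``/``istim2`` are added to the fast and slow drives I1/I2.
    """
    y = state.to_vector()
    if not np.all(np.isfinite(y)):
        raise BlowupError("non-finite state passed to derivative")
    out = np.empty(6)
    _rhs(
        y, params.x0, params.y0, params.tau0, params.tau2,
        params.I1_base + istim1, params.I2_base + istim2, params.gamma, out,
    )
    return out


def _stim_indicator(
    stim: StimulusTrain | None, n_steps: int, dt: float
) -> NDArray[np.float64]:
    """Amplitude scale per internal step (dt in model units)."""
    on = np.zeros(n_steps)
    if stim is None or len(stim.pulse_onsets_ms) == 0 or stim.amplitude_scale == 0:
        return on
    step_ms = dt * MS_PER_MODEL_UNIT
    width_steps = max(1, int(round(stim.pulse_width_ms / step_ms)))
    starts = np.round(stim.pulse_onsets_ms / step_ms).astype(int)
    scales = (np.full(starts.size, 1.0) if stim.per_pulse_scales is None
              else stim.per_pulse_scales)
    for s, ps in zip(starts, scales):
        if s >= n_steps:
            break
        on[s : min(s + width_steps, n_steps)] = stim.amplitude_scale * ps
    return on


def _run(
    params: EpileptorParams,
    initial: EpileptorState,
    stim: StimulusTrain | None,
    n_steps: int,
    stochastic: bool,
    seed: int | None,
    keep_fine_proxy: bool = False,
) -> SimulationResult:
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    stim_on = _stim_indicator(stim, n_steps, params.dt)
    noise_std = np.sqrt(
        np.array([params.noise_var_x1, params.noise_var_x2, params.noise_var_y2])
    )
    # decimate to the canonical 10 ms grid whatever the internal step
    decim = max(1, int(round(1.0 / params.dt)))
    states, stim_out, proxy_fine, blow_step = _integrate_kernel(
        initial.to_vector(), params.to_vector(), stim_on, n_steps,
        params.dt, decim, noise_std, stochastic,
        0 if seed is None else int(seed),
    )
    if blow_step >= 0:
        raise BlowupError(f"state diverged at internal step {blow_step}")
    step_ms = params.dt * MS_PER_MODEL_UNIT
    time_ms = initial.t + np.arange(len(states)) * step_ms * decim
    proxy = states[:, 0] + states[:, 3]  # x1 + x2
    return SimulationResult(
        time_ms=time_ms, states=states, ieeg_proxy=proxy,
        stim_trace=stim_out, params=params, seed=seed,
        fine_proxy=proxy_fine if keep_fine_proxy else None,
        fine_step_ms=step_ms if keep_fine_proxy else None,
    )


def integrate_deterministic(
    params: EpileptorParams,
    initial: EpileptorState,
    stim: StimulusTrain | None = None,
    n_steps: int = 10_000,
    keep_fine_proxy: bool = False,
) -> SimulationResult:
    """Classical RK4 at fixed internal step ``params.dt``.

    ``n_steps`` counts internal steps; the returned trajectory is decimated
    to the 10 ms grid.
    """
    return _run(params, initial, stim, n_steps, stochastic=False, seed=None,
                keep_fine_proxy=keep_fine_proxy)


def integrate_stochastic(
    params: EpileptorParams,
    initial: EpileptorState,
    stim: StimulusTrain | None = None,
    n_steps: int = 10_000,
    seed: int = 0,
    keep_fine_proxy: bool = False,
) -> SimulationResult:
    """Stochastic Heun scheme with additive Gaussian noise on x1, x2, y2.

    Noise variances are interpreted per unit model time; with all variances
    zero the scheme degenerates to a second-order deterministic integrator
    and tracks :func:`integrate_deterministic` closely.
    """
    return _run(params, initial, stim, n_steps, stochastic=True, seed=seed,
                keep_fine_proxy=keep_fine_proxy)


def find_fixed_point(params: EpileptorParams) -> EpileptorState:
    """Stable non-ictal equilibrium of the deterministic system.

    Solves the full 6-dimensional root problem starting from the analytic
    lower-branch guess and verifies linear stability via a finite-difference
    Jacobian.  Raises if no stable root exists (x0 beyond the fold).
    """

    def rhs_vec(y):
        out = np.empty(6)
        _rhs(y, params.x0, params.y0, params.tau0, params.tau2,
             params.I1_base, params.I2_base, params.gamma, out)
        return out

    # lower-branch cubic for x1 (< -4/3): -x1^3 - 2 x1^2 - 4(x1 - x0) + y0 + I1 = 0
    coeffs = [-1.0, -2.0, -4.0, 4.0 * params.x0 + params.y0 + params.I1_base]
    roots = np.roots(coeffs)
    cands = sorted(r.real for r in roots if abs(r.imag) < 1e-9 and r.real < 0)
    last_err = None
    for x1g in cands:
        zg = 4.0 * (x1g - params.x0)
        y1g = params.y0 - 5.0 * x1g**2
        x2g = -1.0
        y2g = 0.0 if x2g < -0.25 else 6.0 * (x2g + 0.25)
        gg = x1g / params.gamma
        guess = np.array([x1g, y1g, zg, x2g, y2g, gg])
        sol = optimize.root(rhs_vec, guess, method="hybr", tol=1e-12)
        if not sol.success or np.linalg.norm(rhs_vec(sol.x)) > 1e-8:
            last_err = "root finding did not converge"
            continue
        jac = optimize.approx_fprime(sol.x, rhs_vec, 1e-7)
        eig = np.linalg.eigvals(jac)
        if np.all(eig.real < 0):
            return EpileptorState.from_vector(sol.x)
        last_err = "equilibrium is unstable"
    raise ValueError(
        "no stable non-ictal fixed point found "
        f"(x0={params.x0} may be beyond the critical point): {last_err}"
    )


@dataclass(frozen=True)
class SeizureCriterion:
    """Threshold-crossing detector for ictal transitions.

    Onset is the first time x1 exceeds ``onset_threshold`` and stays above
    ``sustain_threshold`` for ``dwell_s`` of real time.  The ictal branch of
    the fast subsystem is the x1 >= 0 regime; the sustain threshold sits
    below it so that intra-ictal oscillation troughs do not reset the dwell.
    """

    onset_threshold: float = 0.0
    sustain_threshold: float = -1.2
    dwell_s: float = 10.0


def detect_seizure(
    sim: SimulationResult, criterion: SeizureCriterion | None = None
) -> float | None:
    """First ictal onset time (real ms) in a simulated trajectory, or None."""
    crit = criterion or SeizureCriterion()
    x1 = sim.states[:, 0]
    step_ms = sim.time_ms[1] - sim.time_ms[0] if len(sim.time_ms) > 1 else 10.0
    dwell_n = max(1, int(round(crit.dwell_s * 1000.0 / step_ms)))
    above_onset = x1 > crit.onset_threshold
    above_sustain = x1 > crit.sustain_threshold
    idx = np.flatnonzero(above_onset)
    for i in idx:
        seg = above_sustain[i : i + dwell_n]
        if len(seg) >= dwell_n and seg.all():
            return float(sim.time_ms[i])
        # skip ahead past the first sustain failure to keep the scan linear
    return None


def detect_all_seizures(
    sim: SimulationResult,
    criterion: SeizureCriterion | None = None,
    refractory_s: float = 20.0,
) -> list[float]:
    """All ictal onsets, enforcing a refractory gap between detections."""
    crit = criterion or SeizureCriterion()
    onsets: list[float] = []
    x1 = sim.states[:, 0]
    step_ms = sim.time_ms[1] - sim.time_ms[0] if len(sim.time_ms) > 1 else 10.0
    dwell_n = max(1, int(round(crit.dwell_s * 1000.0 / step_ms)))
    refr_n = max(1, int(round(refractory_s * 1000.0 / step_ms)))
    above_onset = x1 > crit.onset_threshold
    above_sustain = x1 > crit.sustain_threshold
    i = 0
    n = len(x1)
    while i < n:
        if above_onset[i]:
            seg = above_sustain[i : i + dwell_n]
            if len(seg) >= dwell_n and seg.all():
                onsets.append(float(sim.time_ms[i]))
                i += refr_n
                continue
        i += 1
    return onsets


# ---------------------------------------------------------------------------
# fast-subsystem bifurcation diagram


@dataclass
class BifurcationDiagram:
    """Equilibria of the (x1, y1) fast subsystem with z as parameter."""

    z_grid: NDArray[np.float64]
    branches: list[list[tuple[float, bool]]]  # per z: [(x1, stable), ...]
    fold_z: float
    fold_x1: float

    def n_stable(self, i: int) -> int:
        return sum(1 for _, s in self.branches[i] if s)


def _fast_equilibria(
    z: float, params: EpileptorParams, x2_fixed: float
) -> list[tuple[float, bool]]:
    """Real equilibria of the frozen fast subsystem at permittivity z.

    x2 enters the ictal branch of f1 only; it is frozen at ``x2_fixed``
    because the slow subsystem is treated as a parameter here.
    """
    I1, y0 = params.I1_base, params.y0
    eq: list[tuple[float, bool]] = []
    # x1 < 0 branch: y0 - 5 x1^2 - (x1^3 - 3 x1^2) - z + I1 = 0
    roots = np.roots([-1.0, -2.0, 0.0, y0 + I1 - z])
    for r in roots:
        if abs(r.imag) < 1e-9 and r.real < 0:
            x1 = r.real
            # Jacobian of (x1, y1) subsystem on this branch
            df1 = 3 * x1**2 - 6 * x1
            eq.append((x1, _fast_stable(df1, x1)))
    # x1 >= 0 branch: y0 - 5 x1^2 - (x2 - 0.6 (z-4)^2) x1 - z + I1 = 0
    a = x2_fixed - 0.6 * (z - 4.0) ** 2
    disc = a * a + 20.0 * (y0 + I1 - z)
    if disc >= 0:
        for sign in (-1.0, 1.0):
            x1 = (-a + sign * np.sqrt(disc)) / 10.0
            if x1 >= 0:
                eq.append((x1, _fast_stable(a, x1)))
    return sorted(set(eq))


def _fast_stable(df1_dx1: float, x1: float) -> bool:
    # J = [[-df1, 1], [-10 x1, -1]]
    tr = -df1_dx1 - 1.0
    det = df1_dx1 - (-10.0 * x1)
    return tr < 0 and det > 0


def bifurcation_diagram(
    params: EpileptorParams,
    z_grid: Sequence[float],
    x2_fixed: float = 0.0,
) -> BifurcationDiagram:
    """S-shaped equilibrium diagram of the fast subsystem over z.

    The non-ictal (lower) stable branch and the middle unstable branch of
    the x1 < 0 cubic merge at a fold; its location is refined by bisection
    on lower-branch existence.  The grid must bracket the fold.
    """
    z_grid = np.asarray(sorted(z_grid), dtype=float)

    def has_lower(z: float) -> bool:
        return any(x1 < -1e-9 and st for x1, st in _fast_equilibria(z, params, x2_fixed))

    exists = np.array([has_lower(z) for z in z_grid])
    if exists.all() or not exists.any():
        raise ValueError("z grid does not bracket the fold of the non-ictal branch")
    # the non-ictal branch exists for z above the fold; bisect the boundary
    i = int(np.flatnonzero(exists)[0])
    hi, lo = z_grid[i], z_grid[i - 1]
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if has_lower(mid):
            hi = mid
        else:
            lo = mid
    fold_z = 0.5 * (lo + hi)
    # at the fold the stable and unstable x1<0 roots coincide at x1 = -4/3
    branches = [_fast_equilibria(z, params, x2_fixed) for z in z_grid]
    return BifurcationDiagram(
        z_grid=z_grid, branches=branches, fold_z=fold_z, fold_x1=-4.0 / 3.0
    )


def critical_x0(params: EpileptorParams) -> float:
    """x0 at which the full-system fixed point reaches the fast fold.

    The interictal equilibrium satisfies z* = 4 (x1* - x0); it collides
    with the fold of the fast subsystem (x1 = -4/3) when
    x0 = x1_fold - z_fold / 4.
    """
    diag = bifurcation_diagram(params, z_grid=[2.0, 3.5])
    return diag.fold_x1 - diag.fold_z / 4.0


# ---------------------------------------------------------------------------
# stimulation protocols


def build_stimulus(
    protocol: Literal["single-pulse", "paired-pulse", "train", "arrhythmic"],
    *,
    frequency_hz: float = 20.0,
    duration_s: float = 1.0,
    intensity_scale: float = 1.0,
    pulse_width_ms: float = 3.0,
    onset_ms: float = 0.0,
    inter_pulse_interval_ms: float = 50.0,
    seed: int | None = None,
) -> StimulusTrain:
    """Standard stimulation protocols as pulse-onset trains.

    ``train`` places pulses at 1/frequency spacing over ``duration_s``;
    ``arrhythmic`` draws exponentially distributed inter-pulse intervals at
    the same mean rate (fixed expected count, seeded); ``paired-pulse``
    places two pulses ``inter_pulse_interval_ms`` apart.
    """
    if protocol == "single-pulse":
        onsets = np.array([onset_ms])
    elif protocol == "paired-pulse":
        if not 0 < inter_pulse_interval_ms:
            raise ValueError("inter-pulse interval must be positive")
        onsets = np.array([onset_ms, onset_ms + inter_pulse_interval_ms])
    elif protocol == "train":
        if frequency_hz * duration_s < 1:
            raise ValueError("train must contain at least one pulse")
        n = int(round(frequency_hz * duration_s))
        onsets = onset_ms + np.arange(n) * 1000.0 / frequency_hz
    elif protocol == "arrhythmic":
        rng = np.random.default_rng(seed)
        n = int(round(frequency_hz * duration_s))
        gaps = rng.exponential(1000.0 / frequency_hz, size=n)
        onsets = onset_ms + np.cumsum(gaps)
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    return StimulusTrain(
        pulse_onsets_ms=onsets,
        pulse_width_ms=pulse_width_ms,
        amplitude_scale=intensity_scale,
        label=protocol,
    )


def time_to_seizure(
    params: EpileptorParams,
    frequency_hz: float = 20.0,
    intensity_scale: float = 1.0,
    max_duration_s: float = 120.0,
    criterion: SeizureCriterion | None = None,
    initial: EpileptorState | None = None,
    stochastic: bool = False,
    seed: int = 0,
    n_repeats: int = 1,
) -> float | None:
    """Stimulation duration (real s) needed to provoke a seizure.

    Simulates a continuous rhythmic train from the resting fixed point and
    returns the elapsed stimulation time at the detected onset, or None if
    no seizure occurs within ``max_duration_s``.

    The deterministic system integrates pulses with resonance-like
    alignment effects between pulse phase and recovery, so the duration is
    only coarsely monotone in frequency.  With ``stochastic=True`` the
    stated model noise smooths these out; ``n_repeats > 1`` averages
    independent realizations (runs without a seizure are censored at
    ``max_duration_s``).
    """
    if initial is None:
        initial = find_fixed_point(params)
    crit = criterion or SeizureCriterion()
    total_s = max_duration_s + crit.dwell_s + 5.0
    stim = build_stimulus(
        "train", frequency_hz=frequency_hz, duration_s=max_duration_s,
        intensity_scale=intensity_scale,
    )
    step_ms = params.dt * MS_PER_MODEL_UNIT
    n_steps = int(round(total_s * 1000.0 / step_ms))

    def one(run_seed: int) -> float | None:
        if stochastic:
            sim = integrate_stochastic(params, initial, stim, n_steps,
                                       seed=run_seed)
        else:
            sim = integrate_deterministic(params, initial, stim, n_steps)
        onset = detect_seizure(sim, crit)
        if onset is None or onset > max_duration_s * 1000.0:
            return None
        return onset / 1000.0

    if not stochastic or n_repeats == 1:
        return one(seed)
    seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)
    vals = [one(int(s)) for s in seeds]
    if all(v is None for v in vals):
        return None
    return float(np.mean([max_duration_s if v is None else v for v in vals]))
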