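"""Bistable adhesion-mode switch: mesenchymal vs amoeboid as two stable states.

The model is a minimal mutual-antagonism system between two dimensionless
engagement variables: ``I`` (integrin-mediated adhesion, sustaining the
mesenchymal state) and ``P`` (PAI-1-mediated engagement, sustaining the
amoeboid/blebbing state), driven by the local matrix-bound active PAI-1
concentration ``C``::

    dI/dt = alpha_I * K^h/(K^h + C^h) * 1/(1 + P^2) - mu * I
    dP/dt = alpha_P * C^h/(K^h + C^h) * 1/(1 + I^2) - mu * P

Rising C simultaneously gates integrin engagement off and PAI-1 engagement on
(Hill exponent ``h``); each variable additionally represses the other's
production. For sufficiently strong gains this creates a saddle-node pair and
a hysteretic cycle: the mesenchymal->amoeboid transition (MAT) happens at
``theta_up`` on an up-sweep of C, the reverse (AMT) at ``theta_down < theta_up``
on the way down. A cell is labeled amoeboid iff P > I (ties mesenchymal).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .errors import ConfigurationError, SweepError

__all__ = [
    "SwitchParams",
    "SwitchState",
    "HysteresisLoop",
    "step_switch",
    "step_switch_arrays",
    "steady_states",
    "bistable_window",
    "sweep_hysteresis",
    "fit_thresholds",
    "FitResult",
]

#: Quasi-static sweep criterion: time units spent per concentration unit must
#: be at least this multiple of 1/mu for the hysteresis loop to be trusted.
QUASI_STATIC_FACTOR = 50.0


@dataclass(frozen=True)
class SwitchParams:
    """Parameters of the adhesion-mode switch.

    ``K`` carries concentration units (half-saturation of the PAI-1 input);
    everything else is dimensionless or a rate. ``h >= 2`` is required for
    bistability. The bistable window sits at C ~ K; the default K places it
    mid-range of the peripheral bound-PAI-1 concentrations the CA/ABM stages
    produce under their default rates — an explicit calibration, not a
    biological measurement (the dynamics depend on C only through C/K).
    """

    alpha_I: float = 6.0
    alpha_P: float = 6.0
    K: float = 6.0
    h: float = 4.0
    mu: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha_I", "alpha_P", "K", "mu"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.h < 2:
            raise ConfigurationError(f"Hill exponent h must be >= 2, got {self.h}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass
class SwitchState:
    """Instantaneous engagement state of one cell."""

    I: float
    P: float

    @property
    def label(self) -> str:
        return "amoeboid" if self.P > self.I else "mesenchymal"

    @classmethod
    def mesenchymal_rest(cls, params: SwitchParams) -> "SwitchState":
        """The C = 0 resting state: full integrin engagement, no PAI-1 engagement."""
        return cls(I=params.alpha_I / params.mu, P=0.0)


@dataclass
class HysteresisLoop:
    theta_up: float
    theta_down: float
    loop_points: list[tuple[float, float, float, str]]  # (C, I, P, label)
    quasi_static: bool

    @property
    def width(self) -> float:
        return self.theta_up - self.theta_down


def _hill(C: float | np.ndarray, K: float, h: float) -> float | np.ndarray:
    Ch = np.power(C, h, dtype=np.float64)
    return Ch / (K**h + Ch)


def derivatives(
    I: float | np.ndarray, P: float | np.ndarray, C: float, p: SwitchParams
) -> tuple[np.ndarray, np.ndarray]:
    """Right-hand side of the switch ODE system."""
    hp = _hill(C, p.K, p.h)
    dI = p.alpha_I * (1.0 - hp) / (1.0 + np.square(P)) - p.mu * I
    dP = p.alpha_P * hp / (1.0 + np.square(I)) - p.mu * P
    return dI, dP


def step_switch_arrays(
    I: np.ndarray,
    P: np.ndarray,
    C: np.ndarray,
    params: SwitchParams,
    dt: float,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized explicit-Euler step for a population of cells.

    Optional Gaussian state noise of sd ``noise_sd*sqrt(dt)`` is added after the
    deterministic update, then both variables are clipped at 0.
    """
    if dt * params.mu >= 1:
        raise ConfigurationError(
            f"dt*mu must be < 1 for the explicit Euler step, got {dt * params.mu}"
        )
    dI, dP = derivatives(I, P, C, params)
    In = I + dt * dI
    Pn = P + dt * dP
    if params.noise_sd > 0 and rng is not None:
        s = params.noise_sd * np.sqrt(dt)
        In = In + rng.normal(0.0, s, np.shape(In))
        Pn = Pn + rng.normal(0.0, s, np.shape(Pn))
    return np.maximum(In, 0.0), np.maximum(Pn, 0.0)


def step_switch(
    state: SwitchState,
    C: float,
    params: SwitchParams,
    dt: float,
    rng: np.random.Generator | None = None,
) -> SwitchState:
    """One explicit-Euler step of a single cell's switch state."""
    if C < 0:
        raise ConfigurationError(f"concentration C must be >= 0, got {C}")
    I, P = step_switch_arrays(
        np.asarray(state.I), np.asarray(state.P), np.asarray(C), params, dt, rng
    )
    return SwitchState(float(I), float(P))


def _jacobian_stable(I: float, P: float, C: float, p: SwitchParams) -> bool:
    hp = _hill(C, p.K, p.h)
    dfdP = p.alpha_I * (1.0 - hp) * (-2.0 * P) / (1.0 + P**2) ** 2
    dgdI = p.alpha_P * hp * (-2.0 * I) / (1.0 + I**2) ** 2
    # eigenvalues are -mu +/- sqrt(dfdP*dgdI); cross product is >= 0 here
    return dfdP * dgdI < p.mu**2


def steady_states(
    C: float,
    params: SwitchParams,
    n_grid: int = 8,
    t_relax: float = 80.0,
    dt: float = 0.05,
    merge_tol: float = 1e-3,
) -> list[SwitchState]:
    """All stable equilibria at concentration ``C``.

    Relaxes the ODE from an ``n_grid x n_grid`` lattice of initial conditions
    covering [0, alpha/mu]^2, polishes the endpoints with a Newton root solve,
    de-duplicates, and keeps points passing the Jacobian stability check.
    Returns 1 state outside the bistable window and 2 inside it, amoeboid
    state first sorted by P.
    """
    noise_free = replace(params, noise_sd=0.0)
    gi = np.linspace(0.0, params.alpha_I / params.mu, n_grid)
    gp = np.linspace(0.0, params.alpha_P / params.mu, n_grid)
    I, P = [a.ravel() for a in np.meshgrid(gi, gp)]
    steps = int(t_relax / dt)
    Carr = np.full_like(I, C)
    for _ in range(steps):
        I, P = step_switch_arrays(I, P, Carr, noise_free, dt)

    found: list[tuple[float, float]] = []
    for i0, p0 in zip(I, P):
        sol, _info, ier, _msg = optimize.fsolve(
            lambda x: np.array(derivatives(x[0], x[1], C, noise_free)),
            [i0, p0],
            full_output=True,
        )
        if ier != 1:
            continue
        si, sp = float(sol[0]), float(sol[1])
        if si < -1e-9 or sp < -1e-9:
            continue
        si, sp = max(si, 0.0), max(sp, 0.0)
        res = derivatives(si, sp, C, noise_free)
        if abs(res[0]) > 1e-8 or abs(res[1]) > 1e-8:
            continue
        if not _jacobian_stable(si, sp, C, noise_free):
            continue
        if any(abs(si - a) < merge_tol and abs(sp - b) < merge_tol for a, b in found):
            continue
        found.append((si, sp))
    states = [SwitchState(a, b) for a, b in found]
    states.sort(key=lambda s: -s.P)
    return states


def bistable_window(
    params: SwitchParams,
    c_max: float | None = None,
    n_scan: int = 200,
) -> tuple[float, float]:
    """(C_low, C_high) bounds of the bistable window located by scanning C.

    Raises SweepError when no bistable concentration exists for these
    parameters (e.g. gains too weak).
    """
    c_max = c_max if c_max is not None else 4.0 * params.K
    cs = np.linspace(0.0, c_max, n_scan)
    bistable = [c for c in cs if len(steady_states(c, params)) >= 2]
    if not bistable:
        raise SweepError("no bistable window found for these parameters")
    return float(min(bistable)), float(max(bistable))


def sweep_hysteresis(
    params: SwitchParams,
    c_max: float,
    rate: float | None = None,
    dt: float = 0.05,
    n_record: int = 400,
    rng: np.random.Generator | None = None,
) -> HysteresisLoop:
    """Quasi-static triangular sweep 0 -> c_max -> 0 recording the label flips.

    ``rate`` is the sweep slowness in time units per concentration unit;
    default is the quasi-static criterion 50/mu. A faster sweep is allowed but
    flagged ``quasi_static=False``. Raises SweepError if the up-sweep never
    produces the mesenchymal->amoeboid transition (c_max below the window).
    """
    if c_max <= 0:
        raise ConfigurationError("c_max must be > 0")
    min_rate = QUASI_STATIC_FACTOR / params.mu
    if rate is None:
        rate = min_rate
    quasi_static = rate >= min_rate
    duration = 2.0 * c_max * rate
    n_steps = max(int(duration / dt), 2)
    t = np.linspace(0.0, duration, n_steps)
    c_path = np.where(t <= duration / 2, t / rate, (duration - t) / rate)

    state = SwitchState.mesenchymal_rest(params)
    I, P = np.asarray(state.I), np.asarray(state.P)
    theta_up = None
    theta_down = None
    prev_label = "mesenchymal"
    record_every = max(n_steps // n_record, 1)
    points: list[tuple[float, float, float, str]] = []
    for k, c in enumerate(c_path):
        I, P = step_switch_arrays(I, P, np.asarray(c), params, dt, rng)
        label = "amoeboid" if P > I else "mesenchymal"
        if label != prev_label:
            going_up = k < n_steps / 2
            if going_up and prev_label == "mesenchymal" and theta_up is None:
                theta_up = float(c)
            elif not going_up and prev_label == "amoeboid" and theta_down is None:
                theta_down = float(c)
            prev_label = label
        if k % record_every == 0:
            points.append((float(c), float(I), float(P), label))
    if theta_up is None:
        raise SweepError(
            f"no transition reached: c_max={c_max} never switched the cell"
        )
    if theta_down is None:
        theta_down = 0.0  # cell never reverted within the sweep
    return HysteresisLoop(theta_up, theta_down, points, quasi_static)


@dataclass
class FitResult:
    params: SwitchParams
    theta_up: float
    theta_down: float
    residual: float
    identifiable: bool
    K_interval: tuple[float, float]


def predict_blebbing_fraction(
    params: SwitchParams,
    times: np.ndarray,
    c_of_t: np.ndarray,
    p_b: float = 0.9,
    dt: float = 0.05,
) -> np.ndarray:
    """Model-predicted blebbing fraction along a concentration schedule.

    Integrates a single noise-free trajectory (all cells are identical without
    state noise) and maps the amoeboid label to blebbing with emission
    probability ``p_b``.
    """
    state = SwitchState.mesenchymal_rest(params)
    I, P = np.asarray(state.I), np.asarray(state.P)
    noise_free = replace(params, noise_sd=0.0)
    out = np.empty(len(times))
    t_now = 0.0
    for i, (t_target, c) in enumerate(zip(times, c_of_t)):
        while t_now < t_target - 1e-12:
            step = min(dt, t_target - t_now)
            I, P = step_switch_arrays(I, P, np.asarray(c), noise_free, step)
            t_now += step
        out[i] = p_b if P > I else 0.0
    return out


def _predict_blebbing_all_K(
    params: SwitchParams,
    ks: np.ndarray,
    times: np.ndarray,
    c_of_t: np.ndarray,
    p_b: float,
    dt: float = 0.05,
) -> np.ndarray:
    """Blebbing-fraction predictions for a whole vector of candidate K values.

    Integrates one noise-free trajectory per candidate simultaneously (the
    per-K systems are independent, so the Euler step vectorizes over K).
    Returns an array of shape (len(ks), len(times)).
    """
    n = len(ks)
    I = np.full(n, params.alpha_I / params.mu)
    P = np.zeros(n)
    Kh = np.power(ks, params.h)
    out = np.empty((n, len(times)))
    t_now = 0.0
    for j, (t_target, c) in enumerate(zip(times, c_of_t)):
        Ch = c**params.h
        hp = Ch / (Kh + Ch)
        prod_I = params.alpha_I * (1.0 - hp)
        prod_P = params.alpha_P * hp
        while t_now < t_target - 1e-12:
            step = min(dt, t_target - t_now)
            In = I + step * (prod_I / (1.0 + P**2) - params.mu * I)
            Pn = P + step * (prod_P / (1.0 + I**2) - params.mu * P)
            I, P = np.maximum(In, 0.0), np.maximum(Pn, 0.0)
            t_now += step
        out[:, j] = np.where(P > I, p_b, 0.0)
    return out


def fit_thresholds(
    times: np.ndarray,
    blebbing_fraction: np.ndarray,
    c_of_t: np.ndarray,
    params_init: SwitchParams,
    p_b: float = 0.9,
    scan_span: tuple[float, float] = (0.5, 2.0),
    n_scan: int = 161,
) -> FitResult:
    """Recover the switch thresholds from an observed morphology time-course.

    The half-saturation ``K`` sets the concentration scale of the whole cycle
    (the dynamics depend on C only through C/K), so the fit scans ``K`` over
    ``scan_span`` times its initial value on a log grid, minimizing the sum of
    squared deviations between the model-predicted and observed blebbing
    fractions, then reports the hysteresis thresholds of the fitted model.

    A flat residual landscape (non-identifiable schedule, e.g. C never crossing
    a threshold) is flagged and reported with a wide ``K_interval``.
    """
    times = np.asarray(times, float)
    obs = np.asarray(blebbing_fraction, float)
    c_of_t = np.asarray(c_of_t, float)
    if times.shape != obs.shape or times.shape != c_of_t.shape:
        raise ConfigurationError("times, blebbing_fraction and c_of_t must align")
    ks = params_init.K * np.exp(
        np.linspace(np.log(scan_span[0]), np.log(scan_span[1]), n_scan)
    )
    preds = _predict_blebbing_all_K(params_init, ks, times, c_of_t, p_b)
    sse = np.sum((preds - obs[None, :]) ** 2, axis=1)
    best = int(np.argmin(sse))
    spread = sse.max() - sse.min()
    identifiable = spread > 1e-9 * max(sse.max(), 1.0)
    if identifiable:
        # centroid of the near-optimal plateau: the objective is piecewise
        # constant in K between sampled flip times
        near = ks[sse <= sse[best] + 1e-12]
        k_fit = float(np.exp(np.mean(np.log(near))))
        k_lo, k_hi = float(near.min()), float(near.max())
    else:
        k_fit = params_init.K
        k_lo, k_hi = float(ks.min()), float(ks.max())
    fitted = replace(params_init, K=k_fit, noise_sd=0.0)
    loop = sweep_hysteresis(fitted, c_max=4.0 * k_fit)
    return FitResult(
        params=fitted,
        theta_up=loop.theta_up,
        theta_down=loop.theta_down,
        residual=float(sse[best]),
        identifiable=identifiable,
        K_interval=(k_lo, k_hi),
    )
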