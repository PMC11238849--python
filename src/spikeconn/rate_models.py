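"""Doubly stochastic (Cox) spike-pair generators and their analytic CCs.

Two conditionally independent Poisson trains driven by a shared rate
process produce correlogram structure without any synaptic connection:
smooth oscillatory rates yield smooth undulation, while rate processes
that are not mean-square differentiable (Ornstein–Uhlenbeck, random
telegraph) yield an exponential cusp at zero lag.  Closed forms:

- sinusoid:  c12(t) = r1*r2 + (a1*a2/2) cos(ω t + φ)
- gabor:     c12(t) = r1*r2 + (a1*a2/2) exp(-t²/2δ²) cos(ω t + φ)
- ou / telegraph:  c(t) = μ² + σ² exp(-2|t|/τr)

The OU and telegraph processes share the same CC despite entirely
different sample paths — the correlogram does not identify the rate
process.  ``inject_synaptic_pair`` is the generative twin of the GLM
observation model and provides labelled ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spike_data import SpikeTrain, _bare_train

__all__ = [
    "RateModelSpec",
    "RatePath",
    "SynapticTruth",
    "sample_rate_path",
    "sample_inhomogeneous_poisson",
    "generate_pair",
    "analytic_cc",
    "inject_synaptic_pair",
]

_VARIANTS = ("sinusoid", "gabor", "ou", "telegraph", "mixture")


@dataclass(frozen=True)
class RateModelSpec:
    """Parameters of a shared-rate pair model.

    All rates in spikes/s, times in seconds, ``omega`` in rad/s.  For the
    oscillatory variants the second unit's rate uses ``(r2, a2)`` with
    phase lag ``phi``; ``lag`` shifts the second unit's whole rate path in
    time.  For ou/telegraph both units follow one path with mean ``mu``,
    stationary SD ``sigma`` and fluctuation timescale ``tau_r``.  The
    mixture variant superposes a sinusoid (amplitude ``a1``) on an OU
    fluctuation (SD ``sigma``) around ``mu``.
    """

    variant: str
    r1: float = 20.0
    r2: float = 20.0
    a1: float = 0.0
    a2: float = 0.0
    omega: float = 2 * np.pi * 5.0
    phi: float = 0.0
    delta: float = 0.2
    mu: float = 20.0
    sigma: float = 8.0
    tau_r: float = 0.02
    lag: float = 0.0
    gabor_window: float = 10.0

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "sinusoid" and (self.r1 - abs(self.a1) < 0
                                           or self.r2 - abs(self.a2) < 0):
            raise ValueError("sinusoid requires r - |a| >= 0 (non-negative rate)")
        if self.variant == "telegraph" and self.mu - self.sigma < 0:
            raise ValueError("telegraph requires mu - sigma >= 0")


@dataclass(frozen=True)
class RatePath:
    """A rate realization on a uniform grid (values in spikes/s, never negative)."""

    t: np.ndarray  # s
    values: np.ndarray  # spikes/s

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if self.t.size != self.values.size:
            raise ValueError("grid and values must match")
        if np.any(self.values < 0):
            raise ValueError("rates must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else 0.0

    @property
    def duration(self) -> float:
        return float(self.t.size * self.dt)


@dataclass(frozen=True)
class SynapticTruth:
    """Ground truth of an injected monosynaptic pair."""

    J: float
    tau_s: float  # ms
    d: float  # ms
    r_pre: float
    r_post: float


def _check_dt(spec: RateModelSpec, dt: float):
    if spec.variant in ("ou", "telegraph", "mixture") and dt > spec.tau_r / 10:
        raise ValueError(
            f"dt={dt} too coarse for tau_r={spec.tau_r}; need dt <= tau_r/10"
        )


def _ou_path(mu, sigma, tau_r, n, dt, rng):
    """Exact Gaussian transition of the OU process with relaxation rate
    2/tau_r and stationary SD sigma (autocovariance σ² e^{-2|t|/τr})."""
    from scipy.signal import lfilter

    rho = np.exp(-2.0 * dt / tau_r)
    s = sigma * np.sqrt(1.0 - rho * rho)
    z = s * rng.standard_normal(n)
    z[0] = sigma * rng.standard_normal()  # stationary start
    dev = lfilter([1.0], [1.0, -rho], z)  # AR(1) recursion
    return mu + dev


def _telegraph_path(mu, sigma, tau_r, n, dt, rng):
    """Two-state rate with exponential holding times of mean tau_r."""
    x = np.empty(n)
    state = 1 if rng.random() < 0.5 else -1
    i = 0
    while i < n:
        hold = rng.exponential(tau_r)
        j = min(n, i + max(1, int(round(hold / dt))))
        x[i:j] = mu + state * sigma
        state = -state
        i = j
    return x


def sample_rate_path(spec: RateModelSpec, duration: float, dt: float,
                     seed: int) -> RatePath:
    """Sample (or evaluate) one rate path r(t) on a grid of step *dt* s.

    Deterministic for sinusoid/gabor (the gabor sampler draws one frequency
    per ``gabor_window``-second window, normal around ω with SD 1/δ);
    stochastic variants require ``dt <= tau_r/10``.  Paths are clipped at 0.
    """
    _check_dt(spec, dt)
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    t = dt * np.arange(n)
    if spec.variant == "sinusoid":
        v = spec.r1 + spec.a1 * np.sin(spec.omega * t)
    elif spec.variant == "gabor":
        v = np.empty(n)
        nw = max(1, int(round(spec.gabor_window / dt)))
        for i0 in range(0, n, nw):
            w = spec.omega + rng.standard_normal() / spec.delta
            tt = t[i0:i0 + nw]
            v[i0:i0 + nw] = spec.r1 + spec.a1 * np.sin(w * tt)
    elif spec.variant == "ou":
        v = _ou_path(spec.mu, spec.sigma, spec.tau_r, n, dt, rng)
    elif spec.variant == "telegraph":
        v = _telegraph_path(spec.mu, spec.sigma, spec.tau_r, n, dt, rng)
    else:  # mixture: sinusoid riding on an OU fluctuation
        ou = _ou_path(0.0, spec.sigma, spec.tau_r, n, dt, rng)
        v = spec.mu + spec.a1 * np.sin(spec.omega * t) + ou
    return RatePath(t, np.clip(v, 0.0, None))


def sample_inhomogeneous_poisson(path: RatePath, seed: int,
                                 unit_id: int = 0) -> SpikeTrain:
    """Thinning sampler: homogeneous candidates at max(r), kept with
    probability r(t)/max(r) (piecewise-constant rate over grid steps)."""
    rng = np.random.default_rng(seed)
    rmax = float(path.values.max(initial=0.0))
    T = path.duration
    if rmax <= 0 or T <= 0:
        return _bare_train(unit_id, np.empty(0), 0.0, T)
    n_cand = rng.poisson(rmax * T)
    cand = np.sort(rng.uniform(0.0, T, size=n_cand))
    idx = np.minimum((cand / path.dt).astype(np.int64), path.values.size - 1)
    keep = rng.uniform(0.0, rmax, size=n_cand) < path.values[idx]
    return _bare_train(unit_id, cand[keep], 0.0, T)


def _second_path(spec: RateModelSpec, duration, dt, rng, shared=None):
    """Rate path of the second unit: phase lag for oscillatory variants,
    the shared realization (time-shifted by ``lag``) for stochastic ones."""
    n = int(round(duration / dt))
    t = dt * np.arange(n)
    if spec.variant == "sinusoid":
        v = spec.r2 + spec.a2 * np.sin(spec.omega * (t - spec.lag) + spec.phi)
        return RatePath(t, np.clip(v, 0.0, None))
    if spec.variant == "gabor":
        raise AssertionError("gabor handled jointly")  # pragma: no cover
    # shared stochastic path, shifted by lag
    shift = int(round(spec.lag / dt))
    v = np.roll(shared, shift)
    return RatePath(t, v)


def generate_pair(spec: RateModelSpec, duration: float, dt: float,
                  seed: int) -> tuple[SpikeTrain, SpikeTrain]:
    """Two conditionally independent Poisson trains sharing one rate path.

    No spike of either train influences the other; all correlation comes
    through the common (or phase-lagged) rate.
    """
    _check_dt(spec, dt)
    rng = np.random.default_rng(seed)
    s_path, s1, s2 = rng.integers(0, 2**31 - 1, size=3)
    if spec.variant == "sinusoid":
        p1 = sample_rate_path(spec, duration, dt, int(s_path))
        p2 = _second_path(spec, duration, dt, rng)
    elif spec.variant == "gabor":
        # both units share the per-window frequency draws
        n = int(round(duration / dt))
        t = dt * np.arange(n)
        v1 = np.empty(n)
        v2 = np.empty(n)
        wrng = np.random.default_rng(int(s_path))
        nw = max(1, int(round(spec.gabor_window / dt)))
        for i0 in range(0, n, nw):
            w = spec.omega + wrng.standard_normal() / spec.delta
            tt = t[i0:i0 + nw]
            v1[i0:i0 + nw] = spec.r1 + spec.a1 * np.sin(w * tt)
            v2[i0:i0 + nw] = spec.r2 + spec.a2 * np.sin(w * (tt - spec.lag) + spec.phi)
        p1 = RatePath(t, np.clip(v1, 0.0, None))
        p2 = RatePath(t, np.clip(v2, 0.0, None))
    else:
        p1 = sample_rate_path(spec, duration, dt, int(s_path))
        p2 = _second_path(spec, duration, dt, rng, shared=p1.values)
    tr1 = sample_inhomogeneous_poisson(p1, int(s1), unit_id=0)
    tr2 = sample_inhomogeneous_poisson(p2, int(s2), unit_id=1)
    return tr1, tr2


def analytic_cc(spec: RateModelSpec, lags_ms) -> np.ndarray:
    """Closed-form CC (pair-rate density, spikes²/s²) at the given lags (ms)."""
    t = np.asarray(lags_ms, float) * 1e-3
    if spec.variant == "sinusoid":
        return spec.r1 * spec.r2 + 0.5 * spec.a1 * spec.a2 * np.cos(
            spec.omega * (t - spec.lag) + spec.phi)
    if spec.variant == "gabor":
        tt = t - spec.lag
        return spec.r1 * spec.r2 + 0.5 * spec.a1 * spec.a2 * np.exp(
            -tt * tt / (2 * spec.delta**2)) * np.cos(spec.omega * tt + spec.phi)
    if spec.variant in ("ou", "telegraph"):
        tt = np.abs(t - spec.lag)
        return spec.mu**2 + spec.sigma**2 * np.exp(-2.0 * tt / spec.tau_r)
    raise ValueError(f"no closed-form CC for variant {spec.variant!r}")


def inject_synaptic_pair(r_pre: float, r_post: float, J: float,
                         tau_s: float = 2.0, d: float = 2.0,
                         duration: float = 3600.0,
                         background: RateModelSpec | None = None,
                         seed: int = 0, dt: float = 1e-4,
                         intensity_cap: float = 1000.0,
                         ) -> tuple[SpikeTrain, SpikeTrain, SynapticTruth]:
    """Generate a pre/post pair with a true monosynaptic coupling.

    The postsynaptic intensity is ``r_post(t) * exp(J * Σ_k f(t - t_k))``
    with f the delayed exponential synaptic kernel (``tau_s``, ``d`` in
    ms) and ``t_k`` the presynaptic spikes.  A *background* rate spec, if
    given, modulates both units' base rates with a shared path.

    Raises ``ValueError`` if the resulting intensity exceeds
    *intensity_cap* spikes/s (suggesting a smaller J).
    """
    rng = np.random.default_rng(seed)
    s_bg, s_pre, s_post = rng.integers(0, 2**31 - 1, size=3)
    n = int(round(duration / dt))
    if background is not None:
        bg = sample_rate_path(background, duration, dt, int(s_bg)).values
        bg_mean = max(bg.mean(), 1e-12)
        pre_rate = bg * (r_pre / bg_mean)
        post_base = bg * (r_post / bg_mean)
    else:
        pre_rate = np.full(n, float(r_pre))
        post_base = np.full(n, float(r_post))
    t_grid = dt * np.arange(n)
    pre = sample_inhomogeneous_poisson(RatePath(t_grid, pre_rate), int(s_pre), 0)

    # synaptic drive s(t) = Σ_k f(t - t_k) via exact exponential recursion
    from scipy.signal import lfilter

    decay = np.exp(-dt * 1e3 / tau_s)
    impulses = np.zeros(n)
    arrive = ((pre.times + d * 1e-3) / dt).astype(np.int64)
    arrive = arrive[arrive < n]
    np.add.at(impulses, arrive, 1.0)
    s = lfilter([1.0], [1.0, -decay], impulses)
    lam = post_base * np.exp(J * s)
    if lam.max(initial=0.0) > intensity_cap:
        raise ValueError(
            f"postsynaptic intensity {lam.max():.1f}/s exceeds cap "
            f"{intensity_cap}/s; use a smaller J or lower rates"
        )
    post = sample_inhomogeneous_poisson(RatePath(t_grid, lam), int(s_post), 1)
    return pre, post, SynapticTruth(J, tau_s, d, r_pre, r_post)
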