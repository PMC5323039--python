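"""Position-dependent diffusion coefficient from restrained windows.

For an ion confined near z₀ (harmonic well or flat-bottom disk), the local
diffusion coefficient follows from the fluctuation statistics of its
z-coordinate:

    D(z₀) = var(z) / τ(z),    τ = ∫₀^cutoff ⟨δz(0)δz(t)⟩ dt / var(z),

with δz = z − ⟨z⟩.  For an Ornstein–Uhlenbeck process (harmonic well k,
temperature T) this identity is exact in expectation for any (k, D₀):
var = k_BT/k and τ = k_BT/(D₀k), so var/τ = D₀.  A profile D(z) is built
from many windows spanning the pore axis and interpolated with a natural
cubic spline; per-window error bars come from splitting each window's
samples in half.

Autocorrelations use the biased (1/N) normalisation, which keeps the
integrated correlation time stable against the noisy tail at long lags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.interpolate import CubicSpline

from .profiles import Profile1D


@dataclass
class WindowTrajectory:
    """z-samples of one restrained window at uniform time spacing ``dt`` (ps)."""

    center: float
    samples: np.ndarray
    dt: float
    half_length: float = 1.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 2:
            raise ValueError("a window needs at least two samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")
        if self.dt <= 0:
            raise ValueError("sample spacing dt must be positive")

    @property
    def span_ps(self) -> float:
        return (self.samples.size - 1) * self.dt


class AutocorrResult(NamedTuple):
    lags: np.ndarray        # ps
    values: np.ndarray      # same units as var(z)
    degenerate: bool        # constant input series


class CorrelationTime(NamedTuple):
    tau: float              # ps
    converged: bool         # plateau test over the last 20% of lags


def autocorrelation(samples, max_lag: float, dt: float) -> AutocorrResult:
    """Biased (1/N) autocovariance ⟨δz(0)δz(t)⟩ up to ``max_lag`` via FFT.

    C(0) equals the (biased) sample variance exactly.  A constant series
    returns C ≡ 0 with the degeneracy flag set.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if max_lag >= (n - 1) * dt:
        raise ValueError("max_lag must be smaller than the sample span")
    n_lags = int(np.floor(max_lag / dt)) + 1
    dx = x - x.mean()
    if np.allclose(dx, 0.0):
        lags = np.arange(n_lags) * dt
        return AutocorrResult(lags, np.zeros(n_lags), True)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(dx, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n_lags] / n
    lags = np.arange(n_lags) * dt
    return AutocorrResult(lags, acov, False)


def correlation_time(samples, cutoff: float, dt: float, plateau_rtol: float = 0.02) -> CorrelationTime:
    """Integrated correlation time τ = ∫₀^cutoff C(t)/C(0) dt (trapezoidal).

    The convergence flag reports a plateau test: the running integral over
    the last 20% of the lag range must vary by less than ``plateau_rtol``
    relative to its final value.  A non-plateaued integral warns but the
    value is still returned.
    """
    ac = autocorrelation(samples, cutoff, dt)
    if ac.degenerate:
        raise ValueError("constant series: correlation time undefined")
    norm = ac.values / ac.values[0]
    running = np.concatenate(([0.0], np.cumsum((norm[1:] + norm[:-1]) / 2.0 * dt)))
    tau = float(running[-1])
    tail = running[int(0.8 * (running.size - 1)):]
    scale = max(abs(tau), dt)
    converged = bool(np.max(np.abs(tail - tau)) <= plateau_rtol * scale)
    if not converged:
        warnings.warn(
            f"correlation-time integral not plateaued at cutoff {cutoff} ps",
            RuntimeWarning,
            stacklevel=2,
        )
    return CorrelationTime(tau=tau, converged=converged)


def auto_cutoff(samples, dt: float, factor: float = 7.0, max_iter: int = 8) -> float:
    """Self-consistent integration cutoff ≈ ``factor`` correlation times.

    Iterates τ̂ → cutoff = factor·τ̂ until stable (Sokal-style windowing):
    a cutoff much shorter than τ truncates the integral, one much longer
    only accumulates noise from the autocorrelation tail.
    """
    span = (np.asarray(samples).size - 1) * dt
    cutoff = min(60.0 * dt, span / 4)
    for _ in range(max_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tau = max(correlation_time(samples, cutoff, dt).tau, dt)
        new = float(np.clip(factor * tau, 10 * dt, span / 4))
        if abs(new - cutoff) <= 0.2 * cutoff:
            return new
        cutoff = new
    return cutoff


def window_diffusion(window: WindowTrajectory, cutoff: float = 100.0) -> float:
    """D = var(z)/τ(z) for one window (Å²/ps)."""
    var = float(np.var(window.samples))
    tau = correlation_time(window.samples, cutoff, window.dt).tau
    if tau <= 0:
        raise ValueError(f"non-positive correlation time τ={tau:.4g} ps")
    return var / tau


@dataclass
class DiffusionProfile:
    """Point estimates D(z_i) with half-split errors and a cubic-spline interpolant."""

    profile: Profile1D
    spline: CubicSpline = field(repr=False)

    def __call__(self, z):
        return self.spline(z)


def diffusion_profile(windows: list, cutoff: float = 100.0) -> DiffusionProfile:
    """Build D(z) from windowed estimates (natural cubic spline through points).

    Windows must be sorted by center with no duplicates.  The error bar of
    each window is |D_half1 − D_half2| from the two halves of its samples.
    """
    if len(windows) < 2:
        raise ValueError("need at least two windows")
    centers = np.array([w.center for w in windows], dtype=float)
    if np.any(np.diff(centers) <= 0):
        raise ValueError("window centers must be strictly increasing (no duplicates)")
    estimates = np.empty(centers.size)
    errs = np.empty(centers.size)
    for i, w in enumerate(windows):
        estimates[i] = window_diffusion(w, cutoff)
        mid = w.samples.size // 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d1 = window_diffusion(WindowTrajectory(w.center, w.samples[:mid], w.dt, w.half_length), cutoff)
            d2 = window_diffusion(WindowTrajectory(w.center, w.samples[mid:], w.dt, w.half_length), cutoff)
        errs[i] = abs(d1 - d2)
    prof = Profile1D(centers, estimates, errs, units=("A", "A2_per_ps"))
    return DiffusionProfile(profile=prof, spline=CubicSpline(centers, estimates, bc_type="natural"))


def windows_from_trajectory(traj, centers, half_length: float = 1.0, equilibration_ps: float = 0.0) -> list:
    """Slice a multi-particle trajectory (one particle per window) into windows."""
    centers = np.asarray(centers, dtype=float)
    if centers.size != traj.n_particles:
        raise ValueError("need exactly one trajectory particle per window center")
    dt = float(traj.times[1] - traj.times[0])
    keep = traj.times >= equilibration_ps
    return [
        WindowTrajectory(center=float(c), samples=traj.positions[keep, i, 2], dt=dt, half_length=half_length)
        for i, c in enumerate(centers)
    ]
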