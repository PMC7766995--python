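"""Orientational dynamics and NMR spin-lattice relaxation observables.

The pipeline here is: unit-vector time series (H-H vectors of CH2 groups,
or core-to-end vectors) -> first/second-order Legendre orientational
autocorrelation functions P1(t), P2(t) (and the normalised size-pulsation
ACF for scalar series such as Rg^2(t)) -> spectral density J(w) by cosine
transform of P2 -> reduced spin-lattice relaxation rate w[J(w) + 4 J(2w)]
-> physical 1/T1H in the susceptibility representation via A0/wH.

ACFs are estimated with all time origins (FFT-based) and averaged over
vector instances; the lag window defaults to 10% of the trajectory length
for variance control.  The cosine transform integrates the piecewise-linear
interpolant of the sampled P2 exactly at every frequency and adds an
analytic tail from a multi-exponential fit, so J is accurate both for
w*dt ~ 1 and for frequencies far below the sampled window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

#: theoretical dipolar prefactor for CH2 protons (s^-2)
A0_THEORY = 0.56e10
#: spectrometer angular frequency, 400 MHz proton resonance (rad/s)
OMEGA_H = 2 * np.pi * 400e6


class AnalysisError(ValueError):
    pass


@dataclass
class VectorSeries:
    """Unit-vector trajectories: shape (n_frames, n_instances, 3)."""

    times: np.ndarray
    vectors: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        v = np.asarray(self.vectors)
        if not np.issubdtype(v.dtype, np.floating):
            v = v.astype(np.float64)
        if v.ndim == 2:
            v = v[:, None, :]
        # chunk-wise, in-place normalisation: series can be very large
        for lo in range(0, len(v), 4096):
            blk = v[lo:lo + 4096]
            norm = np.linalg.norm(blk, axis=2, keepdims=True)
            if np.any(norm <= 0):
                raise AnalysisError("zero-length vector in series")
            if np.max(np.abs(norm - 1.0)) > 1e-6:
                blk /= norm
        self.vectors = v

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class CorrelationFunction:
    """Lag-indexed ACF with origin-averaging metadata."""

    lags: np.ndarray        # ps
    values: np.ndarray
    order: str              # "P1" | "P2" | "scalar"
    n_instances: int = 1
    n_time_origins: int = 0

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])


def _fft_corr_sums(x: np.ndarray, max_lag: int) -> np.ndarray:
    """sum_t x[t] x[t+lag] for each column, via FFT.  x: (n, k).

    Single precision inputs are transformed in single precision (adequate:
    the correlation sums are averaged over >> 1/eps32 effective samples
    only in pathological cases) which roughly halves the cost.
    """
    from scipy import fft as sfft

    n = x.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = sfft.rfft(x, nfft, axis=0)
    corr = sfft.irfft(f * np.conj(f), nfft, axis=0)[:max_lag + 1]
    return corr.astype(np.float64, copy=False)


def _check_uniform(times: np.ndarray) -> None:
    steps = np.diff(times)
    if len(steps) and np.max(steps) - np.min(steps) > 1e-6 * np.max(steps):
        raise AnalysisError("ACF estimation requires uniform time spacing")


def _resolve_max_lag(n: int, max_lag: int | None,
                     max_lag_frac: float) -> int:
    if max_lag is None:
        max_lag = max(1, int(n * max_lag_frac))
    return min(max_lag, n - 1)


def acf_p1(series: VectorSeries, max_lag: int | None = None,
           max_lag_frac: float = 0.1) -> CorrelationFunction:
    """First-order orientational ACF P1(t) = <u(t0) . u(t0+t)>."""
    _check_uniform(series.times)
    n, m, _ = series.vectors.shape
    max_lag = _resolve_max_lag(n, max_lag, max_lag_frac)
    counts = n - np.arange(max_lag + 1)
    total = np.zeros(max_lag + 1)
    for i in range(m):
        total += _fft_corr_sums(series.vectors[:, i, :], max_lag).sum(axis=1)
    values = total / (counts * m)
    return CorrelationFunction(series.dt * np.arange(max_lag + 1), values,
                               "P1", n_instances=m, n_time_origins=n)


def acf_p2(series: VectorSeries, max_lag: int | None = None,
           max_lag_frac: float = 0.1) -> CorrelationFunction:
    """Second-order orientational ACF P2(t) = <3 (u.u')^2 - 1>/2.

    (u(t0).u(t0+t))^2 expands into correlations of the 6 independent
    quadratic products u_a u_b, which are FFT-correlated directly.
    """
    _check_uniform(series.times)
    n, m, _ = series.vectors.shape
    max_lag = _resolve_max_lag(n, max_lag, max_lag_frac)
    counts = n - np.arange(max_lag + 1)
    pairs = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
    wts = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
    total = np.zeros(max_lag + 1)
    for i in range(m):
        u = series.vectors[:, i, :]
        prods = np.stack([u[:, a] * u[:, b] for a, b in pairs], axis=1)
        total += _fft_corr_sums(prods, max_lag) @ wts
    dot_sq = total / (counts * m)
    values = 1.5 * dot_sq - 0.5
    return CorrelationFunction(series.dt * np.arange(max_lag + 1), values,
                               "P2", n_instances=m, n_time_origins=n)


def acf_scalar(times: np.ndarray, values: np.ndarray,
               max_lag: int | None = None,
               max_lag_frac: float = 0.1) -> CorrelationFunction:
    """Normalised fluctuation ACF of a scalar series (e.g. Rg^2 pulsation).

    C(t) = (<x(t0) x(t0+t)> - <x>^2) / (<x^2> - <x>^2); raises on a
    constant series (zero variance).
    """
    times = np.asarray(times, float)
    _check_uniform(times)
    x = np.asarray(values, float)
    n = len(x)
    max_lag = _resolve_max_lag(n, max_lag, max_lag_frac)
    dx = x - x.mean()
    var = np.mean(dx ** 2)
    if var <= 1e-12 * max(1.0, abs(x.mean())) ** 2:
        raise AnalysisError("zero-variance scalar series")
    counts = n - np.arange(max_lag + 1)
    corr = _fft_corr_sums(dx[:, None], max_lag)[:, 0] / counts / var
    dt = float(times[1] - times[0])
    return CorrelationFunction(dt * np.arange(max_lag + 1), corr, "scalar",
                               n_time_origins=n)


# ---------------------------------------------------------------------------
# characteristic times
# ---------------------------------------------------------------------------

@dataclass
class CharacteristicTime:
    tau: float          # ps; lower bound if censored
    censored: bool


def characteristic_time(cf: CorrelationFunction,
                        level: float = 1.0 / np.e) -> CharacteristicTime:
    """First crossing time of the ACF below ``level`` (default 1/e).

    The crossing is located by log-linear interpolation between the
    bracketing lags; if the ACF never reaches the level in the window the
    result is censored and reports the window end as a lower bound.
    """
    v = cf.values
    below = np.flatnonzero(v < level)
    if len(below) == 0:
        return CharacteristicTime(float(cf.lags[-1]), censored=True)
    i = below[0]
    if i == 0:
        return CharacteristicTime(0.0, censored=False)
    v0, v1 = v[i - 1], v[i]
    if v1 > 0 and v0 > 0:
        frac = (np.log(v0) - np.log(level)) / (np.log(v0) - np.log(v1))
    else:
        frac = (v0 - level) / (v0 - v1)
    tau = cf.lags[i - 1] + frac * (cf.lags[i] - cf.lags[i - 1])
    return CharacteristicTime(float(tau), censored=False)


@dataclass
class P1CubedReport:
    """Deviation of P2(t) from P1(t)^3 (exact for isotropic diffusion)."""

    max_abs_deviation: float
    n_lags: int
    tolerance: float

    @property
    def passed(self) -> bool:
        return self.max_abs_deviation < self.tolerance


def p1_cubed_check(p1: CorrelationFunction, p2: CorrelationFunction,
                   p1_floor: float = 0.1,
                   tolerance: float = 1e-2) -> P1CubedReport:
    """Compare P2 with P1^3 over lags where P1 > ``p1_floor``."""
    n = min(len(p1.values), len(p2.values))
    mask = p1.values[:n] > p1_floor
    dev = np.abs(p2.values[:n][mask] - p1.values[:n][mask] ** 3)
    return P1CubedReport(float(dev.max()) if mask.any() else 0.0,
                         int(mask.sum()), tolerance)


# ---------------------------------------------------------------------------
# spectral density and relaxation rates
# ---------------------------------------------------------------------------

def fit_multi_exponential(lags: np.ndarray, values: np.ndarray,
                          max_terms: int = 3) -> list[tuple[float, float]]:
    """Fit values ~ sum_i a_i exp(-t/tau_i); order chosen by AIC.

    Amplitudes are solved linearly for trial decay times (variable
    projection); decay times are optimised in log space.  Returns
    [(a_i, tau_i), ...].
    """
    t = np.asarray(lags, float)
    y = np.asarray(values, float)
    span = max(t[-1], t[1] if len(t) > 1 else 1.0)

    def amplitudes(taus):
        basis = np.exp(-t[:, None] / taus[None, :])
        a, *_ = np.linalg.lstsq(basis, y, rcond=None)
        return a, basis

    best = None
    for k in range(1, max_terms + 1):
        tau0 = np.geomspace(span / (10 ** k), span, k)

        def resid(log_tau):
            a, basis = amplitudes(np.exp(log_tau))
            return basis @ a - y

        try:
            sol = least_squares(resid, np.log(tau0), method="lm",
                                max_nfev=200 * k)
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        aic = len(y) * np.log(max(rss / len(y), 1e-300)) + 2 * (2 * k)
        if best is None or aic < best[0] - 2.0:
            taus = np.exp(sol.x)
            a, _ = amplitudes(taus)
            best = (aic, list(zip(a.tolist(), taus.tolist())))
    if best is None:
        raise AnalysisError("multi-exponential fit failed")
    return best[1]


def _cos_transform_linear(lags: np.ndarray, values: np.ndarray,
                          omega: np.ndarray) -> np.ndarray:
    """Exact cosine transform of the piecewise-linear interpolant.

    integral_0^T p(t) cos(wt) dt with p linear on each lag segment; reduces
    to the trapezoid rule as w -> 0 but keeps full accuracy at w*dt ~ 1.
    """
    t = lags
    p = values
    out = np.empty(len(omega))
    slopes = np.diff(p) / np.diff(t)
    small = np.abs(omega) * t[-1] < 1e-6
    for idx, w in enumerate(omega):
        if small[idx]:
            out[idx] = np.trapezoid(p, t)
            continue
        ct = np.cos(w * t)
        out[idx] = (p[-1] * np.sin(w * t[-1]) - p[0] * np.sin(w * t[0])) / w \
            + np.sum(slopes * (ct[1:] - ct[:-1])) / w ** 2
    return out


def spectral_density(cf: CorrelationFunction, omega: np.ndarray,
                     tail_mode: str = "exp_fit",
                     max_exp_terms: int = 3) -> np.ndarray:
    """Spectral density J(w) = 2 integral_0^inf P2(t) cos(wt) dt, in ps.

    The sampled window is integrated exactly (piecewise-linear
    interpolant); beyond the window the ACF is extended analytically by a
    multi-exponential fit (tail_mode="exp_fit", default) or set to zero
    (tail_mode="truncate", which warns when the ACF has not decayed).
    Frequencies are in rad/ps.
    """
    omega = np.atleast_1d(np.asarray(omega, float))
    t_end = cf.lags[-1]
    window = _cos_transform_linear(cf.lags, cf.values, omega)

    if tail_mode == "truncate":
        if abs(cf.values[-1]) > 0.05:
            warnings.warn("ACF not decayed at window end; J(w) is biased at "
                          "low frequency under truncate mode", stacklevel=2)
        tail = np.zeros_like(omega)
    elif tail_mode == "exp_fit":
        terms = fit_multi_exponential(cf.lags, cf.values, max_exp_terms)
        tail = np.zeros_like(omega)
        for a, tau in terms:
            s = 1.0 / tau
            tail += a * np.exp(-t_end * s) * (
                s * np.cos(omega * t_end) - omega * np.sin(omega * t_end)
            ) / (s ** 2 + omega ** 2)
    else:
        raise AnalysisError(f"unknown tail_mode {tail_mode!r}")
    return 2.0 * (window + tail)


def reduced_rate(cf: CorrelationFunction, omega: np.ndarray,
                 **j_kwargs) -> np.ndarray:
    """Reduced relaxation rate w [J(w) + 4 J(2w)] (dimensionless).

    This susceptibility-representation combination peaks near w ~ 1/tau
    and vanishes in both the extreme-narrowing (w -> 0) and rigid
    (w -> inf) limits for exponential ACFs.
    """
    omega = np.atleast_1d(np.asarray(omega, float))
    j = spectral_density(cf, np.concatenate([omega, 2 * omega]), **j_kwargs)
    n = len(omega)
    return omega * (j[:n] + 4.0 * j[n:])


def t1_susceptibility(reduced: np.ndarray | float, a0: float = A0_THEORY,
                      omega_h: float = OMEGA_H) -> np.ndarray | float:
    """Physical spin-lattice rate 1/T1H = (A0/wH) * reduced rate, in s^-1.

    A0 is the dipolar prefactor (0.56e10 s^-2 theoretical for CH2 protons;
    may be overridden per group class), wH the spectrometer angular
    frequency in rad/s.
    """
    if a0 <= 0 or omega_h <= 0:
        raise AnalysisError("A0 and omega_H must be > 0")
    return a0 / omega_h * reduced


def lorentzian_j(omega: np.ndarray, tau: float) -> np.ndarray:
    """Closed-form J(w) = 2 tau / (1 + w^2 tau^2) for P2 = exp(-t/tau)."""
    omega = np.asarray(omega, float)
    return 2.0 * tau / (1.0 + omega ** 2 * tau ** 2)


# ---------------------------------------------------------------------------
# per-topological-distance mobility
# ---------------------------------------------------------------------------

def hh_vector_series(traj, system, pairs: list[tuple[int, int]],
                     label: str = "") -> VectorSeries:
    """Normalised H-H difference vectors for a list of (H, H) atom pairs."""
    i1 = [p[0] for p in pairs]
    i2 = [p[1] for p in pairs]
    v = traj.coords[:, i2, :] - traj.coords[:, i1, :]
    return VectorSeries(traj.times, v, label=label)


def group_mobility_by_topology(traj, system, max_lag: int | None = None,
                               max_lag_frac: float = 0.1) -> dict:
    """P2 ACF and 1/e time per topological-distance class of side CH2 groups.

    H-H vectors of CH2 groups sitting the same number of bonds from the end
    of their side segment are pooled into one class; returns
    {n_bonds: {"cf": CorrelationFunction, "tau": CharacteristicTime,
    "n_pairs": int}}.
    """
    from .system import hh_pairs_by_distance

    out = {}
    for dist, pairs in sorted(hh_pairs_by_distance(system).items()):
        if not pairs:
            continue
        vs = hh_vector_series(traj, system, pairs, label=f"{dist}-bond")
        cf = acf_p2(vs, max_lag=max_lag, max_lag_frac=max_lag_frac)
        out[dist] = {"cf": cf, "tau": characteristic_time(cf),
                     "n_pairs": len(pairs)}
    return out
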