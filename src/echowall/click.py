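"""Tongue-click surrogate and the envelope-threshold duration estimator.

The original palatal click recording is not distributed; the surrogate
here is a damped sinusoid with a fast raised-cosine attack and a
two-stage exponential decay whose time constants are solved by bisection
so that the duration estimator returns the documented click metrology:
3.7 ms above -26 dBFS (95 % of the energy) and an 8.5 ms tail above
-32 dBFS, with the spectral peak at 4.1 kHz — the range typical of
palatal clicks (3–8 kHz, 3–15 ms).

The duration estimator follows the click-metrology procedure used for
the study stimuli: the signal envelope is the magnitude of the analytic
signal; the onset is the first crossing of its 0.4 ms moving average
above the threshold; the offset is the instant a decaying exponential,
least-squares fitted to the post-peak envelope, crosses the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize, signal
from scipy.io import wavfile


@dataclass
class ClickSignal:
    """Unit-peak click waveform with its measured metrology."""

    samples: np.ndarray
    rate: float
    peak_frequency: float
    duration_26db: float
    tail_32db: float

    def resampled(self, rate: float) -> "ClickSignal":
        from fractions import Fraction

        if rate == self.rate:
            return self
        frac = Fraction(rate / self.rate).limit_denominator(1000)
        out = signal.resample_poly(self.samples, frac.numerator, frac.denominator)
        out = out / np.max(np.abs(out))
        return ClickSignal(out, rate, self.peak_frequency, self.duration_26db, self.tail_32db)

    def save(self, path: str | Path) -> None:
        wavfile.write(Path(path), int(round(self.rate)), self.samples.astype(np.float32))


def _envelope(x: np.ndarray) -> np.ndarray:
    return np.abs(signal.hilbert(x))


def _moving_average(env: np.ndarray, rate: float, window: float = 0.4e-3) -> np.ndarray:
    n = max(1, int(round(window * rate)))
    kernel = np.ones(n) / n
    return np.convolve(env, kernel, mode="same")


def estimate_duration(x: np.ndarray, rate: float, threshold_db: float = -26.0) -> float:
    """Envelope span above ``threshold_db`` (dB re the envelope peak), s.

    Onset: first crossing of the 0.4 ms moving-averaged analytic-signal
    envelope above the threshold.  Offset: crossing of a decaying
    exponential fitted (nonlinear least squares) to the post-peak
    envelope down to the threshold.  Invariant to amplitude scaling and
    polarity.
    """
    if threshold_db >= 0:
        raise ValueError("threshold_db must be negative (dB re peak)")
    x = np.asarray(x, dtype=float)
    if not np.any(x):
        raise ValueError("signal is silent")
    env = _envelope(x)
    peak = env.max()
    thr = peak * 10 ** (threshold_db / 20.0)

    smoothed = _moving_average(env, rate)
    above = np.nonzero(smoothed >= thr)[0]
    if len(above) == 0:
        raise ValueError("envelope never exceeds the threshold")
    onset = above[0] / rate

    i_peak = int(np.argmax(env))
    below = np.nonzero(env[i_peak:] < thr)[0]
    i_end = i_peak + (below[0] if len(below) else len(env) - i_peak)
    seg = env[i_peak:i_end]
    if len(seg) < 4:
        raise ValueError("decay segment too short for an exponential fit")
    t = np.arange(len(seg)) / rate
    # log-domain linear fit seeds the nonlinear fit
    slope, intercept = np.polyfit(t, np.log(np.maximum(seg, 1e-12 * peak)), 1)
    tau0 = -1.0 / slope if slope < 0 else t[-1]
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau),
            t,
            seg,
            p0=(np.exp(intercept), max(tau0, 1.0 / rate)),
            sigma=np.maximum(seg, 1e-6 * peak),  # relative-error weighting
            maxfev=10_000,
        )
    except RuntimeError as err:
        raise ValueError(f"exponential fit failed to converge: {err}") from err
    a_fit, tau_fit = popt
    if a_fit <= thr or tau_fit <= 0:
        raise ValueError("exponential fit does not cross the threshold")
    offset = i_peak / rate + tau_fit * np.log(a_fit / thr)
    return float(offset - onset)


def _build_waveform(
    rate: float,
    f0: float,
    tau1: float,
    tau2: float,
    break_db: float,
    attack: float,
    total: float,
) -> np.ndarray:
    """Damped sinusoid: raised-cosine attack, then exp(tau1) decay down to
    ``break_db`` re peak, continuing with the slower exp(tau2) tail."""
    t = np.arange(int(round(total * rate))) / rate
    env = np.zeros_like(t)
    rising = t < attack
    env[rising] = 0.5 * (1.0 - np.cos(np.pi * t[rising] / attack))
    td = t[~rising] - attack
    level_break = 10 ** (break_db / 20.0)
    t_break = -tau1 * np.log(level_break)
    first = td <= t_break
    decay = np.empty_like(td)
    decay[first] = np.exp(-td[first] / tau1)
    decay[~first] = level_break * np.exp(-(td[~first] - t_break) / tau2)
    env[~rising] = decay
    x = env * np.sin(2.0 * np.pi * f0 * t)
    return x / np.max(np.abs(x))


def generate_click(
    peak_frequency: float = 4100.0,
    duration_26db: float = 3.7e-3,
    tail_32db: float = 8.5e-3,
    rate: float = 44_100.0,
    output_rate: float = 48_000.0,
    attack: float = 0.8e-3,
    total: float = 40e-3,
) -> ClickSignal:
    """Synthesize the surrogate click, calibrated to the target metrology.

    The fast decay constant is solved by bisection so the estimator
    returns ``duration_26db`` at -26 dBFS, then the tail constant so it
    returns ``tail_32db`` at -32 dBFS.  The waveform is generated at the
    44.1 kHz native rate and resampled to ``output_rate`` (48 kHz).
    """
    if tail_32db <= duration_26db:
        raise ValueError("tail_32db must exceed duration_26db (a -32 dB span cannot be shorter)")
    if peak_frequency <= 0 or duration_26db <= 0:
        raise ValueError("peak_frequency and duration_26db must be positive")

    break_db = -26.0

    def span26(tau1: float) -> float:
        x = _build_waveform(rate, peak_frequency, tau1, tau1 * 4.0, break_db, attack, total)
        return estimate_duration(x, rate, -26.0)

    tau1 = _bisect_monotone(span26, duration_26db, lo=duration_26db / 20.0, hi=duration_26db)

    def span32(tau2: float) -> float:
        x = _build_waveform(rate, peak_frequency, tau1, tau2, break_db, attack, total)
        return estimate_duration(x, rate, -32.0)

    tau2 = _bisect_monotone(span32, tail_32db, lo=tail_32db / 50.0, hi=tail_32db * 4.0)

    x = _build_waveform(rate, peak_frequency, tau1, tau2, break_db, attack, total)
    native = ClickSignal(
        samples=x,
        rate=rate,
        peak_frequency=peak_frequency,
        duration_26db=estimate_duration(x, rate, -26.0),
        tail_32db=estimate_duration(x, rate, -32.0),
    )
    return native.resampled(output_rate)


def _bisect_monotone(fn, target: float, lo: float, hi: float, tol: float = 1e-6, max_iter: int = 60) -> float:
    """Bisection for an increasing scalar map; expands the bracket if needed."""
    f_lo, f_hi = fn(lo), fn(hi)
    grow = 0
    while f_lo > target and grow < 20:
        lo /= 2.0
        f_lo = fn(lo)
        grow += 1
    while f_hi < target and grow < 40:
        hi *= 2.0
        f_hi = fn(hi)
        grow += 1
    if not (f_lo <= target <= f_hi):
        raise ValueError(f"infeasible envelope target {target!r} (bracket [{f_lo}, {f_hi}])")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if fn(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, abs(target)):
            break
    return 0.5 * (lo + hi)


def spectral_peak(x: np.ndarray, rate: float) -> float:
    """Frequency (Hz) of the FFT magnitude maximum."""
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / rate)
    return float(freqs[np.argmax(mag)])
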