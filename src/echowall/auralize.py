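"""OBRIR assembly, stimulus configurations, loudness equalization, calibration.

The direct component of a room impulse response is what the echolocator
hears of their own click (mouth-to-ear path, the OBTF); the reflected
component arrives from the wall in front (0 degree HRTF).  Convolving
each part with its head filter and summing gives the oral-binaural room
impulse response (OBRIR); convolving with the click and applying a
session-level calibration gain yields the presented stimulus.

Three stimulus configurations are supported:

``normal``
    the OBRIR as assembled;
``rdld_plus6``
    the reflected part raised by exactly 6 dB (reflected-to-direct
    level difference enhancement), direct part untouched;
``reflections_only``
    the direct part removed; the set of echo-only stimuli is then
    equalized to a common loudness by bisection and level-matched to
    the normal-case sound pressure level.

Loudness for the equalization is pluggable.  The default metric is the
A-weighted sound exposure raised to a compressive Stevens exponent
(sone-like growth); any strictly gain-monotone callable works.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .click import ClickSignal
from .fdtd import RIRBundle

REFERENCE_PRESSURE = 20e-6  # Pa

# ---------------------------------------------------------------------------
# A-weighting


def a_weighting_coefficients(rate: float) -> tuple[np.ndarray, np.ndarray]:
    """IIR A-weighting filter (IEC 61672 analog poles, bilinear transform)."""
    f1, f2, f3, f4 = 20.598997, 107.65265, 737.86223, 12194.217
    a1000 = 1.9997  # gain normalization at 1 kHz
    nums = [(2 * np.pi * f4) ** 2 * 10 ** (a1000 / 20), 0, 0, 0, 0]
    dens = np.polymul(
        [1, 4 * np.pi * f4, (2 * np.pi * f4) ** 2],
        [1, 4 * np.pi * f1, (2 * np.pi * f1) ** 2],
    )
    dens = np.polymul(np.polymul(dens, [1, 2 * np.pi * f3]), [1, 2 * np.pi * f2])
    b, a = signal.bilinear(nums, dens, rate)
    return b, a


def a_weighting_magnitude(freqs: np.ndarray) -> np.ndarray:
    """Exact analog A-curve magnitude (unity at 1 kHz)."""
    f1, f2, f3, f4 = 20.598997, 107.65265, 737.86223, 12194.217
    f = np.asarray(freqs, dtype=float)

    def ra(ff):
        ff = np.asarray(ff, dtype=float)
        return (f4**2 * ff**4) / (
            (ff**2 + f1**2) * np.sqrt((ff**2 + f2**2) * (ff**2 + f3**2)) * (ff**2 + f4**2)
        )

    return ra(f) / ra(1000.0)


def a_weight(x: np.ndarray, rate: float) -> np.ndarray:
    """A-weight a finite waveform (zero-phase, exact analog magnitude).

    Offline application in the frequency domain avoids the bilinear
    warping error of IIR A-filters near Nyquist at 48 kHz.
    """
    x = np.asarray(x, dtype=float)
    spec = np.fft.rfft(x)
    spec *= a_weighting_magnitude(np.fft.rfftfreq(len(x), 1.0 / rate))
    return np.fft.irfft(spec, n=len(x))


# ---------------------------------------------------------------------------
# FS <-> SPL convention and levels


@dataclass(frozen=True)
class Calibration:
    """Digital full scale to sound pressure mapping plus the session target.

    ``full_scale_spl``: SPL (dB re 20 uPa) of a full-scale digital sine,
    94 dB by default.  ``target_sel``: A-weighted sound exposure level of
    the direct-only reference stimulus, 51 dB(A).
    """

    full_scale_spl: float = 94.0
    target_sel: float = 51.0

    @property
    def pascal_per_unit(self) -> float:
        # full-scale sine has rms 1/sqrt(2) digital units
        rms_pa = REFERENCE_PRESSURE * 10 ** (self.full_scale_spl / 20.0)
        return rms_pa * np.sqrt(2.0)


def sound_exposure_level(x: np.ndarray, rate: float, calibration: Calibration, weighted: bool = True) -> float:
    """(A-weighted) sound exposure level, dB re (20 uPa)^2 * 1 s."""
    pa = np.asarray(x, dtype=float) * calibration.pascal_per_unit
    if weighted:
        pa = a_weight(pa, rate)
    energy = np.sum(pa**2) / rate
    return float(10.0 * np.log10(energy / REFERENCE_PRESSURE**2))


def peak_spl(x: np.ndarray, rate: float, calibration: Calibration, weighted: bool = True) -> float:
    pa = np.asarray(x, dtype=float) * calibration.pascal_per_unit
    if weighted:
        pa = a_weight(pa, rate)
    return float(20.0 * np.log10(np.max(np.abs(pa)) / REFERENCE_PRESSURE))


# ---------------------------------------------------------------------------
# Loudness metrics


class LoudnessMetric:
    """Waveform -> scalar loudness; strictly increasing in uniform gain."""

    name = "abstract"

    def __call__(self, x: np.ndarray, rate: float) -> float:  # pragma: no cover
        raise NotImplementedError


class AWeightedExposure(LoudnessMetric):
    """A-weighted energy of the waveform (linear units)."""

    name = "a_weighted_exposure"

    def __call__(self, x: np.ndarray, rate: float) -> float:
        xa = a_weight(x, rate)
        return float(np.sum(xa**2) / rate)


class StevensLoudness(LoudnessMetric):
    """Sone-like compressive loudness: A-weighted exposure ** exponent.

    Stevens' power law for loudness gives roughly a 0.3 exponent on
    intensity; this is a stationary-loudness proxy for the impulsive
    loudness model used to equalize the study's echo-only stimuli, which
    is not publicly reproducible.
    """

    name = "stevens"

    def __init__(self, exponent: float = 0.3):
        self.exponent = exponent

    def __call__(self, x: np.ndarray, rate: float) -> float:
        return float(AWeightedExposure()(x, rate) ** self.exponent)


METRICS: dict[str, Callable[[], LoudnessMetric]] = {
    "a_weighted_exposure": AWeightedExposure,
    "stevens": StevensLoudness,
}


# ---------------------------------------------------------------------------
# Head filters and OBRIR


@dataclass
class HeadFilters:
    """Mouth-to-ear (OBTF) and frontal HRTF impulse responses at 48 kHz."""

    obtf: np.ndarray
    hrtf_left: np.ndarray
    hrtf_right: np.ndarray
    rate: float = 48_000.0

    def __post_init__(self) -> None:
        for name in ("obtf", "hrtf_left", "hrtf_right"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1 or not np.isfinite(arr).all():
                raise ValueError(f"{name} must be a finite 1D impulse response")
            setattr(self, name, arr)

    @classmethod
    def identity(cls, rate: float = 48_000.0) -> "HeadFilters":
        imp = np.array([1.0])
        return cls(obtf=imp.copy(), hrtf_left=imp.copy(), hrtf_right=imp.copy(), rate=rate)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        wavfile.write(directory / "obtf.wav", int(self.rate), self.obtf.astype(np.float32))
        hrtf = np.stack([self.hrtf_left, self.hrtf_right], axis=1).astype(np.float32)
        wavfile.write(directory / "hrtf.wav", int(self.rate), hrtf)

    @classmethod
    def load(cls, directory: str | Path) -> "HeadFilters":
        directory = Path(directory)
        rate_o, obtf = wavfile.read(directory / "obtf.wav")
        rate_h, hrtf = wavfile.read(directory / "hrtf.wav")
        if rate_o != rate_h:
            raise ValueError("OBTF and HRTF rates differ")
        return cls(
            obtf=obtf.astype(float),
            hrtf_left=hrtf[:, 0].astype(float),
            hrtf_right=hrtf[:, 1].astype(float),
            rate=float(rate_o),
        )


CONFIGURATIONS = ("normal", "rdld_plus6", "reflections_only")


@dataclass
class OBRIR:
    """Oral-binaural room impulse response with separable components.

    ``direct`` and ``reflected`` are (2, N) arrays (left/right); the
    audible response is their sum.  Keeping the parts separate is what
    makes the RDLD manipulations exact.
    """

    direct: np.ndarray
    reflected: np.ndarray
    rate: float
    configuration: str = "normal"
    texture: str = ""
    distance: float = float("nan")

    def __post_init__(self) -> None:
        self.direct = np.atleast_2d(np.asarray(self.direct, dtype=float))
        self.reflected = np.atleast_2d(np.asarray(self.reflected, dtype=float))
        if self.direct.shape != self.reflected.shape or self.direct.shape[0] != 2:
            raise ValueError("direct and reflected must both be (2, N)")
        if self.configuration not in CONFIGURATIONS:
            raise ValueError(f"unknown configuration {self.configuration!r}")

    @property
    def left(self) -> np.ndarray:
        return self.direct[0] + self.reflected[0]

    @property
    def right(self) -> np.ndarray:
        return self.direct[1] + self.reflected[1]

    @property
    def is_degenerate(self) -> bool:
        """True when the audible response is silent."""
        return not (np.any(self.direct) or np.any(self.reflected))


def _pad_to(x: np.ndarray, n: int) -> np.ndarray:
    return np.pad(x, (0, n - len(x)))


def assemble_obrir(bundle: RIRBundle, filters: HeadFilters, rate: float = 48_000.0) -> OBRIR:
    """Convolve RIR components with the head filters into an OBRIR.

    The bundle is resampled to the filter rate (48 kHz); the direct part
    goes through the OBTF, the reflected part through the left/right
    HRTFs.  Components share the t = 0 origin, so their sum is the
    audible binaural response.
    """
    if filters.rate != rate:
        raise ValueError(f"filters are at {filters.rate} Hz, expected {rate}")
    bundle = bundle.resampled(rate)
    d = np.convolve(bundle.direct, filters.obtf)
    rl = np.convolve(bundle.reflected, filters.hrtf_left)
    rr = np.convolve(bundle.reflected, filters.hrtf_right)
    n = max(len(d), len(rl), len(rr))
    direct = np.stack([_pad_to(d, n), _pad_to(d, n)])
    reflected = np.stack([_pad_to(rl, n), _pad_to(rr, n)])
    return OBRIR(
        direct=direct,
        reflected=reflected,
        rate=rate,
        configuration="normal",
        texture=bundle.texture,
        distance=bundle.distance,
    )


def apply_configuration(obrir: OBRIR, mode: str) -> OBRIR:
    """Apply one of the three stimulus configurations.

    ``rdld_plus6`` scales the reflected part by 10**(6/20); the
    reflections-only loudness equalization across walls is a set-level
    operation, see :func:`equalize_set`.
    """
    if mode == "normal":
        return replace(obrir, configuration="normal")
    if mode == "rdld_plus6":
        return replace(obrir, reflected=obrir.reflected * 10 ** (6.0 / 20.0), configuration="rdld_plus6")
    if mode == "reflections_only":
        return replace(obrir, direct=np.zeros_like(obrir.direct), configuration="reflections_only")
    raise ValueError(f"unknown configuration mode {mode!r}")


def rdld_db(obrir: OBRIR) -> float:
    """Reflected-to-direct level difference (energy, dB) of an OBRIR."""
    e_ref = np.sum(obrir.reflected**2)
    e_dir = np.sum(obrir.direct**2)
    if e_dir == 0 or e_ref == 0:
        raise ValueError("RDLD undefined for a silent component")
    return float(10.0 * np.log10(e_ref / e_dir))


def equalize_set(
    waveforms: Sequence[np.ndarray],
    rate: float,
    metric: LoudnessMetric | None = None,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> np.ndarray:
    """Per-waveform gains equalizing the set to its maximal loudness.

    Each gain is solved by bisection (dichotomy) so that
    ``metric(g * x)`` matches the loudest member within ``tol``
    (relative).  All gains are >= 1.
    """
    if len(waveforms) < 2:
        raise ValueError("need at least two waveforms to equalize")
    metric = metric or AWeightedExposure()
    values = []
    for i, x in enumerate(waveforms):
        if not np.any(x):
            raise ValueError(f"waveform {i} is silent; loudness equalization undefined")
        values.append(metric(np.asarray(x, float), rate))
    target = max(values)
    gains = np.ones(len(waveforms))
    for i, (x, v) in enumerate(zip(waveforms, values)):
        if v >= target * (1 - tol):
            continue
        lo, hi = 1.0, 2.0
        it = 0
        while metric(hi * x, rate) < target:
            hi *= 2.0
            it += 1
            if it > 60:
                raise RuntimeError("equalization bracket expansion failed")
        for it in range(max_iter):
            mid = 0.5 * (lo + hi)
            if metric(mid * x, rate) < target:
                lo = mid
            else:
                hi = mid
            if (hi - lo) / hi < 1e-12:
                break
        g = 0.5 * (lo + hi)
        if abs(metric(g * x, rate) - target) > tol * target:
            raise RuntimeError(f"equalization did not converge for waveform {i}")
        gains[i] = g
    return gains


# ---------------------------------------------------------------------------
# Stimulus


@dataclass
class Stimulus:
    """Binaural presented waveform with its calibrated levels."""

    left: np.ndarray
    right: np.ndarray
    rate: float
    sel_dba: float
    peak_spl_dba: float
    texture: str = ""
    distance: float = float("nan")
    configuration: str = "normal"

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError("channel length mismatch")

    @property
    def stereo(self) -> np.ndarray:
        return np.stack([self.left, self.right])

    def save(self, path: str | Path) -> None:
        data = np.stack([self.left, self.right], axis=1)
        peak = np.max(np.abs(data))
        if peak > 1.0:
            raise ValueError("stimulus clips; lower the calibration gain")
        wavfile.write(Path(path), int(self.rate), (data * 32767).astype(np.int16))


def session_gain(reference: np.ndarray, rate: float, calibration: Calibration) -> float:
    """Gain mapping the direct-only reference to the target SEL of 51 dB(A).

    A single session-global gain is shared by every stimulus so that
    relative levels between walls and configurations are preserved.
    """
    sel = sound_exposure_level(reference, rate, calibration)
    return float(10 ** ((calibration.target_sel - sel) / 20.0))


def auralize_stimulus(
    obrir: OBRIR,
    click: ClickSignal,
    calibration: Calibration,
    gain: float,
    extra_gain: float = 1.0,
) -> Stimulus:
    """Convolve the OBRIR with the click and apply the calibrated gain.

    ``gain`` is the session-global calibration gain from
    :func:`session_gain`; ``extra_gain`` carries the per-wall
    reflections-only equalization/level-match factor (1 otherwise).
    Raises on clipping.
    """
    if click.rate != obrir.rate:
        raise ValueError(f"rate mismatch: click {click.rate} vs OBRIR {obrir.rate}")
    g = gain * extra_gain
    left = np.convolve(obrir.left, click.samples) * g
    right = np.convolve(obrir.right, click.samples) * g
    peak = max(np.max(np.abs(left)), np.max(np.abs(right)), 0.0)
    if peak > 1.0:
        raise ValueError(f"stimulus clips (peak {peak:.3f} > 1); lower the FS<->SPL convention gain")
    both = np.concatenate([left, right])
    if np.any(both):
        sel = sound_exposure_level(0.5 * (left + right), obrir.rate, calibration)
        pk = peak_spl(0.5 * (left + right), obrir.rate, calibration)
    else:
        sel = pk = float("-inf")
    return Stimulus(
        left=left,
        right=right,
        rate=obrir.rate,
        sel_dba=sel,
        peak_spl_dba=pk,
        texture=obrir.texture,
        distance=obrir.distance,
        configuration=obrir.configuration,
    )


def level_match_gain(x: np.ndarray, reference: np.ndarray) -> float:
    """Gain matching the rms level of ``x`` to ``reference`` (the
    reflections-only stimuli are matched to the normal-case SPL)."""
    rms_x = np.sqrt(np.mean(np.square(x)))
    rms_ref = np.sqrt(np.mean(np.square(reference)))
    if rms_x == 0:
        raise ValueError("cannot level-match a silent signal")
    return float(rms_ref / rms_x)
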