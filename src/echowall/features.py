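"""Single-number echo-difference quantities (SNQ1-3) between wall pairs.

For each pair of stimuli the three quantities are:

* **SNQ1** — rms of the difference of the time signals;
* **SNQ2** — rms over frequency bins of the difference of the
  dB-magnitude spectra (each normalized to 0 dB at 1.5 kHz, band
  limited to 0.5-12 kHz);
* **SNQ3** — absolute difference of the rms values of the numerically
  differentiated dB spectra (difference in spectral non-smoothness),
  same normalization and band.

All three are symmetric, non-negative, and zero for identical inputs.
Binaural inputs are reduced by computing per channel and averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

BAND = (500.0, 12_000.0)
NORM_FREQ = 1500.0


def _as_channels(x) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(getattr(x, "stereo", x), dtype=float))
    return arr


def _common(x, y) -> tuple[np.ndarray, np.ndarray]:
    cx, cy = _as_channels(x), _as_channels(y)
    if cx.shape[0] != cy.shape[0]:
        raise ValueError("channel count mismatch")
    n = max(cx.shape[1], cy.shape[1])
    cx = np.pad(cx, ((0, 0), (0, n - cx.shape[1])))
    cy = np.pad(cy, ((0, 0), (0, n - cy.shape[1])))
    return cx, cy


def snq1(x, y, rate: float | None = None) -> float:
    """rms of the time-signal difference, channels averaged."""
    cx, cy = _common(x, y)
    per_channel = np.sqrt(np.mean((cx - cy) ** 2, axis=1))
    return float(np.mean(per_channel))


def _db_spectrum(chan: np.ndarray, rate: float, n_fft: int) -> tuple[np.ndarray, np.ndarray]:
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    mag = np.abs(np.fft.rfft(chan, n=n_fft))
    db = 20.0 * np.log10(np.maximum(mag, 1e-300))
    k = int(np.argmin(np.abs(freqs - NORM_FREQ)))
    db = db - db[k]
    sel = (freqs >= BAND[0]) & (freqs <= BAND[1])
    if not sel.any():
        raise ValueError("frequency band empty at this rate/length")
    return freqs[sel], db[sel]


def _fft_length(n: int) -> int:
    return 1 << max(6, int(np.ceil(np.log2(n))))


def snq2(x, y, rate: float) -> float:
    """rms of the dB-spectrum difference over the 0.5-12 kHz band."""
    cx, cy = _common(x, y)
    n_fft = _fft_length(cx.shape[1])
    vals = []
    for a, b in zip(cx, cy):
        _, da = _db_spectrum(a, rate, n_fft)
        _, db_ = _db_spectrum(b, rate, n_fft)
        vals.append(np.sqrt(np.mean((da - db_) ** 2)))
    return float(np.mean(vals))


def snq3(x, y, rate: float) -> float:
    """|rms(dS_x/df) - rms(dS_y/df)| on the dB spectra (non-smoothness)."""
    cx, cy = _common(x, y)
    n_fft = _fft_length(cx.shape[1])
    vals = []
    for a, b in zip(cx, cy):
        _, da = _db_spectrum(a, rate, n_fft)
        _, db_ = _db_spectrum(b, rate, n_fft)
        ra = np.sqrt(np.mean(np.diff(da) ** 2))
        rb = np.sqrt(np.mean(np.diff(db_) ** 2))
        vals.append(abs(ra - rb))
    return float(np.mean(vals))


@dataclass(frozen=True)
class SNQVector:
    pair: tuple[str, str]
    distance: float
    configuration: str
    snq1: float
    snq2: float
    snq3: float


def snq_pair(x, y, rate: float) -> tuple[float, float, float]:
    return snq1(x, y), snq2(x, y, rate), snq3(x, y, rate)


def snq_table(
    stimuli: Mapping[str, object],
    rate: float,
    distance: float = float("nan"),
    configuration: str = "normal",
) -> pd.DataFrame:
    """All-pairs SNQ table for one (distance, configuration) stimulus set.

    ``stimuli`` maps texture name -> waveform (1D/2D array or Stimulus).
    Six textures give the study's C(6,2) = 15 pairs.  Signals are
    zero-padded to a common power-of-two FFT length so SNQ3's bin
    spacing is comparable across pairs.
    """
    if not isinstance(stimuli, Mapping):
        items = list(stimuli)  # sequence of (name, waveform) pairs
        names = [n for n, _ in items]
        if len(names) != len(set(names)):
            raise ValueError("duplicate texture entries")
        stimuli = dict(items)
    names = list(stimuli)
    if len(names) < 2:
        raise ValueError("need at least two textures")
    rows = []
    for a, b in combinations(names, 2):
        s1, s2, s3 = snq_pair(stimuli[a], stimuli[b], rate)
        rows.append(
            {
                "pair_i": a,
                "pair_j": b,
                "distance": distance,
                "configuration": configuration,
                "snq1": s1,
                "snq2": s2,
                "snq3": s3,
            }
        )
    return pd.DataFrame(rows)


def snq_tables(
    stimulus_sets: Mapping[tuple[float, str], Mapping[str, object]],
    rate: float,
    n_textures: int | None = 6,
) -> pd.DataFrame:
    """Concatenate :func:`snq_table` over (distance, configuration) blocks.

    When ``n_textures`` is given, each block must contain exactly that
    many textures (the full study design uses 6 -> 15 pairs per block).
    """
    frames = []
    for (distance, configuration), stimuli in stimulus_sets.items():
        if n_textures is not None and len(stimuli) != n_textures:
            raise ValueError(
                f"block ({distance}, {configuration}) has {len(stimuli)} textures, expected {n_textures}"
            )
        frames.append(snq_table(stimuli, rate, distance=distance, configuration=configuration))
    if not frames:
        raise ValueError("no stimulus sets given")
    return pd.concat(frames, ignore_index=True)
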