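"""Synthetic listeners, ABX response simulation, and fixture head filters.

The listener model stands in for the study's 14 human participants.  A
trial's probability of a correct answer follows a saturating-exponential
psychometric link anchored at the 2AFC guessing limit:

    P(correct) = 0.5 + (0.5 - lapse) * (1 - exp(-sensitivity * d))

where ``d`` is a non-negative stimulus discriminability (by default the
pair's spectral-difference SNQ2 scaled by its cohort mean, since
reflection coloration is the dominant texture cue).  Sensitivity varies
between participants on a log scale; a small fraction of trials
(default 5 per mille, the observed timeout rate) go unanswered and are
scored incorrect downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .abx_stats import TRIAL_COLUMNS
from .auralize import HeadFilters


@dataclass(frozen=True)
class ListenerModel:
    """Cohort-level response model for ABX texture-discrimination trials."""

    sensitivity: float = 1.0
    lapse_rate: float = 0.02
    participant_effect_sd: float = 0.3
    timeout_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sensitivity < 0:
            raise ValueError("sensitivity must be >= 0")
        if not (0 <= self.lapse_rate < 0.5):
            raise ValueError("lapse_rate must be in [0, 0.5)")
        if not (0 <= self.timeout_rate < 1):
            raise ValueError("timeout_rate must be in [0, 1)")


def p_correct(model: ListenerModel, discriminability: float, sensitivity: float | None = None) -> float:
    """Psychometric link: chance floor 0.5, saturating toward 1 - lapse/2."""
    d = np.asarray(discriminability, dtype=float)
    if np.any(d < 0):
        raise ValueError("discriminability must be >= 0")
    s = model.sensitivity if sensitivity is None else sensitivity
    return 0.5 + (0.5 - model.lapse_rate) * (1.0 - np.exp(-s * d))


def _discriminability(snq_table: pd.DataFrame, feature: str) -> pd.Series:
    col = snq_table[feature]
    scale = col.mean()
    return col / scale if scale > 0 else col * 0.0


def simulate_experiment(
    model: ListenerModel,
    snq_table: pd.DataFrame,
    n_participants: int = 14,
    n_reps: int = 3,
    feature: str = "snq2",
) -> pd.DataFrame:
    """Simulate a complete ABX session cohort; returns a trial table.

    ``snq_table`` needs columns pair_i, pair_j, distance, configuration
    plus the chosen SNQ ``feature`` (the 15 pairs x 2 distances x 3
    configurations of the full design, or any subset for fixtures).
    Emits one row per participant x table row x repetition in the
    schema consumed by :mod:`echowall.abx_stats`.
    """
    if n_participants < 1 or n_reps < 1:
        raise ValueError("participant and repetition counts must be >= 1")
    required = {"pair_i", "pair_j", "distance", "configuration", feature}
    missing = required - set(snq_table.columns)
    if missing:
        raise ValueError(f"snq_table missing columns: {sorted(missing)}")
    rng = np.random.default_rng(model.seed)
    disc = _discriminability(snq_table, feature).to_numpy()
    sens = model.sensitivity * np.exp(rng.normal(0.0, model.participant_effect_sd, size=n_participants))

    rows = []
    for p in range(n_participants):
        for rep in range(1, n_reps + 1):
            order = rng.permutation(len(snq_table))  # random presentation order
            for idx in order:
                r = snq_table.iloc[idx]
                pc = p_correct(model, disc[idx], sensitivity=sens[p])
                correct = rng.random() < pc
                x_assignment = "A" if rng.random() < 0.5 else "B"
                response = x_assignment if correct else ("B" if x_assignment == "A" else "A")
                timeout = rng.random() < model.timeout_rate
                rows.append(
                    {
                        "participant": p + 1,
                        "configuration": r["configuration"],
                        "distance": r["distance"],
                        "pair_i": r["pair_i"],
                        "pair_j": r["pair_j"],
                        "repetition": rep,
                        "x_assignment": x_assignment,
                        "response": response,
                        "answered": not timeout,
                        "response_time": 30.0 if timeout else float(rng.uniform(2.0, 15.0)),
                    }
                )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def pairwise_df_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a scored trial table into the deposited-data DF layout."""
    agg = (
        scored.groupby(["participant", "configuration", "distance", "pair_i", "pair_j"], observed=True)["correct"]
        .mean()
        .rename("df")
        .reset_index()
    )
    return agg


def fit_sensitivity(
    model: ListenerModel, snq_table: pd.DataFrame, df_observed: pd.DataFrame, feature: str = "snq2"
) -> float:
    """Maximum-likelihood sensitivity from per-pair correct counts.

    ``df_observed`` needs columns pair_i, pair_j, distance,
    configuration, n_correct, n_trials (from ``compute_df``).  Used for
    parameter-recovery checks of the generator.
    """
    merged = df_observed.merge(snq_table, on=["pair_i", "pair_j", "distance", "configuration"])
    disc = _discriminability(merged, feature).to_numpy()
    k = merged["n_correct"].to_numpy()
    n = merged["n_trials"].to_numpy()

    def nll(log_s: float) -> float:
        p = np.clip(p_correct(model, disc, sensitivity=np.exp(log_s)), 1e-9, 1 - 1e-9)
        return float(-(k * np.log(p) + (n - k) * np.log1p(-p)).sum())

    res = optimize.minimize_scalar(nll, bounds=(-5.0, 5.0), method="bounded")
    return float(np.exp(res.x))


def make_fixture_filters(seed: int = 0, rate: float = 48_000.0) -> HeadFilters:
    """Deterministic synthetic head filters for download-free tests.

    The OBTF is a short, strong mouth-to-ear path (0.3 ms delay, unity
    gain, mild seeded ripple); the HRTF pair a weaker frontal echo path
    (no interaural delay at 0 degrees, gentle low-pass head shadow).
    The direct path is louder than the echo path, so a flat-wall OBRIR
    built from these has RDLD < 0 dB, as in the modelled scenario.
    """
    rng = np.random.default_rng(seed)
    n = 64
    obtf = np.zeros(n)
    d_obtf = int(round(0.3e-3 * rate))
    obtf[d_obtf] = 1.0
    obtf += 0.02 * rng.standard_normal(n) * signal.windows.hann(n)

    cutoff = 9_000.0
    fir = signal.firwin(33, cutoff, fs=rate)
    hrtf = np.zeros(n)
    d_hrtf = int(round(0.5e-3 * rate))
    hrtf[d_hrtf] = 1.0
    hrtf = 0.45 * np.convolve(hrtf, fir)[:n]
    return HeadFilters(obtf=obtf, hrtf_left=hrtf.copy(), hrtf_right=hrtf.copy(), rate=rate)
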