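"""ABX trial scoring, discrimination fractions, and repeated-measures ANOVA.

The listening test is a 2AFC/ABX design: on each trial the listener
hears A, B and X (X identical to A or B) and must say which, so chance
performance is 50 %.  Trials that time out (30 s limit) count as
incorrect.  Performance is summarized by the discrimination fraction
(DF): the fraction of comparisons answered correctly for any grouping
of trials.

The ANOVA is a full-factorial three-way repeated-measures model
(factors: wall texture, distance group, impulse-response configuration)
computed from a complete sums-of-squares decomposition of the balanced
subject x factor table.  Each within effect is tested against its
interaction with subjects; both partial eta-squared
(SS_effect / (SS_effect + SS_error)) and eta-squared
(SS_effect / SS_total) are reported, with Bonferroni-corrected paired
post-hoc comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

TRIAL_COLUMNS = [
    "participant",
    "configuration",
    "distance",
    "pair_i",
    "pair_j",
    "repetition",
    "x_assignment",
    "response",
    "answered",
    "response_time",
]

TIMEOUT_SECONDS = 30.0


def score_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Add a boolean ``correct`` column: answered and response == X.

    Unanswered (timed-out) trials are scored incorrect regardless of the
    recorded response.
    """
    missing = [c for c in ("x_assignment", "response", "answered") if c not in table.columns]
    if missing:
        raise ValueError(f"response table is missing columns: {missing}")
    if "repetition" in table.columns and not table["repetition"].isin([1, 2, 3]).all():
        raise ValueError("repetition must be 1, 2 or 3")
    if "response_time" in table.columns and (table["response_time"] > TIMEOUT_SECONDS + 1e-9).any():
        raise ValueError(f"response_time exceeds the {TIMEOUT_SECONDS:.0f} s limit")
    bad = ~table["x_assignment"].isin(["A", "B"]) | ~table["response"].isin(["A", "B"])
    if bad.any():
        raise ValueError(f"malformed rows (x_assignment/response not A/B): {table.index[bad].tolist()[:5]}")
    scored = table.copy()
    scored["correct"] = scored["answered"].astype(bool) & (scored["response"] == scored["x_assignment"])
    return scored


def compute_df(scored: pd.DataFrame, grouping: Sequence[str]) -> pd.DataFrame:
    """Discrimination fraction per group: n_correct / n_trials.

    Empty groups are simply absent (pandas drops them); the result is
    sorted on the grouping keys for deterministic ordering.
    """
    if "correct" not in scored.columns:
        raise ValueError("run score_trials first (no 'correct' column)")
    grouping = list(grouping)
    agg = (
        scored.groupby(grouping, observed=True)["correct"]
        .agg(n_correct="sum", n_trials="count")
        .reset_index()
    )
    agg["df"] = agg["n_correct"] / agg["n_trials"]
    return agg.sort_values(grouping, kind="stable").reset_index(drop=True)


def pooled_df(scored: pd.DataFrame) -> float:
    return float(scored["correct"].mean())


def per_texture_df(pairwise: pd.DataFrame, grouping: Sequence[str] = ()) -> pd.DataFrame:
    """Per-texture DF: mean over the pairs containing each texture.

    ``pairwise`` needs columns pair_i, pair_j, df (e.g. from
    :func:`compute_df` or the deposited DF layout); each texture's score
    aggregates the 5 pairs it appears in.
    """
    grouping = list(grouping)
    long = pd.concat(
        [
            pairwise.rename(columns={"pair_i": "texture"}).drop(columns=["pair_j"]),
            pairwise.rename(columns={"pair_j": "texture"}).drop(columns=["pair_i"]),
        ],
        ignore_index=True,
    )
    out = long.groupby(grouping + ["texture"], observed=True)["df"].mean().reset_index()
    return out.sort_values(grouping + ["texture"], kind="stable").reset_index(drop=True)


def binomial_vs_chance(df: float, n: int) -> float:
    """Exact two-sided binomial test of a DF against the 50 % guessing limit."""
    if n < 1:
        raise ValueError("need at least one trial")
    if not (0.0 <= df <= 1.0):
        raise ValueError("df must lie in [0, 1]")
    k = int(round(df * n))
    return float(stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA


@dataclass
class AnovaResult:
    """Effect table plus Bonferroni post-hoc pairwise p-values."""

    table: pd.DataFrame
    posthoc: dict[str, pd.DataFrame] = field(default_factory=dict)

    def effect(self, name: str) -> pd.Series:
        row = self.table[self.table["effect"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]

    def report(self) -> str:
        lines = []
        for _, r in self.table.iterrows():
            p = "< 0.001" if r["p"] < 0.001 else f"= {r['p']:.3f}"
            lines.append(
                f"{r['effect']}: F({r['df_num']:.0f},{r['df_den']:.0f}) = {r['F']:.2f}, "
                f"p {p}, partial eta2 = {r['partial_eta_sq']:.2f}, eta2 = {r['eta_sq']:.3f}"
            )
        return "\n".join(lines)


def _decompose(y: np.ndarray) -> dict[frozenset, np.ndarray]:
    """Full ANOVA decomposition of a balanced array (axis 0 = subject).

    Returns the effect term (broadcastable to y's shape) for every
    non-empty subset of axes, by marginal means with lower-order terms
    subtracted (inclusion-exclusion).
    """
    ndim = y.ndim
    axes = list(range(ndim))
    grand = y.mean()
    terms: dict[frozenset, np.ndarray] = {}
    subsets = []
    for r in range(1, ndim + 1):
        subsets.extend(combinations(axes, r))
    subsets.sort(key=len)
    for sub in subsets:
        others = tuple(a for a in axes if a not in sub)
        marg = y.mean(axis=others, keepdims=True) if others else y.copy()
        term = marg - grand
        for smaller, t in terms.items():
            if smaller < frozenset(sub):
                term = term - t
        terms[frozenset(sub)] = term
    return terms


def _gg_epsilon(y: np.ndarray, effect_axes: tuple[int, ...]) -> float:
    """Greenhouse-Geisser sphericity epsilon for one within effect.

    ``y`` is the balanced (subject, factor...) array; the effect's cell
    means are taken per subject (marginalized over the other factors)
    and epsilon computed from the covariance of orthonormal-contrast
    scores: tr(M)^2 / ((k-1) tr(M^2)).
    """
    others = tuple(a for a in range(1, y.ndim) if a not in effect_axes)
    cells = y.mean(axis=others) if others else y
    n = cells.shape[0]
    m = cells.reshape(n, -1)
    k = m.shape[1]
    if k < 3:
        return 1.0  # 2-level effects are trivially spherical
    # orthonormal contrasts as a Kronecker product over the effect's factors
    c = np.eye(1)
    for a in effect_axes:
        la = y.shape[a]
        h = np.linalg.qr(np.column_stack([np.ones(la), np.eye(la)[:, :-1]]))[0][:, 1:]
        c = np.kron(c, h.T)
    s = np.cov(m, rowvar=False, ddof=1)
    t = c @ s @ c.T
    eps = np.trace(t) ** 2 / ((k - 1) * np.trace(t @ t))
    return float(min(1.0, max(eps, 1.0 / (k - 1))))


def rm_anova(
    df_table: pd.DataFrame,
    dv: str = "df",
    subject: str = "participant",
    within: Sequence[str] = ("texture", "distance", "configuration"),
    correction: str | None = None,
) -> AnovaResult:
    """Full-factorial within-subject ANOVA with effect sizes.

    ``df_table`` must be balanced with exactly one ``dv`` value per
    subject x cell (aggregate first with :func:`compute_df` /
    :func:`per_texture_df`).  Univariate uncorrected F tests by
    default; ``correction="gg"`` adds Greenhouse-Geisser adjusted
    degrees of freedom and p-values per effect.
    """
    within = list(within)
    levels = {f: sorted(df_table[f].unique().tolist()) for f in within}
    subjects = sorted(df_table[subject].unique().tolist())
    shape = (len(subjects), *(len(levels[f]) for f in within))

    pivot = df_table.set_index([subject] + within)[dv]
    if pivot.index.has_duplicates:
        raise ValueError("multiple observations per subject x cell; aggregate first")
    full_index = pd.MultiIndex.from_product([subjects] + [levels[f] for f in within], names=[subject] + within)
    missing = full_index.difference(pivot.index)
    if len(missing):
        raise ValueError(f"unbalanced design; missing cells: {missing.tolist()[:5]}")
    y = pivot.reindex(full_index).to_numpy().reshape(shape)

    terms = _decompose(y)
    n_cells = y.size
    ss = {sub: float(np.sum(t**2) * (n_cells / t.size)) for sub, t in terms.items()}
    ss_total = float(np.sum((y - y.mean()) ** 2))

    rows = []
    for r in range(1, len(within) + 1):
        for combo in combinations(range(1, len(within) + 1), r):
            eff = frozenset(combo)
            err = frozenset({0} | eff)
            df_num = int(np.prod([shape[a] - 1 for a in combo]))
            df_den = int((shape[0] - 1) * np.prod([shape[a] - 1 for a in combo]))
            ms_num = ss[eff] / df_num
            ms_den = ss[err] / df_den
            f_val = ms_num / ms_den if ms_den > 0 else np.inf
            p = float(stats.f.sf(f_val, df_num, df_den)) if np.isfinite(f_val) else 0.0
            row = {
                "effect": " x ".join(within[a - 1] for a in sorted(combo)),
                "F": f_val,
                "df_num": df_num,
                "df_den": df_den,
                "p": p,
                "SS_effect": ss[eff],
                "SS_error": ss[err],
                "partial_eta_sq": ss[eff] / (ss[eff] + ss[err]) if ss[eff] + ss[err] > 0 else 0.0,
                "eta_sq": ss[eff] / ss_total if ss_total > 0 else 0.0,
            }
            if correction == "gg":
                eps = _gg_epsilon(y, combo)
                row["gg_epsilon"] = eps
                row["p_gg"] = (
                    float(stats.f.sf(f_val, eps * df_num, eps * df_den)) if np.isfinite(f_val) else 0.0
                )
            elif correction is not None:
                raise ValueError(f"unknown correction {correction!r}; use None or 'gg'")
            rows.append(row)
    table = pd.DataFrame(rows)

    posthoc = {f: pairwise_bonferroni(df_table, factor=f, dv=dv, subject=subject) for f in within}
    return AnovaResult(table=table, posthoc=posthoc)


def pairwise_bonferroni(
    df_table: pd.DataFrame, factor: str, dv: str = "df", subject: str = "participant"
) -> pd.DataFrame:
    """Bonferroni-corrected paired t-tests on subject means per level pair.

    Marginal means per subject and level are compared with paired t
    tests; raw p-values are multiplied by the number of comparisons and
    clipped at 1.  These approximate the printed post-hoc families.
    """
    means = df_table.groupby([subject, factor], observed=True)[dv].mean().unstack(factor)
    lev = list(means.columns)
    pairs = list(combinations(lev, 2))
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_rel(means[a], means[b])
        rows.append({"level_a": a, "level_b": b, "t": float(t), "p_raw": float(p), "p_bonf": min(1.0, float(p) * len(pairs))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Deposited DF table ingestion


S1_COLUMNS = ["participant", "configuration", "distance", "pair_i", "pair_j", "df"]


def read_df_table(path: str | Path) -> pd.DataFrame:
    """Read a per-participant pairwise DF table (deposited-data layout).

    Accepts CSV or XLSX with (case-insensitive) columns participant,
    configuration, distance, pair_i, pair_j, df — one row per
    participant x configuration x distance x wall pair, holding the
    discrimination fraction over that cell's repetitions.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)
    raw.columns = [str(c).strip().lower() for c in raw.columns]
    aliases = {"subject": "participant", "id": "participant", "texture_i": "pair_i", "texture_j": "pair_j", "config": "configuration", "rdld": "configuration"}
    raw = raw.rename(columns=aliases)
    missing = [c for c in S1_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"DF table at {path} is missing columns: {missing} (found {list(raw.columns)})")
    out = raw[S1_COLUMNS].copy()
    if ((out["df"] < 0) | (out["df"] > 1)).any():
        raise ValueError("df values outside [0, 1]")
    return out


def read_responses(path: str | Path) -> pd.DataFrame:
    """Read a raw-trial response table (schema in TRIAL_COLUMNS)."""
    raw = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"response table missing columns: {missing}")
    raw["answered"] = raw["answered"].astype(bool)
    return raw


def anova_from_pairwise(pairwise: pd.DataFrame) -> AnovaResult:
    """Three-way RM-ANOVA from a per-participant pairwise DF table.

    Per-texture DFs are reconstructed as means over the 5 pairs
    containing each texture, yielding the texture F(5, 65), distance
    F(1, 13) and configuration F(2, 26) tests of the full design with
    14 participants.
    """
    per_tex = per_texture_df(pairwise, grouping=["participant", "configuration", "distance"])
    return rm_anova(per_tex, dv="df", subject="participant", within=["texture", "distance", "configuration"])
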