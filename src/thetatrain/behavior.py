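"""Signal-detection analysis, screening, learning slopes, exact
nonparametric tests, effect size and sample-size planning.

The Mann-Whitney and Wilcoxon tests use exact null distributions (counting
recurrences, equivalent to full enumeration) for small untied samples and
normal approximations with tie correction otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import nct as nct_dist
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

__all__ = [
    "SDTSummary",
    "LearningFit",
    "dprime",
    "dprime_table",
    "sdt_counts",
    "hits_minus_fa",
    "screen_subject",
    "learning_slope",
    "mannwhitney_u",
    "wilcoxon_signed",
    "cohens_d",
    "required_sample_size",
    "two_sample_t_power",
    "monte_carlo_power",
    "unbiased_percent_correct",
]


@dataclass
class SDTSummary:
    hit_rate: float
    fa_rate: float
    dprime: float
    criterion: float
    n_signal: int
    n_noise: int
    corrected: bool


@dataclass
class LearningFit:
    slope: float
    intercept: float
    sessions: tuple[int, ...]
    dprimes: tuple[float, ...]


def _clamp_rate(k: int, n: int) -> tuple[float, bool]:
    """Clamp k/n into [1/(2n), 1 - 1/(2n)] ahead of the probit transform."""
    rate = k / n
    lo, hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
    clamped = min(max(rate, lo), hi)
    return clamped, clamped != rate


def dprime(n_hit: int, n_miss: int, n_fa: int, n_cr: int) -> SDTSummary:
    """Equal-variance d' and criterion from a 2x2 response table.

    A hit is a "mismatch" response on a mismatch (signal) trial, a false
    alarm a "mismatch" response on a match trial.  Rates are clamped to
    ``[1/(2N), 1 - 1/(2N)]`` per response class before the probit
    transform.
    """
    n_signal = n_hit + n_miss
    n_noise = n_fa + n_cr
    if n_signal < 1 or n_noise < 1:
        raise ValueError("both signal and noise trials are required")
    h, ch = _clamp_rate(n_hit, n_signal)
    fa, cf = _clamp_rate(n_fa, n_noise)
    zh, zf = norm.ppf(h), norm.ppf(fa)
    return SDTSummary(
        hit_rate=h, fa_rate=fa,
        dprime=float(zh - zf),
        criterion=float(-(zh + zf) / 2.0),
        n_signal=n_signal, n_noise=n_noise,
        corrected=ch or cf,
    )


def sdt_counts(table: pd.DataFrame) -> tuple[int, int, int, int]:
    """(n_hit, n_miss, n_fa, n_cr) from behavior-table rows."""
    signal = table[~table["is_match"]]
    noise = table[table["is_match"]]
    n_hit = int((signal["response"] == "mismatch").sum())
    n_fa = int((noise["response"] == "mismatch").sum())
    return n_hit, len(signal) - n_hit, n_fa, len(noise) - n_fa


def dprime_table(
    table: pd.DataFrame,
    by: tuple[str, ...] = ("subject", "group", "session", "trial_type"),
) -> pd.DataFrame:
    """Per-cell SDT summaries of a behavior table."""
    rows = []
    for key, cell in table.groupby(list(by), sort=True):
        counts = sdt_counts(cell)
        s = dprime(*counts)
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row.update({
            "n_hit": counts[0], "n_miss": counts[1],
            "n_fa": counts[2], "n_cr": counts[3],
            "hit_rate": s.hit_rate, "fa_rate": s.fa_rate,
            "dprime": s.dprime, "criterion": s.criterion,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def hits_minus_fa(table: pd.DataFrame) -> float:
    """Raw Hits - False Alarms rate (no clamping); screening metric."""
    signal = table[~table["is_match"]]
    noise = table[table["is_match"]]
    if len(signal) == 0 or len(noise) == 0:
        raise ValueError("both match and mismatch trials are required")
    h = (signal["response"] == "mismatch").mean()
    fa = (noise["response"] == "mismatch").mean()
    return float(h - fa)


def screen_subject(
    rate: float, chance_criterion: float = 0.1, ceiling: float = 0.70
) -> str:
    """Enrollment decision from the screening Hits - FA rate.

    Returns ``"exclude_ceiling"`` for rates strictly above ``ceiling``,
    ``"exclude_low"`` for rates at or below ``chance_criterion`` (the
    above-chance cutoff is a configurable convention), else ``"enroll"``.
    """
    if not -1.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [-1, 1]")
    if rate > ceiling:
        return "exclude_ceiling"
    if rate <= chance_criterion:
        return "exclude_low"
    return "enroll"


def learning_slope(
    dprimes_by_session: dict[int, float] | pd.Series,
    sessions: tuple[int, ...] = (2, 3, 4, 5, 6),
) -> LearningFit:
    """OLS slope of d' over the given training sessions."""
    if isinstance(dprimes_by_session, pd.Series):
        dprimes_by_session = dprimes_by_session.to_dict()
    use = [s for s in sessions if s in dprimes_by_session]
    if len(use) < 2:
        raise ValueError("need at least 2 sessions with defined d'")
    x = np.array(use, dtype=float)
    y = np.array([dprimes_by_session[s] for s in use], dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return LearningFit(float(slope), float(intercept), tuple(use), tuple(y))


# ---------------------------------------------------------------------------
# exact nonparametric tests
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _mw_counts(m: int, n: int) -> tuple[int, ...]:
    """Null counts of the Mann-Whitney U statistic for samples (m, n).

    ``counts[u]`` is the number of the C(m+n, m) rank arrangements giving
    U = u; recurrence N(u; m, n) = N(u - n; m - 1, n) + N(u; m, n - 1).
    """
    if m == 0 or n == 0:
        return (1,)
    left = _mw_counts(m - 1, n)
    right = _mw_counts(m, n - 1)
    size = m * n + 1
    out = [0] * size
    for u in range(size):
        if u - n >= 0 and u - n < len(left):
            out[u] += left[u - n]
        if u < len(right):
            out[u] += right[u]
    return tuple(out)


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def mannwhitney_u(
    x, y, tail: str = "two", method: str = "auto"
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U, p) with U = min(U_x, U_y).

    With ``method="auto"``, p is exact (counting over all rank
    arrangements) when ``len(x) + len(y) <= 20`` and there are no ties;
    otherwise the normal approximation with tie and continuity corrections.
    ``method="exact"``/``"normal"`` force a branch (exact rejects ties).
    ``tail``: "two" | "greater" (x tends larger) | "less".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if tail not in ("two", "greater", "less"):
        raise ValueError(f"unknown tail {tail!r}")
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    m, n = x.size, y.size
    ranks = rankdata(np.concatenate([x, y]))
    r_x = ranks[:m].sum()
    u_x = r_x - m * (m + 1) / 2.0  # pairs where x beats y (+0.5 per tie)
    u_y = m * n - u_x
    u_min = min(u_x, u_y)

    ties = _has_ties(np.concatenate([x, y]))
    if method == "exact" and ties:
        raise ValueError("exact method requires untied data")
    use_exact = (
        method == "exact"
        or (method == "auto" and m + n <= 20 and not ties)
    )
    if use_exact:
        counts = np.array(_mw_counts(m, n), dtype=float)
        total = counts.sum()
        u_int = int(round(u_x))
        p_ge = counts[u_int:].sum() / total
        p_le = counts[: u_int + 1].sum() / total
    else:
        mu = m * n / 2.0
        tie_vals, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = ((tie_counts ** 3 - tie_counts).sum()
                    / ((m + n) * (m + n - 1.0)))
        sigma = math.sqrt(m * n / 12.0 * ((m + n + 1.0) - tie_term))
        if sigma == 0:
            p_ge = p_le = 1.0
        else:
            p_ge = float(norm.sf((u_x - 0.5 - mu) / sigma))
            p_le = float(norm.cdf((u_x + 0.5 - mu) / sigma))
    if tail == "greater":
        p = p_ge
    elif tail == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return float(u_min), float(p)


@lru_cache(maxsize=None)
def _wilcoxon_counts(n: int) -> tuple[int, ...]:
    """Counts of the positive-rank sum W+ over all 2^n sign patterns."""
    poly = np.array([1], dtype=object)
    for r in range(1, n + 1):
        term = np.zeros(r + 1, dtype=object)
        term[0] = 1
        term[r] = 1
        poly = np.convolve(poly, term)
    return tuple(int(c) for c in poly)


def wilcoxon_signed(
    x, y=None, mu: float = 0.0, tail: str = "two"
) -> tuple[float, float]:
    """Wilcoxon signed-rank test; returns (W, p) with W = positive-rank sum.

    One-sample against ``mu`` or paired when ``y`` is given.  Zero
    differences are dropped.  Exact p by sign-pattern counting for
    ``n <= 25`` untied data, else normal approximation with tie correction.
    ``tail``: "two" | "greater" (differences tend positive) | "less".
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x - mu
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    if tail not in ("two", "greater", "less"):
        raise ValueError(f"unknown tail {tail!r}")
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    ties = _has_ties(np.abs(d))

    if n <= 25 and not ties:
        counts = np.array(_wilcoxon_counts(n), dtype=float)
        total = counts.sum()
        w_int = int(round(w_pos))
        p_ge = counts[w_int:].sum() / total
        p_le = counts[: w_int + 1].sum() / total
    else:
        mu_w = n * (n + 1) / 4.0
        tie_vals, tie_counts = np.unique(ranks, return_counts=True)
        var = (n * (n + 1) * (2 * n + 1)
               - 0.5 * (tie_counts ** 3 - tie_counts).sum()) / 24.0
        sigma = math.sqrt(var)
        if sigma == 0:
            p_ge = p_le = 1.0
        else:
            p_ge = float(norm.sf((w_pos - 0.5 - mu_w) / sigma))
            p_le = float(norm.cdf((w_pos + 0.5 - mu_w) / sigma))
    if tail == "greater":
        p = p_ge
    elif tail == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return w_pos, float(p)


# ---------------------------------------------------------------------------
# effect size and power
# ---------------------------------------------------------------------------

def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Cohen's d with the equal-n pooled SD ``sqrt((sd1^2 + sd2^2)/2)``."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    pooled = math.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0)
    return (mean1 - mean2) / pooled


def two_sample_t_power(
    d: float, n_per_group: int, alpha: float = 0.05, tails: int = 2
) -> float:
    """Exact power of a two-sample t-test via the noncentral t."""
    df = 2 * n_per_group - 2
    ncp = d * math.sqrt(n_per_group / 2.0)
    if tails == 2:
        crit = t_dist.ppf(1.0 - alpha / 2.0, df)
        return float(nct_dist.sf(crit, df, ncp) + nct_dist.cdf(-crit, df, ncp))
    crit = t_dist.ppf(1.0 - alpha, df)
    return float(nct_dist.sf(crit, df, ncp))


def required_sample_size(
    d: float,
    alpha: float = 0.05,
    power: float = 0.8,
    tails: int = 2,
    method: str = "nct",
) -> int:
    """Smallest balanced n per group reaching the requested power.

    ``method="nct"`` uses the noncentral-t power function;
    ``method="normal"`` uses the classical normal-approximation formula
    ``n = ceil(2 (z_{1-alpha/tails} + z_{power})^2 / d^2)``, which is the
    rounding convention behind many published totals.
    """
    if d <= 0:
        raise ValueError("effect size must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if method == "normal":
        z_a = norm.ppf(1.0 - alpha / tails)
        z_b = norm.ppf(power)
        return int(math.ceil(2.0 * (z_a + z_b) ** 2 / d ** 2))
    if method != "nct":
        raise ValueError(f"unknown method {method!r}")
    n = 2
    while two_sample_t_power(d, n, alpha, tails) < power:
        n += 1
        if n > 10**6:
            raise RuntimeError("sample size search did not converge")
    return n


def monte_carlo_power(
    d: float,
    n_per_group: int,
    alpha: float = 0.05,
    tails: int = 2,
    n_sims: int = 100_000,
    seed: int | None = None,
) -> float:
    """Simulated two-sample t-test power; independent check on the
    noncentral-t computation."""
    rng = np.random.default_rng(seed)
    x = rng.normal(d, 1.0, size=(n_sims, n_per_group))
    y = rng.normal(0.0, 1.0, size=(n_sims, n_per_group))
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1)
    v2 = y.var(axis=1, ddof=1)
    pooled = (v1 + v2) / 2.0
    t = (m1 - m2) / np.sqrt(pooled * 2.0 / n_per_group)
    df = 2 * n_per_group - 2
    if tails == 2:
        crit = t_dist.ppf(1.0 - alpha / 2.0, df)
        return float(np.mean(np.abs(t) > crit))
    crit = t_dist.ppf(1.0 - alpha, df)
    return float(np.mean(t > crit))


def unbiased_percent_correct(d: float) -> float:
    """Percent correct of an unbiased equal-variance observer with equal
    class priors: ``100 * Phi(d'/2)``."""
    if d < 0:
        raise ValueError("d' must be non-negative")
    return float(100.0 * norm.cdf(d / 2.0))
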