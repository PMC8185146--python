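"""Paired winner/loser inference, effect sizes and rater agreement.

The battery mirrors common practice in notational analysis: per
variable, a Shapiro-Wilk gate on the paired differences chooses
between the paired t-test and the Wilcoxon signed-rank test (two-
tailed, alpha = 0.05, no multiple-testing correction); Cohen's d is
reported both as the standardized mean difference of the paired
differences (dz) and as a pooled two-group d.  Inter-rater agreement
uses Cohen's kappa.

The Wilcoxon implementation is pinned to the SPSS convention: zero
differences dropped, mid-ranks for ties, normal approximation with
tie-corrected variance and a continuity correction; the sign of Z
follows the deviation of the positive-rank sum from its null mean.
An exact sign-permutation p-value is available for small samples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_DEFAULT = 0.05


class DegenerateSampleError(ValueError):
    """A sample whose dispersion is zero where a test requires spread."""


# ---------------------------------------------------------------------------
# paired t


def paired_t(differences: Sequence[float]) -> Tuple[float, int, float]:
    """Paired t-test from raw paired differences.

    Returns ``(t, df, p_two_tailed)`` with ``t = M / (SD / sqrt(n))``,
    ``df = n - 1`` and p from the central t distribution.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("paired t needs at least 2 differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("zero SD of differences")
    return paired_t_from_summary(d.mean(), sd, d.size)


def paired_t_from_summary(mean_diff: float, sd_diff: float, n: int) -> Tuple[float, int, float]:
    """Paired t-test from summary statistics of the differences."""
    if n < 2:
        raise ValueError("paired t needs n >= 2")
    if sd_diff <= 0:
        raise DegenerateSampleError("SD of differences must be positive")
    t = mean_diff / (sd_diff / math.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


# ---------------------------------------------------------------------------
# Wilcoxon signed rank


def _signed_rank_stats(differences: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        raise DegenerateSampleError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))  # mid-ranks for ties
    return d, ranks

def wilcoxon_signed_rank(
    differences: Sequence[float], method: str = "approx"
) -> Tuple[float, float]:
    """Wilcoxon signed-rank test for paired differences.

    Returns ``(Z, p_two_tailed)``.  ``method="approx"`` (default) uses
    the tie-corrected normal approximation with continuity correction;
    ``method="exact"`` replaces the p-value by exact enumeration of
    all sign assignments of the (mid-ranked) nonzero differences,
    feasible for up to ~20 pairs.  Z is reported from the
    approximation in both cases.
    """
    if method not in ("approx", "exact"):
        raise ValueError("method must be 'approx' or 'exact'")
    d, ranks = _signed_rank_stats(differences)
    n = d.size
    t_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: sum(t^3 - t)/48 over groups of tied |d|
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= float(((counts.astype(float) ** 3 - counts).sum()) / 48.0)
    dev = t_plus - mu
    if var <= 0:
        raise DegenerateSampleError("zero variance of the rank sum (all |d| tied at one value)")
    sigma = math.sqrt(var)
    z = (dev - math.copysign(0.5, dev)) / sigma if dev != 0 else 0.0
    if method == "approx":
        p = 2.0 * stats.norm.sf(abs(z))
        p = min(p, 1.0)
    else:
        p = _exact_signed_rank_p(ranks, abs(dev))
    return z, p


def _exact_signed_rank_p(ranks: np.ndarray, abs_dev: float) -> float:
    """Exact two-tailed p by enumerating all 2^n sign assignments:
    the probability, under sign symmetry, that |T+ - mu| >= the
    observed deviation (mid-ranks kept fixed)."""
    n = ranks.size
    if n > 20:
        raise ValueError("exact enumeration limited to n <= 20")
    mu = float(ranks.sum()) / 2.0
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        t = float(sum(r for r, s in zip(ranks, signs) if s))
        if abs(t - mu) >= abs_dev - 1e-12:
            count += 1
    return count / 2.0**n


# ---------------------------------------------------------------------------
# effect sizes


EFFECT_BANDS = ((0.20, "trivial"), (0.50, "small"), (0.80, "medium"))


def classify_effect_size(d: float) -> str:
    """Magnitude class of |d|: trivial (<0.20), small (<0.50),
    medium (<0.80), large (>=0.80)."""
    a = abs(d)
    for cut, label in EFFECT_BANDS:
        if a < cut:
            return label
    return "large"


def cohens_d_paired(differences: Sequence[float]) -> float:
    """dz: mean of the paired differences over their SD."""
    d = np.asarray(differences, dtype=float)
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("zero SD of differences")
    return float(d.mean() / sd)


def cohens_d_groups(x: Sequence[float], y: Sequence[float]) -> float:
    """Pooled two-group d: (mean(x) - mean(y)) / pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        raise DegenerateSampleError("zero pooled variance")
    return float((x.mean() - y.mean()) / math.sqrt(pooled_var))


def effect_size_d(
    differences: Optional[Sequence[float]] = None,
    groups: Optional[Tuple[Sequence[float], Sequence[float]]] = None,
    variant: str = "dz",
) -> float:
    """Cohen's d, either ``variant="dz"`` from paired differences or
    ``variant="pooled_groups"`` from the two group samples."""
    if variant == "dz":
        if differences is None:
            raise ValueError("dz needs the paired differences")
        return cohens_d_paired(differences)
    if variant == "pooled_groups":
        if groups is None:
            raise ValueError("pooled_groups needs the two group samples")
        return cohens_d_groups(*groups)
    raise ValueError("variant must be 'dz' or 'pooled_groups'")


# ---------------------------------------------------------------------------
# normality gate


def normality_gate(sample: Sequence[float], alpha: float = ALPHA_DEFAULT) -> bool:
    """True (use the parametric test) iff Shapiro-Wilk does not reject
    normality at ``alpha``.  A constant sample is treated as a gate
    failure (non-normal)."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk gate requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        return False
    _, p = stats.shapiro(x)
    return bool(p >= alpha)


# ---------------------------------------------------------------------------
# winner/loser battery


@dataclass(frozen=True)
class ComparisonResult:
    """Paired winner-loser inference for one variable."""

    variable: str
    n_pairs: int
    mean_diff: float
    sd_diff: float
    test_used: Optional[str]  # "paired_t" | "wilcoxon" | None (degenerate)
    statistic: Optional[float]  # t or Z
    df: Optional[int]  # t only
    p_two_tailed: Optional[float]
    d_dz: Optional[float]
    d_pooled: Optional[float]
    magnitude: Optional[str]
    significant: bool

    def to_dict(self) -> Dict[str, object]:
        return {
            "variable": self.variable,
            "n_pairs": self.n_pairs,
            "M": self.mean_diff,
            "SD": self.sd_diff,
            "test": self.test_used,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p_two_tailed,
            "d_dz": self.d_dz,
            "d_pooled": self.d_pooled,
            "magnitude": self.magnitude,
            "significant": self.significant,
        }


def compare_paired(
    variable: str,
    winner_values: Sequence[float],
    loser_values: Sequence[float],
    alpha: float = ALPHA_DEFAULT,
) -> ComparisonResult:
    """Winner-minus-loser paired comparison for one variable."""
    w = np.asarray(winner_values, dtype=float)
    l = np.asarray(loser_values, dtype=float)
    if w.shape != l.shape or w.ndim != 1:
        raise ValueError("winner and loser samples must be 1-D and paired")
    diffs = w - l
    n = diffs.size
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1)) if n > 1 else 0.0

    if np.all(diffs == 0.0) or sd_diff == 0.0:
        return ComparisonResult(
            variable, n, mean_diff, sd_diff, None, None, None, None,
            None, None, None, significant=False,
        )

    d_dz = cohens_d_paired(diffs)
    try:
        d_pooled = cohens_d_groups(w, l)
    except DegenerateSampleError:
        d_pooled = None

    # the gate needs n >= 3; with fewer pairs default to the t-test
    if n < 3 or normality_gate(diffs, alpha=alpha):
        t, df, p = paired_t(diffs)
        test, statistic = "paired_t", t
    else:
        z, p = wilcoxon_signed_rank(diffs)
        test, statistic, df = "wilcoxon", z, None

    return ComparisonResult(
        variable=variable,
        n_pairs=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        test_used=test,
        statistic=float(statistic),
        df=df,
        p_two_tailed=float(p),
        d_dz=d_dz,
        d_pooled=d_pooled,
        magnitude=classify_effect_size(d_dz),
        significant=bool(p < alpha),
    )


def compare_winners_losers(
    winners: pd.DataFrame, losers: pd.DataFrame, alpha: float = ALPHA_DEFAULT
) -> List[ComparisonResult]:
    """Run the battery over every shared numeric column of two aligned
    tables (one winner row and one loser row per game, same order)."""
    if len(winners) != len(losers):
        raise ValueError("winner and loser tables must have the same number of rows")
    results = []
    for col in winners.columns:
        if col not in losers.columns:
            continue
        w = pd.to_numeric(winners[col], errors="coerce")
        l = pd.to_numeric(losers[col], errors="coerce")
        mask = w.notna() & l.notna()
        if mask.sum() < 2:
            continue
        results.append(compare_paired(col, w[mask].to_numpy(), l[mask].to_numpy(), alpha=alpha))
    return results


# ---------------------------------------------------------------------------
# Cohen's kappa


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    n_observations: int
    categories: Tuple[str, ...]


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> KappaResult:
    """Cohen's kappa between two raters' category labels.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with expected agreement from
    the product of the marginals.  When both raters are constant and
    identical (``p_e = 1``) agreement is perfect and kappa is 1 by
    definition.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    n = a.size
    if n < 1:
        raise ValueError("need at least one observation")
    categories = sorted(set(a.tolist()) | set(b.tolist()), key=str)
    idx = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    table = np.zeros((k, k))
    for x, y in zip(a.tolist(), b.tolist()):
        table[idx[x], idx[y]] += 1
    table /= n
    p_o = float(np.trace(table))
    p_e = float(table.sum(axis=1) @ table.sum(axis=0))
    if abs(1.0 - p_e) < 1e-15:
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(kappa=float(kappa), n_observations=n,
                       categories=tuple(str(c) for c in categories))


def significance_marker(p: Optional[float], nonparametric: bool = False) -> str:
    """Footnote-style marker: stars by p-value plus ``^a`` for
    variables compared with the nonparametric test."""
    if p is None:
        stars = ""
    elif p < 0.001:
        stars = "***"
    elif p < 0.01:
        stars = "**"
    elif p < 0.05:
        stars = "*"
    else:
        stars = ""
    return stars + ("^a" if nonparametric else "")
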