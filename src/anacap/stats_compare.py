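"""Paired and repeated-measures comparisons of anaerobic-capacity estimates.

Implements the classical fully-within-subject analyses of a two-condition
crossover: paired t tests, one-way repeated-measures ANOVA (for the three
crossover MAOD variants) and two-way repeated-measures ANOVA (method ×
condition), with Bonferroni-adjusted post-hoc pairwise tests.  Each
within-subject effect is tested against its own subject-by-effect
interaction error term; no sphericity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "paired_t",
    "rm_anova_oneway",
    "rm_anova_twoway",
    "bonferroni",
]


@dataclass(frozen=True)
class ComparisonResult:
    design: str  # paired_t | rm_anova_1w | rm_anova_2w
    statistic: float  # t, or headline F (interaction for two-way)
    df: tuple[float, float]  # (numerator, denominator); (df, 0) for t
    p: float
    effects: dict[str, dict] = field(default_factory=dict)
    posthoc: list[tuple[object, float]] = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.df[0] <= 0:
            raise ValueError("degrees of freedom must be positive")


def paired_t(x, y) -> ComparisonResult:
    """Classical two-sided paired t test on per-participant differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays paired by participant")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            # identical samples: no evidence of any difference
            return ComparisonResult("paired_t", 0.0, (float(n - 1), 0.0), 1.0)
        raise ValueError("zero-variance non-zero differences: t is undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return ComparisonResult(
        "paired_t", t, (float(n - 1), 0.0), p,
        effects={"difference": {"mean": float(d.mean()), "sd": float(sd)}},
    )


def _f_p(ss_eff: float, df_eff: float, ss_err: float, df_err: float):
    """F and p with the degenerate conventions: a zero effect is F = 0, p = 1;
    a non-zero effect over zero error is F = inf, p = 0."""
    if ss_eff <= 1e-12 * max(1.0, ss_err):
        return 0.0, 1.0
    if ss_err <= 0:
        return float("inf"), 0.0
    F = (ss_eff / df_eff) / (ss_err / df_err)
    return float(F), float(sps.f.sf(F, df_eff, df_err))


def rm_anova_oneway(matrix, posthoc: bool = False) -> ComparisonResult:
    """One-way repeated-measures ANOVA on a participants × conditions matrix.

    The within-subject partition SS_total = SS_subjects + SS_treatment +
    SS_error is tested with F on (k − 1, (k − 1)(n − 1)) degrees of freedom.
    With ``posthoc=True``, Bonferroni-adjusted pairwise paired t tests on all
    column pairs are attached.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be participants x conditions")
    if np.any(~np.isfinite(X)):
        raise ValueError("missing cells: the design must be complete")
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n < 2:
        raise ValueError("need at least 2 participants")
    grand = X.mean()
    ss_total = float(((X - grand) ** 2).sum())
    ss_subj = float(k * ((X.mean(axis=1) - grand) ** 2).sum())
    ss_treat = float(n * ((X.mean(axis=0) - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_treat
    df_treat = k - 1
    df_err = (k - 1) * (n - 1)
    F, p = _f_p(ss_treat, df_treat, ss_err, df_err)

    ph: list[tuple[object, float]] = []
    if posthoc:
        pairs = list(combinations(range(k), 2))
        raw = [paired_t(X[:, i], X[:, j]).p for i, j in pairs]
        ph = list(zip(pairs, bonferroni(raw)))
    return ComparisonResult(
        "rm_anova_1w", F, (float(df_treat), float(df_err)), p,
        effects={"treatment": {"F": F, "df": (df_treat, df_err), "p": p,
                               "ss": ss_treat, "ss_error": ss_err}},
        posthoc=ph,
    )


def rm_anova_twoway(array) -> ComparisonResult:
    """Two-way fully-within repeated-measures ANOVA.

    ``array`` has shape (participants, levels of factor A, levels of factor
    B); both factors are within-subject.  Main effects and the interaction
    are each tested against their subject-by-effect error term.  The
    headline ``statistic``/``p`` of the result is the interaction; the full
    table lives in ``effects``.
    """
    Y = np.asarray(array, dtype=float)
    if Y.ndim != 3:
        raise ValueError("array must be participants x factorA x factorB")
    if np.any(~np.isfinite(Y)):
        raise ValueError("missing cells: the crossed design must be complete")
    n, a, b = Y.shape
    if n < 2 or a < 2 or b < 2:
        raise ValueError("need >= 2 participants and >= 2 levels per factor")
    g = Y.mean()
    m_s = Y.mean(axis=(1, 2))  # subject means
    m_a = Y.mean(axis=(0, 2))  # factor-A level means
    m_b = Y.mean(axis=(0, 1))
    m_ab = Y.mean(axis=0)  # (a, b)
    m_sa = Y.mean(axis=2)  # (n, a)
    m_sb = Y.mean(axis=1)  # (n, b)

    ss_a = n * b * float(((m_a - g) ** 2).sum())
    ss_b = n * a * float(((m_b - g) ** 2).sum())
    ss_ab = n * float(
        ((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2).sum()
    )
    ss_sa = b * float(
        ((m_sa - m_s[:, None] - m_a[None, :] + g) ** 2).sum()
    )
    ss_sb = a * float(
        ((m_sb - m_s[:, None] - m_b[None, :] + g) ** 2).sum()
    )
    ss_subj = a * b * float(((m_s - g) ** 2).sum())
    ss_total = float(((Y - g) ** 2).sum())
    ss_sab = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_sa - ss_sb

    effects = {}
    for name, ss_eff, df_eff, ss_err, df_err in (
        ("factor_a", ss_a, a - 1, ss_sa, (a - 1) * (n - 1)),
        ("factor_b", ss_b, b - 1, ss_sb, (b - 1) * (n - 1)),
        ("interaction", ss_ab, (a - 1) * (b - 1), ss_sab, (a - 1) * (b - 1) * (n - 1)),
    ):
        F, p = _f_p(ss_eff, df_eff, ss_err, df_err)
        effects[name] = {"F": F, "df": (df_eff, df_err), "p": p,
                         "ss": ss_eff, "ss_error": ss_err}

    inter = effects["interaction"]
    return ComparisonResult(
        "rm_anova_2w", inter["F"],
        (float(inter["df"][0]), float(inter["df"][1])), inter["p"],
        effects=effects,
    )


def bonferroni(pvals, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, p·m); ``m`` defaults to len(pvals)."""
    pvals = list(pvals)
    if any(not 0.0 <= p <= 1.0 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(pvals)
    return [min(1.0, p * m) for p in pvals]
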