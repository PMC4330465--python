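"""Statistical comparison of predicted and measured potencies.

The null hypothesis is that a model's predicted pIC50 values and the
measured ones are drawn from the same distribution.  Both samples are
first screened for normality (Anderson–Darling with estimated mean and
variance); only normal pairs proceed to the parametric path — a one-tailed
F test for equal variance gating a paired two-tailed t test for equal
mean.  The distribution-free Kolmogorov–Smirnov and Mann–Whitney U tests
run regardless, subject to their sample-size rules (n > 10 and n > 7
respectively).  Inapplicable cells are flagged, not errored, mirroring a
sparse results grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad

__all__ = [
    "TestOutcome",
    "ComparisonReport",
    "anderson_darling",
    "equal_variance_f",
    "paired_t",
    "ks_two_sample",
    "mann_whitney",
    "compare_predictions",
]

#: inapplicability codes, as used in the report grid
CODE_FAILED_F = "failed_F"          # variances differ, t test not run
CODE_NON_NORMAL = "non_normal"      # AD rejected normality, F/t not run
CODE_N_RULE = "n_rule"              # sample too small for KS/MW

KS_MIN_N = 10   # strict: n must exceed this
MW_MIN_N = 7


@dataclass
class TestOutcome:
    test: str
    applicable: bool
    statistic: float | None = None
    p_value: float | None = None
    reject: bool | None = None     # at the report's alpha
    code: str | None = None        # why inapplicable


@dataclass
class ComparisonReport:
    alpha: float
    normality_p: dict[str, float]
    outcomes: dict[str, TestOutcome] = field(default_factory=dict)

    def p(self, test: str) -> float | None:
        out = self.outcomes.get(test)
        return out.p_value if out and out.applicable else None

    @property
    def verdicts(self) -> dict[str, str]:
        v = {}
        for name, out in self.outcomes.items():
            if not out.applicable:
                v[name] = f"-({out.code})"
            else:
                v[name] = "reject" if out.reject else "equal"
        return v


def _clean(sample) -> np.ndarray:
    a = np.asarray(sample, dtype=float).ravel()
    if not np.isfinite(a).all():
        raise ValueError("sample contains non-finite values")
    return a


def anderson_darling(sample, alpha: float = 0.05) -> tuple[float, bool]:
    """Anderson–Darling normality test (mean and variance estimated).

    Returns (p_value, is_normal_verdict).  Uses the small-sample adjusted
    statistic and p-value mapping for the estimated-parameters case.
    """
    a = _clean(sample)
    if a.size < 5:
        raise ValueError(f"need n >= 5, got {a.size}")
    if np.ptp(a) == 0:
        raise ValueError("constant sample has zero variance")
    _, p = normal_ad(a)
    return float(p), bool(p >= alpha)


def equal_variance_f(sample_a, sample_b) -> tuple[float, float]:
    """One-tailed F test for equal variances (larger over smaller).

    Returns (F, p).  F = s²_max / s²_min ≥ 1; identical variances give
    F = 1 with p = 0.5, which is reported and never rejected.  Because the
    ratio is always oriented larger-over-smaller, this one-tailed p covers
    both tails: a level-α equal-variance decision must compare p to α/2
    (done in :func:`compare_predictions`), otherwise the test rejects twice
    as often as nominal.
    """
    a, b = _clean(sample_a), _clean(sample_b)
    if a.size < 3 or b.size < 3:
        raise ValueError("need n >= 3 per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("zero variance sample")
    if va >= vb:
        F, dfn, dfd = va / vb, a.size - 1, b.size - 1
    else:
        F, dfn, dfd = vb / va, b.size - 1, a.size - 1
    p = float(stats.f.sf(F, dfn, dfd))
    return float(F), p


def paired_t(sample_a, sample_b) -> tuple[float, float]:
    """Paired two-tailed t test on the differences; returns (t, p)."""
    a, b = _clean(sample_a), _clean(sample_b)
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    d = a - b
    if np.ptp(d) == 0:
        # all differences identical: zero shift is certain (t = 0) …
        if d[0] == 0:
            return 0.0, 1.0
        raise ValueError("constant nonzero differences: t undefined (zero s.d.)")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test; returns (D, p)."""
    a, b = _clean(sample_a), _clean(sample_b)
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def mann_whitney(sample_a, sample_b) -> tuple[float, float]:
    """Two-tailed Mann–Whitney U.

    Uses the exact U distribution when both samples are small (≤ 25) and
    tie-free — where it coincides with brute-force enumeration over all
    rank assignments — and the normal approximation with midranks and tie
    correction otherwise.
    """
    a, b = _clean(sample_a), _clean(sample_b)
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if no_ties and max(a.size, b.size) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_predictions(predicted, measured, alpha: float = 0.05) -> ComparisonReport:
    """Full comparison grid for one (model, test set) cell.

    Runs Anderson–Darling on both samples; if both pass, the F test; if the
    F test does not reject, the paired t test.  KS and MW run whenever
    their size rules (n > 10, n > 7) are met.  Each inapplicable test is
    recorded with the reason code rather than omitted silently.
    """
    p_arr, m_arr = _clean(predicted), _clean(measured)
    if p_arr.size != m_arr.size:
        raise ValueError(f"length mismatch: {p_arr.size} vs {m_arr.size}")
    n = p_arr.size
    if n < 3:
        raise ValueError(f"need at least 3 paired values, got {n}")

    report = ComparisonReport(alpha=alpha, normality_p={})
    both_normal = True
    for label, arr in (("predicted", p_arr), ("measured", m_arr)):
        try:
            p_ad, normal = anderson_darling(arr, alpha=alpha)
        except ValueError:
            p_ad, normal = float("nan"), False
        report.normality_p[label] = p_ad
        both_normal &= normal

    if not both_normal:
        report.outcomes["F"] = TestOutcome("F", False, code=CODE_NON_NORMAL)
        report.outcomes["t"] = TestOutcome("t", False, code=CODE_NON_NORMAL)
    else:
        F, pF = equal_variance_f(p_arr, m_arr)
        # the larger/smaller one-tailed p covers both tails: level-alpha
        # decision compares against alpha/2
        f_reject = pF < alpha / 2
        report.outcomes["F"] = TestOutcome("F", True, F, pF, reject=f_reject)
        if f_reject:
            report.outcomes["t"] = TestOutcome("t", False, code=CODE_FAILED_F)
        else:
            t, pt = paired_t(p_arr, m_arr)
            report.outcomes["t"] = TestOutcome("t", True, t, pt, reject=pt < alpha)

    if n > KS_MIN_N:
        D, pks = ks_two_sample(p_arr, m_arr)
        report.outcomes["KS"] = TestOutcome("KS", True, D, pks, reject=pks < alpha)
    else:
        report.outcomes["KS"] = TestOutcome("KS", False, code=CODE_N_RULE)

    if n > MW_MIN_N:
        U, pmw = mann_whitney(p_arr, m_arr)
        report.outcomes["MW"] = TestOutcome("MW", True, U, pmw, reject=pmw < alpha)
    else:
        report.outcomes["MW"] = TestOutcome("MW", False, code=CODE_N_RULE)

    return report


def comparison_grid(predictions: Mapping[str, Mapping[str, np.ndarray]],
                    measured: Mapping[str, np.ndarray],
                    alpha: float = 0.05) -> dict[str, dict[str, ComparisonReport]]:
    """Reports for every (model, set) pair: predictions[model][set] vs measured[set]."""
    grid: dict[str, dict[str, ComparisonReport]] = {}
    for model, per_set in predictions.items():
        grid[model] = {}
        for label, pred in per_set.items():
            grid[model][label] = compare_predictions(pred, measured[label], alpha=alpha)
    return grid
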