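"""Normality-gated group comparisons and significance reporting.

The selection rule mirrors common practice in quantitative microscopy
papers: every dataset is screened with the D'Agostino–Pearson omnibus
normality test (α = 0.05; the test needs n ≥ 8, smaller samples are treated
as non-normal).  Two normal samples are compared with an unpaired t test,
upgraded to Welch's t when an F test rejects equality of variances
(α = 0.05); otherwise the Mann–Whitney U test is used (exact p for small
tie-free samples, normal approximation with tie correction otherwise).
Cumulative distributions are compared with the two-sample
Kolmogorov–Smirnov test, and paired designs with a paired t test.
Significance stars follow the strict thresholds 0.05 / 0.01 / 0.001 /
0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GroupComparison", "compare_groups", "per_animal_summary",
           "star_labels", "NORMALITY_MIN_N"]

#: Minimum sample size for the omnibus normality test.
NORMALITY_MIN_N = 8


@dataclass
class GroupComparison:
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    normality_p: tuple            # (p_a, p_b), NaN when n < 8
    test_used: str                # student_t | welch_t | mann_whitney | ks_2samp | paired_t
    statistic: float
    p_value: float
    stars: str
    notes: str = ""


def star_labels(p: float) -> str:
    """Significance label from a two-sided p-value (strict thresholds)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p!r} outside [0, 1]")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan


def _normal(x: np.ndarray) -> tuple[bool, float]:
    if len(x) < NORMALITY_MIN_N:
        return False, np.nan
    _, p = stats.normaltest(x)
    return p >= 0.05, float(p)


def _variances_differ(a: np.ndarray, b: np.ndarray) -> bool:
    """Two-sided F test of variance equality at α = 0.05."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return False
    if vb == 0 or va == 0:
        return True
    f = va / vb
    p = 2 * min(stats.f.cdf(f, len(a) - 1, len(b) - 1),
                stats.f.sf(f, len(a) - 1, len(b) - 1))
    return p < 0.05


def compare_groups(
    a,
    b,
    paired: bool = False,
    distributional: bool = False,
    force_test: str | None = None,
) -> GroupComparison:
    """Compare two samples under the normality-gated selection rule.

    ``distributional=True`` compares the full distributions (two-sample KS);
    ``paired=True`` forces a paired t test (equal lengths required; a
    normality caveat is recorded in ``notes`` when either sample fails the
    screen).  ``force_test`` bypasses the gate for a named test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if paired and len(a) != len(b):
        raise ValueError("paired comparison requires equal-length samples")

    norm_a, p_norm_a = _normal(a)
    norm_b, p_norm_b = _normal(b)
    notes = ""

    if force_test == "mann_whitney":
        test = "mann_whitney"
    elif force_test is not None:
        test = force_test
    elif distributional:
        test = "ks_2samp"
    elif paired:
        test = "paired_t"
        if not (norm_a and norm_b):
            notes = "paired t forced; normality screen not passed"
    elif norm_a and norm_b:
        test = "welch_t" if _variances_differ(a, b) else "student_t"
    else:
        test = "mann_whitney"

    if test == "student_t":
        stat, p = stats.ttest_ind(a, b, equal_var=True)
    elif test == "welch_t":
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    elif test == "paired_t":
        stat, p = stats.ttest_rel(a, b)
    elif test == "ks_2samp":
        res = stats.ks_2samp(a, b, method="auto")
        stat, p = res.statistic, res.pvalue
    elif test == "mann_whitney":
        ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (min(len(a), len(b)) <= NORMALITY_MIN_N
                             and not ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = res.statistic, res.pvalue
    else:
        raise ValueError(f"unknown test {test!r}")

    p = float(np.clip(p, 0.0, 1.0))
    return GroupComparison(
        n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=_sem(a), sem_b=_sem(b),
        normality_p=(p_norm_a, p_norm_b),
        test_used=test,
        statistic=float(stat),
        p_value=p,
        stars=star_labels(p),
        notes=notes,
    )


def per_animal_summary(values, animal_ids) -> dict:
    """Animal-level means alongside the pooled per-observation summary.

    Returns the per-animal means, their group mean ± SEM, and the pooled
    mean ± SEM; SEM across animals is missing (with a reason) for a single
    animal.
    """
    values = np.asarray(values, dtype=float)
    ids = np.asarray(animal_ids)
    if len(values) != len(ids):
        raise ValueError("values and animal_ids must have equal length")
    if len(values) == 0 or (ids == None).any() or any(  # noqa: E711
            isinstance(i, float) and np.isnan(i) for i in np.atleast_1d(ids)):
        raise ValueError("every value needs an animal id")

    uniq = list(dict.fromkeys(ids))
    animal_means = {u: float(values[ids == u].mean()) for u in uniq}
    means = np.array(list(animal_means.values()))
    out = {
        "animal_means": animal_means,
        "n_animals": len(uniq),
        "mean": float(means.mean()),
        "sem": _sem(means) if len(means) > 1 else None,
        "pooled_mean": float(values.mean()),
        "pooled_sem": _sem(values),
    }
    if len(means) <= 1:
        out["sem_missing_reason"] = "single animal; SEM across animals undefined"
    return out
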