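"""Hypothesis tests, effect sizes, resampling CIs and rater agreement.

The comparison protocol for paired distance profiles is the two-sided
Wilcoxon signed-rank test (exact sign-pattern enumeration for up to 15
nonzero differences, normal approximation with tie correction above),
Cohen's d on the pooled sample standard deviation, and percentile 95%
confidence intervals from 1000 resamples of size N/2 (without replacement
by default — sub-sampling; bootstrap with replacement available).

Paired classifier accuracies are compared with the mid-p McNemar test on
discordant counts. Rater agreement uses Cohen's kappa (two raters) and
Fleiss' kappa (panels), plus the leave-one-out protocols: each rater
against the majority vote of the others, and a model appended to rater
subsets as one extra rater.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import binom, norm, rankdata

from .cohort import RaterPanel


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
        }


@dataclass(frozen=True)
class ResampleSummary:
    mean: float
    ci_low: float
    ci_high: float
    n_reps: int
    sample_size: int
    seed: int
    replace: bool

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean + 1e-12 and self.mean <= self.ci_high + 1e-12):
            raise ValueError("CI must bracket the mean")

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_reps": self.n_reps,
            "sample_size": self.sample_size,
            "seed": self.seed,
            "replace": self.replace,
        }


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped. With n <= 15 nonzero differences the
    two-sided p is computed by full enumeration of the 2^n sign patterns
    (P(|W+ - E[W+]| >= observed), valid under ties via average ranks);
    larger n uses the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    if n <= 15:
        # exact null distribution of W+ over all 2^n sign patterns, built by
        # convolution on the doubled-rank scale (average ranks stay integral)
        dr = np.rint(2 * ranks).astype(int)
        dist = np.zeros(dr.sum() + 1)
        dist[0] = 1.0
        for r in dr:
            new = dist.copy()
            new[r:] += dist[: dist.size - r]
            dist = new
        dist /= dist.sum()
        support = np.arange(dist.size) / 2.0
        dev = abs(w_plus - mean_w)
        p = float(dist[np.abs(support - mean_w) >= dev - 1e-9].sum())
    else:
        _, tie_sizes = np.unique(np.abs(d), return_counts=True)
        tie_term = float((tie_sizes**3 - tie_sizes).sum()) / 48.0
        var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean_w) / np.sqrt(var_w)
        p = float(2 * norm.sf(abs(z)))
    return TestResult(w_plus, min(p, 1.0), "wilcoxon_signed_rank", n)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized mean difference with pooled (n-1) sample SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def resample_summary(
    values: np.ndarray,
    n_reps: int = 1000,
    sample_size: int | None = None,
    replace: bool = False,
    seed: int = 0,
) -> ResampleSummary:
    """Mean and percentile 95% CI of resampled means (default: 1000
    sub-samples of size ceil(N/2) without replacement)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values")
    if sample_size is None:
        sample_size = int(np.ceil(n / 2))
    if sample_size < 1 or (not replace and sample_size > n):
        raise ValueError("invalid sample_size")
    rng = np.random.default_rng(seed)
    means = np.empty(n_reps)
    for r in range(n_reps):
        means[r] = values[rng.choice(n, size=sample_size, replace=replace)].mean()
    lo, hi = np.percentile(means, [2.5, 97.5])
    return ResampleSummary(
        float(means.mean()), float(lo), float(hi), n_reps, sample_size, seed, replace
    )


def mcnemar_mid_p(n01: int, n10: int) -> TestResult:
    """Mid-p McNemar test on the discordant-pair counts.

    With k = min(n01, n10) and n = n01 + n10, X ~ Binomial(n, 1/2):
    p = 2 * (P(X <= k) - P(X = k) / 2), capped at 1; p = 1 when n = 0.
    """
    if n01 < 0 or n10 < 0:
        raise ValueError("discordant counts must be non-negative")
    n = n01 + n10
    k = min(n01, n10)
    if n == 0:
        return TestResult(0.0, 1.0, "mcnemar_mid_p", 0)
    p = 2.0 * (binom.cdf(k, n, 0.5) - 0.5 * binom.pmf(k, n, 0.5))
    return TestResult(float(k), float(min(p, 1.0)), "mcnemar_mid_p", n)


def cohens_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected agreement between two raters (binary labels)."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("label vectors must be non-empty and equally long")
    n = a.size
    p_o = float((a == b).mean())
    cats = np.union1d(a, b)
    p_e = float(sum((a == c).mean() * (b == c).mean() for c in cats))
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        raise ValueError("kappa undefined: chance agreement is 1 with imperfect agreement")
    return (p_o - p_e) / (1.0 - p_e)


def _fleiss_from_counts(counts: np.ndarray) -> float:
    """Fleiss' kappa from an items x categories vote-count matrix."""
    counts = np.asarray(counts, dtype=float)
    n_raters = counts.sum(axis=1)
    if not np.all(n_raters == n_raters[0]):
        raise ValueError("all items must have the same number of votes")
    n = n_raters[0]
    if n < 2:
        raise ValueError("Fleiss' kappa needs at least 2 raters")
    p_item = ((counts**2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = float(p_item.mean())
    p_cat = counts.sum(axis=0) / counts.sum()
    p_e = float((p_cat**2).sum())
    if p_e == 1.0:
        return 1.0 if p_bar == 1.0 else float("nan")
    return (p_bar - p_e) / (1.0 - p_e)


def fleiss_kappa(panel: RaterPanel) -> float:
    """Fleiss' kappa of a binary recommendation panel (raters x cases)."""
    rec = panel.recommendations
    if rec.shape[0] < 2:
        raise ValueError("Fleiss' kappa needs at least 2 raters")
    ones = rec.sum(axis=0)
    counts = np.column_stack([rec.shape[0] - ones, ones])
    return _fleiss_from_counts(counts)


def majority_vote(panel: RaterPanel, tie_rule: str = "exc") -> np.ndarray:
    """Per-case modal recommendation; even-split ties default to EXC (the
    clinically conservative choice), ``tie_rule='noexc'`` inverts that."""
    rec = panel.recommendations
    if rec.shape[0] < 1:
        raise ValueError("empty panel")
    ones = rec.sum(axis=0)
    zeros = rec.shape[0] - ones
    if tie_rule == "exc":
        return (ones >= zeros).astype(np.int64)
    if tie_rule == "noexc":
        return (ones > zeros).astype(np.int64)
    raise ValueError(f"unknown tie rule {tie_rule!r}")


def pairwise_cohen_summary(panel: RaterPanel) -> tuple[float, float]:
    """Mean and SD of Cohen's kappa over all rater pairs."""
    rec = panel.recommendations
    kappas = [
        cohens_kappa(rec[i], rec[j]) for i, j in combinations(range(rec.shape[0]), 2)
    ]
    return float(np.mean(kappas)), float(np.std(kappas))


def loo_cohen_protocol(panel: RaterPanel) -> tuple[float, float, int]:
    """Each rater against the majority vote of all the others.

    Returns (mean, sd, n_excluded); folds with an undefined kappa are
    excluded and counted.
    """
    rec = panel.recommendations
    if rec.shape[0] < 3:
        raise ValueError("need at least 3 raters")
    kappas = []
    n_excluded = 0
    for r in range(rec.shape[0]):
        others = RaterPanel(
            np.delete(rec, r, axis=0),
            [i for k, i in enumerate(panel.rater_ids) if k != r],
            panel.case_ids,
        )
        try:
            kappas.append(cohens_kappa(rec[r], majority_vote(others)))
        except ValueError:
            n_excluded += 1
    return float(np.mean(kappas)), float(np.std(kappas)), n_excluded


def panel_model_fleiss(
    panel: RaterPanel,
    model_preds: np.ndarray,
    subset_size: int | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Fleiss' kappa of rater subsets augmented with the model's predictions.

    With ``subset_size`` given: per repetition, sample that many raters
    without replacement, append the model as one extra rater, compute
    Fleiss' kappa; returns mean and sd over repetitions. With
    ``subset_size=None``: the leave-one-out variant — all raters minus one,
    plus the model, once per rater.
    """
    rec = panel.recommendations
    model_preds = np.asarray(model_preds, dtype=np.int64)
    if model_preds.size != rec.shape[1]:
        raise ValueError("model predictions must cover every panel case")

    def kappa_with(rows: np.ndarray) -> float:
        stacked = np.vstack([rows, model_preds])
        ones = stacked.sum(axis=0)
        counts = np.column_stack([stacked.shape[0] - ones, ones])
        return _fleiss_from_counts(counts)

    if subset_size is None:
        kappas = [kappa_with(np.delete(rec, r, axis=0)) for r in range(rec.shape[0])]
    else:
        if subset_size >= rec.shape[0]:
            raise ValueError("subset_size must be smaller than the rater count")
        rng = np.random.default_rng(seed)
        kappas = [
            kappa_with(rec[rng.choice(rec.shape[0], size=subset_size, replace=False)])
            for _ in range(n_reps)
        ]
    return float(np.mean(kappas)), float(np.std(kappas))
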