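"""Agreement statistics for percent-density raters.

Implements the full evaluation methodology: reference-standard
construction (per-subject median of the rater panel), two-way
random-effects absolute-agreement single-measurement ICC — the form that
matches a quadratically weighted kappa — with a McGraw–Wong F-based 95%
CI, quadratically weighted kappa itself, Pearson correlation,
Bland-Altman bias and limits of agreement, the within-one-BI-RADS-
category proportion, and per-category five-number summaries.

Conventions fixed here (the published design leaves them open):
- ICC CI via the McGraw–Wong F method at alpha = 0.05.
- Bland-Altman differences are reference minus algorithm; sigma is the
  sample (n-1) standard deviation.
- Even rater counts take the mean of the two central values as median.
- Box summaries use linear-interpolation quartiles and Tukey 1.5 IQR
  whiskers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .density_core import birads_category
from .errors import UndefinedStatisticError

ICC_SCALE = (
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "excellent"),
)

PERCENT_GRID = np.arange(0, 105, 5)


@dataclass
class RaterPanel:
    """Complete subjects-by-raters matrix of percent-density ratings."""

    ratings: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    rater_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=float)
        if self.ratings.ndim != 2 or self.ratings.size == 0:
            raise ValueError("ratings must be a non-empty 2-D matrix")
        if np.any(np.isnan(self.ratings)):
            raise ValueError("ratings must have no missing cells")
        if np.any((self.ratings < 0) | (self.ratings > 100)):
            raise ValueError("ratings must lie in [0, 100]")
        if not self.subject_ids:
            self.subject_ids = [f"subject-{i}"
                                for i in range(self.ratings.shape[0])]
        if not self.rater_ids:
            self.rater_ids = [f"rater-{r}"
                              for r in range(self.ratings.shape[1])]

    @property
    def n_subjects(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[1]


def reference_standard(panel: RaterPanel) -> np.ndarray:
    """Per-subject median across raters (mean of the central pair when the
    rater count is even)."""
    if panel.n_raters < 1:
        raise ValueError("panel must have at least one rater")
    return np.median(panel.ratings, axis=1)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_two_way(ratings: np.ndarray,
                alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measurement, with a 95% CI by the McGraw–Wong F method.

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    from the two-way ANOVA mean squares (rows = subjects, columns =
    raters).  This absolute-agreement form is the one equivalent to a
    quadratically weighted kappa.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be at least 2 subjects x 2 raters")
    if np.any(np.isnan(x)):
        raise ValueError("ratings must have no missing cells")
    msr, msc, mse, n, k = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        raise UndefinedStatisticError(
            "ICC undefined: no variance in the ratings")
    icc = (msr - mse) / denom
    if mse == 0 and msc == 0:
        # perfect agreement: every rater identical on every subject
        return 1.0, 1.0, 1.0
    if icc >= 1.0 - 1e-12:
        return float(icc), float(icc), float(icc)

    # McGraw & Wong confidence bounds for ICC(A,1)
    a = k * icc / (n * (1.0 - icc))
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr)
    lower = min(lower, icc)
    upper = max(upper, icc)
    return float(icc), float(lower), float(upper)


def icc_interpretation(icc: float) -> str:
    """Label an ICC on the five-step agreement scale (0.20/0.40/0.60/0.80
    boundaries); negative values are 'poor'."""
    if not -1.0 <= icc <= 1.0:
        raise ValueError(f"ICC {icc} outside [-1, 1]")
    for bound, name in ICC_SCALE:
        if icc <= bound:
            return name
    return "excellent"


# ---------------------------------------------------------------------------
# kappa / correlation / Bland-Altman
# ---------------------------------------------------------------------------

def quadratic_weighted_kappa(ratings_a, ratings_b,
                             categories: np.ndarray | None = None) -> float:
    """Cohen's kappa with quadratic disagreement weights
    w_ij = (i - j)^2 / (K - 1)^2 on an ordered category grid (defaults to
    the 21-point percent grid when the data live on it)."""
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rating vectors must be 1-D and aligned")
    if categories is None:
        on_grid = np.all(np.isin(a, PERCENT_GRID)) and \
            np.all(np.isin(b, PERCENT_GRID))
        categories = PERCENT_GRID if on_grid else np.unique(
            np.concatenate([a, b]))
    categories = np.asarray(categories, dtype=float)
    k = len(categories)
    if k < 2:
        raise UndefinedStatisticError("kappa needs at least two categories")
    ia = np.searchsorted(categories, a)
    ib = np.searchsorted(categories, b)
    n = a.size
    observed = np.zeros((k, k))
    np.add.at(observed, (ia, ib), 1.0)
    observed /= n
    pa = observed.sum(axis=1)
    pb = observed.sum(axis=0)
    expected = np.outer(pa, pb)
    i_idx, j_idx = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    weights = (i_idx - j_idx) ** 2 / (k - 1) ** 2
    expected_disagreement = float(np.sum(weights * expected))
    if expected_disagreement == 0:
        raise UndefinedStatisticError(
            "kappa undefined: no chance disagreement (constant ratings)")
    return 1.0 - float(np.sum(weights * observed)) / expected_disagreement


def pearson_rho(x, y) -> float:
    """Standard product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need aligned 1-D vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class BlandAltman:
    """Bias and limits of agreement for reference minus algorithm."""

    bias: float
    loa_low: float
    loa_high: float
    differences: np.ndarray
    means: np.ndarray


def bland_altman(reference, algorithm) -> BlandAltman:
    """Differences d = reference - algorithm; bias = mean(d); limits =
    bias +/- 1.96 times the sample (n-1) standard deviation of d."""
    ref = np.asarray(reference, dtype=float)
    alg = np.asarray(algorithm, dtype=float)
    if ref.shape != alg.shape or ref.ndim != 1:
        raise ValueError("reference and algorithm vectors must be aligned")
    if ref.size < 2:
        raise ValueError("need at least two paired measurements")
    d = ref - alg
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        differences=d,
        means=0.5 * (ref + alg),
    )


def within_one_birads(reference, algorithm) -> float:
    """Proportion of subjects whose two density readings fall within one
    BI-RADS category of each other."""
    ref = np.asarray(reference, dtype=float)
    alg = np.asarray(algorithm, dtype=float)
    if ref.shape != alg.shape or ref.ndim != 1 or ref.size == 0:
        raise ValueError("need aligned non-empty vectors")
    ref_cat = np.array([birads_category(v) for v in ref])
    alg_cat = np.array([birads_category(v) for v in alg])
    return float(np.mean(np.abs(ref_cat - alg_cat) <= 1))


def category_distribution_summary(reference, algorithm_categories) -> dict:
    """Five-number summary (plus Tukey whiskers) of the reference values
    within each algorithm-assigned BI-RADS category; empty categories map
    to None."""
    ref = np.asarray(reference, dtype=float)
    cats = np.asarray(algorithm_categories, dtype=int)
    if ref.shape != cats.shape:
        raise ValueError("reference and category vectors must be aligned")
    summaries: dict[int, dict | None] = {}
    for cat in (1, 2, 3, 4):
        values = ref[cats == cat]
        if values.size == 0:
            summaries[cat] = None
            continue
        q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interp
        iqr = q3 - q1
        in_fence = values[(values >= q1 - 1.5 * iqr)
                          & (values <= q3 + 1.5 * iqr)]
        summaries[cat] = {
            "n": int(values.size),
            "min": float(values.min()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "max": float(values.max()),
            "whisker_low": float(in_fence.min()),
            "whisker_high": float(in_fence.max()),
        }
    return summaries


# ---------------------------------------------------------------------------
# composite report
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Everything the evaluation computes, in one place."""

    icc: float
    icc_ci_low: float
    icc_ci_high: float
    icc_label: str
    panel_icc: float
    panel_icc_ci_low: float
    panel_icc_ci_high: float
    panel_icc_label: str
    pearson_rho: float
    bias: float
    loa_low: float
    loa_high: float
    within_one_birads: float
    promising: bool
    n_subjects: int
    category_summaries: dict = field(default_factory=dict)

    def validate(self) -> None:
        assert self.icc_ci_low <= self.icc <= self.icc_ci_high
        assert self.loa_low <= self.bias <= self.loa_high
        assert 0.0 <= self.within_one_birads <= 1.0

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "icc_ci_low": self.icc_ci_low,
            "icc_ci_high": self.icc_ci_high,
            "icc_label": self.icc_label,
            "panel_icc": self.panel_icc,
            "panel_icc_ci_low": self.panel_icc_ci_low,
            "panel_icc_ci_high": self.panel_icc_ci_high,
            "panel_icc_label": self.panel_icc_label,
            "pearson_rho": self.pearson_rho,
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "within_one_birads": self.within_one_birads,
            "promising": self.promising,
            "n_subjects": self.n_subjects,
            "category_summaries": self.category_summaries,
        }


def evaluate(panel: RaterPanel, algorithm_densities,
             alpha: float = 0.05) -> AgreementReport:
    """Full evaluation of an algorithm against a rater panel.

    The reference standard is the per-subject panel median.  The
    algorithm is flagged ``promising`` when its ICC against the reference
    standard falls within the 95% CI of the panel's inter-rater ICC.
    """
    alg = np.asarray(algorithm_densities, dtype=float)
    if alg.ndim != 1 or alg.size != panel.n_subjects:
        raise ValueError("algorithm densities must align with panel subjects")
    ref = reference_standard(panel)
    panel_icc, panel_lo, panel_hi = icc_two_way(panel.ratings, alpha=alpha)
    icc, lo, hi = icc_two_way(np.column_stack([ref, alg]), alpha=alpha)
    ba = bland_altman(ref, alg)
    alg_cats = [birads_category(min(max(v, 0.0), 100.0)) for v in alg]
    report = AgreementReport(
        icc=icc,
        icc_ci_low=lo,
        icc_ci_high=hi,
        icc_label=icc_interpretation(icc),
        panel_icc=panel_icc,
        panel_icc_ci_low=panel_lo,
        panel_icc_ci_high=panel_hi,
        panel_icc_label=icc_interpretation(panel_icc),
        pearson_rho=pearson_rho(alg, ref),
        bias=ba.bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        within_one_birads=within_one_birads(ref, alg),
        promising=bool(panel_lo <= icc <= panel_hi),
        n_subjects=panel.n_subjects,
        category_summaries=category_distribution_summary(ref, alg_cats),
    )
    report.validate()
    return report
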