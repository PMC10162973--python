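"""Statistical selection of the ROIs most discriminant of inversion.

Three criteria are applied to the fold x ROI table of inversion relevance
scores, each built on paired Wilcoxon signed-rank tests with Bonferroni
correction inside its own family:

1. relevance significantly higher than the per-fold average across all
   68 ROIs (one-sided, 68 tests);
2. relevance not significantly different from the ROI with maximum
   fold-mean relevance (two-sided, 67 tests; the maximum ROI qualifies);
3. relevance significantly different from the same ROI's relevance under
   the control (house) stimulus (two-sided, 68 tests).

Only ROIs meeting all three criteria are selected.

The signed-rank test itself is implemented here with exact null
distributions: full sign enumeration for n <= 12 (valid with midranks under
ties), a cached convolution-built distribution for larger tie-free samples,
and a tie-corrected normal approximation with continuity correction
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .datatypes import ValidationError

EXACT_ENUMERATION_MAX_N = 12
EXACT_DISTRIBUTION_MAX_N = 25


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+: sum of ranks of positive differences
    pvalue: float
    n_used: int  # pairs remaining after zero handling
    method: str  # 'enumeration' | 'exact' | 'normal'


@lru_cache(maxsize=64)
def _exact_counts(n: int) -> np.ndarray:
    """Null distribution of W+ for untied ranks 1..n (convolution build)."""
    counts = np.zeros(n * (n + 1) // 2 + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r]
        counts = counts + shifted
    return counts


@lru_cache(maxsize=32)
def _sign_matrix(n: int) -> np.ndarray:
    bits = np.arange(2**n, dtype=np.uint32)
    return ((bits[:, None] >> np.arange(n)) & 1).astype(float)


def wilcoxon_signed_rank(
    x,
    y=None,
    alternative: str = "two-sided",
    zero_method: str = "discard",
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test.

    Tests whether the paired differences ``x - y`` (or ``x`` itself if
    ``y`` is None) are symmetric about zero.  Zero differences are
    discarded by default (classic Wilcoxon; ``zero_method='pratt'`` keeps
    them in the ranking).  Tied absolute differences receive averaged
    ranks.  ``alternative='greater'`` tests whether x tends to exceed y.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if d.ndim != 1:
        raise ValidationError("inputs must be 1-D paired samples")

    if zero_method == "pratt":
        ranks_all = rankdata(np.abs(d))
        nz = d != 0
        ranks = ranks_all[nz]
        d_nz = d[nz]
    elif zero_method == "discard":
        nz = d != 0
        d_nz = d[nz]
        ranks = rankdata(np.abs(d_nz))
    else:
        raise ValidationError(f"unknown zero_method {zero_method!r}")

    n = d_nz.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, pvalue=1.0, n_used=0, method="degenerate")
    W = float(ranks[d_nz > 0].sum())

    has_ties = np.unique(np.abs(d_nz)).size != n
    if n <= EXACT_ENUMERATION_MAX_N and zero_method == "discard":
        # Exhaustive sign enumeration; exact even with midranks.
        w_all = _sign_matrix(n) @ ranks
        p_ge = float(np.mean(w_all >= W - 1e-9))
        p_le = float(np.mean(w_all <= W + 1e-9))
        method = "enumeration"
    elif n <= EXACT_DISTRIBUTION_MAX_N and not has_ties and zero_method == "discard":
        counts = _exact_counts(n)
        total = counts.sum()
        wi = int(round(W))
        p_ge = float(counts[wi:].sum() / total)
        p_le = float(counts[: wi + 1].sum() / total)
        method = "exact"
    else:
        mn = n * (n + 1) / 4.0
        tie_sizes = np.unique(np.abs(d_nz), return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_sizes**3 - tie_sizes).sum()) / 48.0
        se = np.sqrt(var)
        p_ge = float(norm.sf((W - mn - 0.5) / se))
        p_le = float(norm.cdf((W - mn + 0.5) / se))
        method = "normal"

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return WilcoxonResult(statistic=W, pvalue=p, n_used=n, method=method)


@dataclass
class CriterionResult:
    name: str
    members: list[str]
    pvalues: pd.Series  # raw p per tested ROI
    pvalues_corrected: pd.Series
    n_tests: int
    alpha: float


def _check_table(scores: pd.DataFrame, min_folds: int = 5) -> None:
    if scores.shape[1] < 2:
        raise ValidationError("need at least 2 ROIs")
    if len(scores) < min_folds:
        raise ValidationError(
            f"need at least {min_folds} folds for the signed-rank criteria, "
            f"got {len(scores)}"
        )


def criterion_above_average(rs, alpha: float = 0.05) -> CriterionResult:
    """ROIs with relevance significantly above the per-fold ROI average."""
    scores = rs.scores if hasattr(rs, "scores") else rs
    _check_table(scores)
    fold_avg = scores.mean(axis=1).to_numpy()
    pvals = {}
    for roi in scores.columns:
        res = wilcoxon_signed_rank(scores[roi].to_numpy(), fold_avg, alternative="greater")
        pvals[roi] = res.pvalue
    p = pd.Series(pvals)
    n_tests = len(p)
    p_corr = (p * n_tests).clip(upper=1.0)
    members = list(p_corr.index[p_corr < alpha])
    return CriterionResult("above-average", members, p, p_corr, n_tests, alpha)


def criterion_comparable_to_max(rs, alpha: float = 0.05) -> CriterionResult:
    """The maximum-relevance ROI plus every ROI statistically comparable to it."""
    scores = rs.scores if hasattr(rs, "scores") else rs
    _check_table(scores)
    max_roi = scores.mean(axis=0).idxmax()
    ref = scores[max_roi].to_numpy()
    pvals = {}
    for roi in scores.columns:
        if roi == max_roi:
            continue
        res = wilcoxon_signed_rank(scores[roi].to_numpy(), ref, alternative="two-sided")
        pvals[roi] = res.pvalue
    p = pd.Series(pvals)
    n_tests = len(p)  # 67 in the full atlas
    p_corr = (p * n_tests).clip(upper=1.0)
    members = [max_roi] + list(p_corr.index[p_corr >= alpha])
    members = [r for r in scores.columns if r in set(members)]  # atlas order
    return CriterionResult("comparable-to-max", members, p, p_corr, n_tests, alpha)


def criterion_social_vs_control(rs_social, rs_control, alpha: float = 0.05) -> CriterionResult:
    """ROIs whose relevance differs between the social and control stimulus."""
    social = rs_social.scores if hasattr(rs_social, "scores") else rs_social
    control = rs_control.scores if hasattr(rs_control, "scores") else rs_control
    if social.shape != control.shape or list(social.columns) != list(control.columns):
        raise ValidationError("social and control tables must share folds x ROIs")
    _check_table(social)
    pvals = {}
    for roi in social.columns:
        res = wilcoxon_signed_rank(social[roi].to_numpy(), control[roi].to_numpy(),
                                   alternative="two-sided")
        pvals[roi] = res.pvalue
    p = pd.Series(pvals)
    n_tests = len(p)
    p_corr = (p * n_tests).clip(upper=1.0)
    members = list(p_corr.index[p_corr < alpha])
    return CriterionResult("social-vs-control", members, p, p_corr, n_tests, alpha)


@dataclass
class SelectionResult:
    criteria: dict[str, CriterionResult]
    selected: list[str]
    report: pd.DataFrame

    @property
    def n_tests(self) -> tuple[int, int, int]:
        return tuple(c.n_tests for c in self.criteria.values())


def select_relevant_rois(rs_social, rs_control, alpha: float = 0.05) -> SelectionResult:
    """Intersect the three criteria on a social vs. control score table."""
    c1 = criterion_above_average(rs_social, alpha)
    c2 = criterion_comparable_to_max(rs_social, alpha)
    c3 = criterion_social_vs_control(rs_social, rs_control, alpha)
    social = rs_social.scores if hasattr(rs_social, "scores") else rs_social
    member_sets = [set(c.members) for c in (c1, c2, c3)]
    selected = [r for r in social.columns if all(r in m for m in member_sets)]

    report = pd.DataFrame({
        "fold_mean_rs": social.mean(axis=0),
        "p1_corrected": c1.pvalues_corrected.reindex(social.columns),
        "p2_corrected": c2.pvalues_corrected.reindex(social.columns),
        "p3_corrected": c3.pvalues_corrected.reindex(social.columns),
        "criterion1": [r in member_sets[0] for r in social.columns],
        "criterion2": [r in member_sets[1] for r in social.columns],
        "criterion3": [r in member_sets[2] for r in social.columns],
    })
    report["selected"] = report[["criterion1", "criterion2", "criterion3"]].all(axis=1)
    return SelectionResult(
        criteria={"above_average": c1, "comparable_to_max": c2, "social_vs_control": c3},
        selected=selected, report=report,
    )
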