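"""Statistical layer: normality gate, ANOVA + Dunnett against the
whole-section reference, unpaired t-tests, outlier flagging and
method-validation reporting.

Region-vs-whole-section comparisons follow the convention of gating on a
Shapiro–Wilk normality test, then running one-way ANOVA with Dunnett's
multiple-comparison adjustment against the whole-section reference group.
Outliers in scalar replicate sets are flagged by a robust-z / FDR rule
(median and MAD location/scale, Benjamini–Hochberg control at Q = 1%) —
a transparent stand-in for regression-based outlier detection, applied to
scalar samples where the two coincide in spirit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateStatisticsError, InsufficientDataError

ALPHA_FIGURE = 0.01   # significance level used for region maps
ALPHA_DEFAULT = 0.05


@dataclass
class ComparisonResult:
    """One group-vs-reference comparison with adjusted p-value."""

    group_label: str
    estimate: float
    reference_label: str
    statistic: float
    p_adjusted: float
    alpha: float
    significant: bool

    def to_dict(self) -> dict:
        return {"group": self.group_label, "estimate": self.estimate,
                "reference": self.reference_label,
                "statistic": self.statistic,
                "p_adjusted": self.p_adjusted,
                "alpha": self.alpha, "significant": self.significant}


def normality_gate(sample: Sequence[float],
                   alpha: float = ALPHA_DEFAULT) -> tuple[float, float, bool]:
    """Shapiro–Wilk normality test; returns (W, p, passed).

    The gate passes (parametric tests may proceed) when p > alpha.
    Requires 3 ≤ n; the W approximation is calibrated for n ≤ 50, larger
    samples raise a warning but are still tested.
    """
    x = np.asarray(list(sample), dtype=float)
    if x.size < 3:
        raise InsufficientDataError("Shapiro–Wilk needs n >= 3")
    if x.size > 50:
        warnings.warn("Shapiro–Wilk approximation calibrated for n <= 50",
                      stacklevel=2)
    w, p = sps.shapiro(x)
    return float(w), float(p), bool(p > alpha)


def dunnett_vs_reference(groups: Sequence[Sequence[float]],
                         reference: Sequence[float],
                         labels: Sequence[str] | None = None,
                         reference_label: str = "whole_section",
                         alpha: float = ALPHA_FIGURE
                         ) -> list[ComparisonResult]:
    """Two-sided Dunnett many-to-one comparisons with pooled ANOVA error.

    Each group is compared against the reference sample; p-values carry
    the Dunnett family-wise adjustment (multivariate-t critical values).
    """
    if len(groups) < 2:
        raise InsufficientDataError("Dunnett needs >= 2 groups")
    arrs = [np.asarray(list(g), dtype=float) for g in groups]
    ref = np.asarray(list(reference), dtype=float)
    if any(a.size < 2 for a in arrs) or ref.size < 2:
        raise InsufficientDataError("each sample needs n >= 2")
    pooled_ss = sum(float(((a - a.mean()) ** 2).sum()) for a in arrs + [ref])
    if pooled_ss == 0:
        raise DegenerateStatisticsError(
            "zero pooled variance: all observations identical within groups")
    res = sps.dunnett(*arrs, control=ref, alternative="two-sided")
    labels = list(labels) if labels is not None \
        else [f"group{i + 1}" for i in range(len(arrs))]
    out = []
    for label, a, stat, p in zip(labels, arrs, res.statistic, res.pvalue):
        p = float(min(max(p, 0.0), 1.0))
        out.append(ComparisonResult(
            group_label=label, estimate=float(a.mean()),
            reference_label=reference_label, statistic=float(stat),
            p_adjusted=p, alpha=alpha, significant=bool(p < alpha)))
    return out


def ttest_unpaired(a: Sequence[float], b: Sequence[float]
                   ) -> tuple[float, float]:
    """Two-tailed pooled-variance (Student) t-test.

    Degenerate zero-variance samples use the convention t = 0, p = 1 when
    the means are equal (no evidence of a difference), p = 0 otherwise.
    """
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("t-test needs n >= 2 per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def flag_outliers(sample: Sequence[float], q: float = 0.01
                  ) -> np.ndarray:
    """Robust-z outlier flags with Benjamini–Hochberg FDR control at
    level ``q``.

    z-scores use the median and the normal-consistent MAD; two-sided
    normal p-values are screened with the BH step-up rule.  With n < 4
    (or zero MAD) nothing is flagged and a warning is issued.
    """
    x = np.asarray(list(sample), dtype=float)
    flags = np.zeros(x.size, dtype=bool)
    if x.size < 4:
        warnings.warn("outlier flagging needs n >= 4; nothing flagged",
                      stacklevel=2)
        return flags
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale == 0:
        return flags
    z = np.abs(x - med) / scale
    p = 2.0 * sps.norm.sf(z)
    order = np.argsort(p)
    n = x.size
    thresh_rank = -1
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / n:
            thresh_rank = rank
    if thresh_rank > 0:
        flags[order[:thresh_rank]] = True
    return flags


@dataclass
class ValidationReport:
    """Method-validation summary: linearity, sensitivity, accuracy and
    precision, IS response stability, QC pass rate."""

    curves: list = field(default_factory=list)        # per-curve dicts
    within_run: list = field(default_factory=list)    # per-level QC dicts
    interday: list = field(default_factory=list)
    is_response_rsd_percent: float | None = None
    is_response_flag: bool = False                    # True when RSD > limit
    qc_pass_rate: float | None = None
    qc_pass_flag: bool = False                        # True when rate < limit
    all_curves_accepted: bool = True

    def to_dict(self) -> dict:
        return {
            "curves": self.curves,
            "within_run": self.within_run,
            "interday": self.interday,
            "is_response_rsd_percent": self.is_response_rsd_percent,
            "is_response_flag": self.is_response_flag,
            "qc_pass_rate": self.qc_pass_rate,
            "qc_pass_flag": self.qc_pass_flag,
            "all_curves_accepted": self.all_curves_accepted,
        }


def validation_report(curves,
                      qc_runs: dict[float, Sequence[float]],
                      replicate_days: dict[float, Sequence[Sequence[float]]]
                      | None = None,
                      is_responses: Sequence[float] | None = None,
                      is_rsd_limit: float = 6.0,
                      qc_window_percent: float = 10.0,
                      qc_rate_limit: float = 0.90,
                      accuracy_limit: float = 15.0,
                      rsd_limit: float = 15.0) -> ValidationReport:
    """Tabulate linearity acceptance, LOD/LLOQ, within-run and interday
    accuracy/precision, IS response RSD and QC pass rate.

    ``qc_runs`` maps nominal level → measured replicates (one run);
    ``replicate_days`` maps nominal level → per-day replicate lists.
    Flags are raised when the IS response RSD exceeds ``is_rsd_limit`` %
    or fewer than ``qc_rate_limit`` of QC measurements fall within
    ±``qc_window_percent`` % of nominal.
    """
    from .quantitation import qc_evaluate

    report = ValidationReport()
    for curve in curves:
        d = curve.to_dict()
        report.curves.append(d)
        if not curve.accepted:
            report.all_curves_accepted = False

    n_in_window = n_total = 0
    for nominal, measured in qc_runs.items():
        qc = qc_evaluate(measured, nominal, accuracy_limit, rsd_limit)
        report.within_run.append({
            "nominal": nominal, "bias_percent": qc.bias_percent,
            "rsd_percent": qc.rsd_percent, "passed": qc.passed})
        vals = np.asarray(list(measured), dtype=float)
        n_total += vals.size
        n_in_window += int((np.abs(vals / nominal - 1.0)
                            <= qc_window_percent / 100.0).sum())
    if n_total:
        report.qc_pass_rate = n_in_window / n_total
        report.qc_pass_flag = report.qc_pass_rate < qc_rate_limit

    if replicate_days:
        for nominal, days in replicate_days.items():
            day_means = np.array([np.mean(list(d)) for d in days],
                                 dtype=float)
            if day_means.size < 2:
                raise InsufficientDataError(
                    "interday precision needs >= 2 days")
            grand = float(day_means.mean())
            rsd = 100.0 * float(day_means.std(ddof=1)) / grand
            bias = 100.0 * (grand - nominal) / nominal
            report.interday.append({
                "nominal": nominal, "bias_percent": bias,
                "rsd_percent": rsd,
                "passed": abs(bias) <= accuracy_limit and rsd <= rsd_limit})

    if is_responses is not None:
        vals = np.asarray(list(is_responses), dtype=float)
        if vals.size >= 2 and vals.mean() != 0:
            rsd = 100.0 * float(vals.std(ddof=1)) / float(vals.mean())
            report.is_response_rsd_percent = rsd
            report.is_response_flag = rsd > is_rsd_limit
    return report
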