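"""Classification metrics, survey-weighted prevalence and underreporting.

Classifications are scored against the self-reported physician diagnosis
with confusion-matrix metrics and rank-based AUC.  On the population level
the weighted 'probable dementia' prevalence of each algorithm is converted
into an expected case count and compared with the count implied by the
external prevalence estimate:

    underreporting = 1 - n_alg / n_ext

per country, where both counts apply a prevalence to the weighted test-set
size of that country.  Values near 0 mean the algorithm recovers the
externally projected case load; negative values mean overestimation.
Country-level values are summarised by their mean with a t-based 95%
confidence interval (countries as units).

Metrics with a zero denominator are reported as NaN (an explicit
undefined marker), never silently as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "METRIC_NAMES",
    "UnderreportingSummary",
    "auc",
    "confusion_metrics",
    "expected_cases",
    "fairness_stratify",
    "underreporting",
    "underreporting_summary",
    "underreporting_table",
    "validity_compare",
    "weighted_prevalence",
]

METRIC_NAMES = (
    "accuracy",
    "balanced_accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "f1",
)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def confusion_metrics(pred, truth) -> dict[str, float]:
    """Confusion-matrix metrics of a binary prediction against truth.

    Returns accuracy, balanced accuracy, sensitivity, specificity,
    precision and F1; ratios with an empty denominator are NaN.
    """
    p = np.asarray(pred).astype(int)
    t = np.asarray(truth).astype(int)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.sum((p == 1) & (t == 1)))
    tn = int(np.sum((p == 0) & (t == 0)))
    fp = int(np.sum((p == 1) & (t == 0)))
    fn = int(np.sum((p == 0) & (t == 1)))
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    bal = (sens + spec) / 2.0
    if math.isnan(prec) or math.isnan(sens) or prec + sens == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return {
        "accuracy": _ratio(tp + tn, len(p)),
        "balanced_accuracy": bal,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
    }


def auc(scores, truth) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted one half.

    Equals the probability that a randomly drawn case outscores a randomly
    drawn control, plus half the tie probability.  NaN when the truth
    vector contains a single class.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth).astype(int)
    if s.shape != t.shape:
        raise ValueError("scores and truth must match in length")
    n1 = int(t.sum())
    n0 = len(t) - n1
    if n1 == 0 or n0 == 0:
        return math.nan
    ranks = stats.rankdata(s)
    u = ranks[t == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def weighted_prevalence(labels, weights, by=None) -> float | pd.Series:
    """Survey-weighted prevalence sum(w*y)/sum(w), optionally per group.

    With ``by`` given (e.g. country codes) returns a Series per group;
    scale-invariant in the weights.
    """
    y = np.asarray(labels, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.shape != w.shape:
        raise ValueError("labels and weights must match in length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if by is None:
        return float(np.sum(w * y) / np.sum(w))
    df = pd.DataFrame({"y": y, "w": w, "g": np.asarray(by)})
    grouped = df.groupby("g", sort=True)
    return grouped.apply(
        lambda d: np.sum(d["w"] * d["y"]) / np.sum(d["w"]), include_groups=False
    )


def expected_cases(p: float, weights) -> float:
    """Expected case count: prevalence times the weighted set size."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"prevalence must lie in [0, 1], got {p!r}")
    return float(p * np.sum(np.asarray(weights, dtype=float)))


def underreporting(n_alg: float, n_ext: float) -> float:
    """Underreporting = 1 - n_alg/n_ext; negative means overestimation."""
    if n_ext <= 0:
        raise ValueError(f"external case count must be positive, got {n_ext!r}")
    if n_alg < 0:
        raise ValueError(f"algorithm case count must be >= 0, got {n_alg!r}")
    return 1.0 - n_alg / n_ext


@dataclass(frozen=True)
class UnderreportingSummary:
    """Cross-country mean underreporting with a t-based 95% CI."""

    algorithm: str
    records: pd.DataFrame  # per-country: country_code, n_alg, n_ext, underreporting
    mean: float
    ci95_low: float
    ci95_high: float


def underreporting_table(
    labels, weights, country_codes, p_ext: dict[str, float]
) -> pd.DataFrame:
    """Per-country underreporting records for one algorithm's labels.

    For each country the algorithm's weighted prevalence and the external
    prevalence are both applied to the weighted country size, giving the
    expected counts whose ratio defines underreporting.
    """
    codes = np.asarray(country_codes)
    y = np.asarray(labels, dtype=float)
    w = np.asarray(weights, dtype=float)
    rows = []
    for code in sorted(np.unique(codes)):
        if code not in p_ext:
            raise KeyError(f"country {code!r} missing from the reference table")
        m = codes == code
        prev_alg = weighted_prevalence(y[m], w[m])
        n_alg = expected_cases(prev_alg, w[m])
        n_ext = expected_cases(p_ext[code], w[m])
        rows.append(
            {
                "country_code": code,
                "prevalence_alg": prev_alg,
                "prevalence_ext": p_ext[code],
                "n_alg": n_alg,
                "n_ext": n_ext,
                "underreporting": underreporting(n_alg, n_ext),
            }
        )
    return pd.DataFrame(rows)


def underreporting_summary(
    records: pd.DataFrame, algorithm: str = ""
) -> UnderreportingSummary:
    """Mean underreporting across countries with a 95% t-interval.

    Countries are the units: CI = mean +/- t(0.975, k-1) * sd / sqrt(k)
    over the k country values.  With a single country the CI is undefined.
    """
    vals = records["underreporting"].to_numpy(dtype=float)
    k = len(vals)
    if k == 0:
        raise ValueError("no country records to summarise")
    mean = float(np.mean(vals))
    if k == 1:
        return UnderreportingSummary(algorithm, records, mean, math.nan, math.nan)
    half = float(stats.t.ppf(0.975, k - 1) * np.std(vals, ddof=1) / math.sqrt(k))
    return UnderreportingSummary(algorithm, records, mean, mean - half, mean + half)


def fairness_stratify(
    pred, truth, country_codes, scores=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-country metrics plus a cross-country dispersion summary.

    Countries lacking one of the truth classes keep their row with NaN
    for the undefined metrics.  The dispersion table reports min, max,
    range and sd per metric, skipping undefined values.
    """
    p = np.asarray(pred).astype(int)
    t = np.asarray(truth).astype(int)
    codes = np.asarray(country_codes)
    s = None if scores is None else np.asarray(scores, dtype=float)
    rows = []
    for code in sorted(np.unique(codes)):
        m = codes == code
        row = {"country_code": code, "n": int(m.sum())}
        row.update(confusion_metrics(p[m], t[m]))
        row["auc"] = auc(s[m], t[m]) if s is not None else math.nan
        rows.append(row)
    per_country = pd.DataFrame(rows)

    disp_rows = []
    for metric in list(METRIC_NAMES) + ["auc"]:
        vals = per_country[metric].dropna()
        disp_rows.append(
            {
                "metric": metric,
                "n_defined": int(len(vals)),
                "min": vals.min() if len(vals) else math.nan,
                "max": vals.max() if len(vals) else math.nan,
                "range": (vals.max() - vals.min()) if len(vals) else math.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else math.nan,
            }
        )
    return per_country, pd.DataFrame(disp_rows)


def _mean_ci(x: np.ndarray) -> tuple[float, float, float]:
    mean = float(np.mean(x))
    if len(x) < 2:
        return mean, math.nan, math.nan
    half = float(stats.t.ppf(0.975, len(x) - 1) * np.std(x, ddof=1) / math.sqrt(len(x)))
    return mean, mean - half, mean + half


def validity_compare(
    cohort: pd.DataFrame,
    labels_by_algorithm: dict[str, pd.Series],
    domains: tuple[str, ...] = (
        "dep_symptoms",
        "verbal_fluency",
        "numeracy",
        "grip_strength",
        "orientation",
    ),
    self_report_col: str = "self_report_dx",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Compare auxiliary health/cognition domains between each algorithm's
    'probable dementia' group and the self-reported-diagnosis group.

    One Welch t-test (Student's pooled-variance behind ``equal_var=True``)
    per algorithm x domain on complete cases; p-values are
    Bonferroni-adjusted with the family size m = number of tests in this
    run.  Rows report both group means with 95% CIs and sizes; groups
    smaller than 2 yield NaN statistics.
    """
    m_tests = len(labels_by_algorithm) * len(domains)
    sr_mask = cohort[self_report_col].to_numpy() == 1
    rows = []
    for alg, labels in labels_by_algorithm.items():
        alg_mask = labels.reindex(cohort.index).to_numpy() == 1
        for domain in domains:
            if domain not in cohort.columns:
                raise KeyError(f"domain column {domain!r} missing from cohort")
            vals = cohort[domain].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            a = vals[alg_mask & ok]
            b = vals[sr_mask & ok]
            mean_a, lo_a, hi_a = _mean_ci(a) if len(a) else (math.nan,) * 3
            mean_b, lo_b, hi_b = _mean_ci(b) if len(b) else (math.nan,) * 3
            if len(a) >= 2 and len(b) >= 2:
                tstat, pval = stats.ttest_ind(a, b, equal_var=equal_var)
                p_adj = min(1.0, m_tests * float(pval))
            else:
                tstat, pval, p_adj = math.nan, math.nan, math.nan
            rows.append(
                {
                    "algorithm": alg,
                    "domain": domain,
                    "n_alg": int(len(a)),
                    "n_self_report": int(len(b)),
                    "mean_alg": mean_a,
                    "ci_low_alg": lo_a,
                    "ci_high_alg": hi_a,
                    "mean_self_report": mean_b,
                    "ci_low_self_report": lo_b,
                    "ci_high_self_report": hi_b,
                    "t_stat": float(tstat) if not math.isnan(float(tstat)) else math.nan,
                    "p_value": float(pval) if not math.isnan(float(pval)) else math.nan,
                    "p_bonferroni": p_adj,
                }
            )
    return pd.DataFrame(rows)
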