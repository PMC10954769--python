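"""Adapted Langa-Weir 'probable dementia' classification.

The classifier scores each respondent by the 10-word recall sum
(immediate 0-10 plus delayed 0-10, range 0-20) and labels 'probable
dementia' when the sum falls strictly below a country-specific cutoff.
Two cutoff rules are supported:

* prevalence-based (equipercentile equating): the cutoff is chosen so that
  the weighted share of the training distribution strictly below it does
  not exceed the country's external dementia prevalence;
* percentile-based: the same construction with a fixed target (default the
  2.5th percentile, an outlier definition of two standard deviations below
  the mean for a normal score).

The combined variants additionally require the IADL limitation count to lie
strictly above a country-specific outlier cutoff, Q3 + 1.5*IQR of the
training IADL distribution (set to 1 where Q3 = 0).  Four variants result:

===========  ==========================  ==============
variant       recall cutoff               IADL condition
===========  ==========================  ==============
``R``         2.5th percentile            no
``RP``        external prevalence         no
``RI``        2.5th percentile            yes
``RIP``       external prevalence         yes
===========  ==========================  ==============

All cutoffs are fitted on training data only; classification never reads
the self-reported diagnosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from probdem.simulate import CountryReference

__all__ = [
    "VARIANTS",
    "CutoffSet",
    "classify",
    "classify_all",
    "fit_cutoffs",
    "fit_iadl_cutoff",
    "fit_percentile_cutoff",
    "fit_prevalence_cutoff",
    "recall_sum",
]

logger = logging.getLogger(__name__)

#: Classification variants: R = recall/percentile cutoff, RP = recall/
#: prevalence cutoff, RI/RIP = the same with the IADL conjunction.
VARIANTS = ("R", "RP", "RI", "RIP")

MAX_RECALL_SUM = 20


@dataclass(frozen=True)
class CutoffSet:
    """Fitted country-specific cutoffs — the 'model' of the adaptation.

    ``recall_cutoff_prev`` equates the classified share to the external
    prevalence ``target_prevalence``; ``recall_cutoff_pct`` uses the fixed
    percentile; ``iadl_cutoff`` is shared by both combined variants.
    """

    country_code: str
    recall_cutoff_prev: int
    recall_cutoff_pct: int
    iadl_cutoff: float
    target_prevalence: float
    percentile: float = 2.5
    fitted_on: str = ""

    def __post_init__(self) -> None:
        for name in ("recall_cutoff_prev", "recall_cutoff_pct"):
            v = getattr(self, name)
            if not (0 <= v <= MAX_RECALL_SUM + 1):
                raise ValueError(f"{name}={v!r} outside the recall score range")


def recall_sum(recall_immediate, recall_delayed):
    """Sum of immediate and delayed 10-word recall, range 0-20.

    Accepts scalars or array-likes; validates the 0-10 item ranges.
    """
    imm = np.asarray(recall_immediate)
    dly = np.asarray(recall_delayed)
    for name, a in (("recall_immediate", imm), ("recall_delayed", dly)):
        if np.any((a < 0) | (a > 10)):
            raise ValueError(f"{name} outside the 0-10 item range")
    out = imm + dly
    return out.item() if np.isscalar(recall_immediate) else out


def fit_prevalence_cutoff(scores, weights=None, target: float = 0.025) -> int:
    """Equipercentile cutoff: the largest integer ``c`` such that the
    weighted share of scores strictly below ``c`` does not exceed ``target``.

    Classification uses the strict rule score < c, so the classified share
    never exceeds the target, and raising the cutoff by one would (unless
    ``c`` is already past the score maximum) push the share above it.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("cannot fit a cutoff on an empty score vector")
    if not (0.0 <= target < 1.0):
        raise ValueError(f"target must lie in [0, 1), got {target!r}")
    if weights is None:
        w = np.ones_like(s)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != s.shape:
            raise ValueError("weights must match scores in length")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")

    total = w.sum()
    best = 0
    for c in range(0, MAX_RECALL_SUM + 2):
        share = w[s < c].sum() / total
        if share <= target:
            best = c
        else:
            break
    if best <= s.min():
        logger.warning(
            "cutoff %d classifies no respondent (floor effect): the score "
            "distribution has no mass below the target share %.4f", best, target
        )
    return int(best)


def fit_percentile_cutoff(scores, weights=None, q: float = 2.5) -> int:
    """Percentile recall cutoff; identical contract with ``target = q/100``."""
    if not (0.0 <= q < 100.0):
        raise ValueError(f"percentile q must lie in [0, 100), got {q!r}")
    return fit_prevalence_cutoff(scores, weights, target=q / 100.0)


def fit_iadl_cutoff(iadl_counts) -> float:
    """IQR outlier cutoff for the IADL count: Q3 + 1.5*(Q3 - Q1).

    Quartiles use linear interpolation of the empirical distribution,
    unweighted.  Where Q3 = 0 (most respondents report no limitation) the
    cutoff is set to 1 so that the rule still requires at least two
    limitations under the strict 'above' comparison.
    """
    counts = np.asarray(iadl_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("cannot fit an IADL cutoff on an empty vector")
    q1, q3 = np.percentile(counts, [25.0, 75.0])
    if q3 == 0.0:
        return 1.0
    return float(q3 + 1.5 * (q3 - q1))


def fit_cutoffs(
    train: pd.DataFrame,
    ref: list[CountryReference],
    q: float = 2.5,
    weighted: bool = True,
    fitted_on: str = "",
) -> dict[str, CutoffSet]:
    """Fit one :class:`CutoffSet` per training country.

    The prevalence-based recall cutoff equates to that country's ``p_ext``;
    the percentile cutoff uses ``q``; the IADL cutoff is fitted once per
    country and shared by both combined variants.  Recall cutoffs use the
    sampling weights by default (the equating target is population-level);
    the IADL quartiles are unweighted.
    """
    p_ext = {r.country_code: r.p_ext for r in ref}
    out: dict[str, CutoffSet] = {}
    for code, grp in train.groupby("country_code", sort=True):
        if code not in p_ext:
            raise KeyError(f"country {code!r} missing from the reference table")
        scores = recall_sum(
            grp["recall_immediate"].to_numpy(), grp["recall_delayed"].to_numpy()
        )
        w = grp["samp_weight"].to_numpy() if weighted else None
        out[code] = CutoffSet(
            country_code=code,
            recall_cutoff_prev=fit_prevalence_cutoff(scores, w, target=p_ext[code]),
            recall_cutoff_pct=fit_percentile_cutoff(scores, w, q=q),
            iadl_cutoff=fit_iadl_cutoff(grp["iadl_count"].to_numpy()),
            target_prevalence=p_ext[code],
            percentile=q,
            fitted_on=fitted_on,
        )
    return out


def classify(
    cohort: pd.DataFrame, cutoffs: dict[str, CutoffSet], variant: str
) -> pd.Series:
    """Label 'probable dementia' (1) / not (0) under one variant.

    R/RP: recall sum strictly below the respective recall cutoff.
    RI/RIP: additionally the IADL count strictly above the IADL cutoff.
    Pure function of the observed cognition/IADL columns and the cutoffs.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    missing = sorted(set(cohort["country_code"]) - set(cutoffs))
    if missing:
        raise KeyError(f"no fitted cutoffs for countries: {missing}")

    codes = cohort["country_code"].to_numpy()
    score = recall_sum(
        cohort["recall_immediate"].to_numpy(), cohort["recall_delayed"].to_numpy()
    )
    attr = "recall_cutoff_prev" if variant in ("RP", "RIP") else "recall_cutoff_pct"
    rc = np.array([getattr(cutoffs[c], attr) for c in codes])
    positive = score < rc
    if variant in ("RI", "RIP"):
        ic = np.array([cutoffs[c].iadl_cutoff for c in codes])
        positive &= cohort["iadl_count"].to_numpy() > ic
    return pd.Series(positive.astype(int), index=cohort.index, name=f"lw_{variant}")


def classify_all(cohort: pd.DataFrame, cutoffs: dict[str, CutoffSet]) -> pd.DataFrame:
    """All four variant labels as columns ``lw_R`` ... ``lw_RIP``."""
    return pd.DataFrame(
        {f"lw_{v}": classify(cohort, cutoffs, v) for v in VARIANTS}, index=cohort.index
    )
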