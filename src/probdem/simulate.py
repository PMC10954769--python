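"""Synthetic multi-country survey cohorts with known latent dementia status.

Restricted-access survey microdata (SHARE-style) cannot be redistributed, so
the pipeline is exercised on simulated cohorts in which every quantity the
downstream stages estimate — per-country dementia prevalence, the
diagnosis-reporting rate, the recall deficit under dementia — is a known
generator parameter.

Generating model, per country ``c`` with external prevalence ``p_ext(c)``:

* latent dementia is Bernoulli with an age-tilted individual probability
  (logistic in standardised age) renormalised so the country marginal equals
  ``p_ext(c)``;
* a self-reported physician diagnosis is a thinning of true cases:
  ``self_report_dx = true_dementia * Bernoulli(r_c)`` with reporting rate
  ``r_c`` — never a false positive;
* immediate and delayed 10-word recall are sums of 10 Bernoulli trials whose
  logit success probability contains a country-level shift and a negative
  dementia effect;
* the IADL limitation count is zero-inflated Poisson, truncated to [0, 9],
  with dementia and age effects on both the zero probability and the rate;
* auxiliary validity markers (depressive symptoms, verbal fluency, numeracy,
  grip strength, orientation to date) are shifted under dementia;
* sampling weights are population-proportional: ``pop_weight_total / n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "AuxEffects",
    "CountryReference",
    "IadlParams",
    "SimConfig",
    "REQUIRED_COLUMNS",
    "LATENT_COLUMNS",
    "apply_eligibility",
    "generate_cohort",
    "generate_reference",
    "split_train_test",
]

#: Observed survey variables every cohort must carry.
REQUIRED_COLUMNS = (
    "country_code",
    "age",
    "sex",
    "education",
    "recall_immediate",
    "recall_delayed",
    "iadl_count",
    "self_report_dx",
    "reading_assistance",
    "willingness",
    "clarification",
    "proxy_present",
    "samp_weight",
)

#: Ground-truth and validity-marker columns present only in synthetic data.
LATENT_COLUMNS = (
    "true_dementia",
    "dep_symptoms",
    "verbal_fluency",
    "numeracy",
    "grip_strength",
    "orientation",
)

SEX_LEVELS = ("male", "female")
EDUCATION_LEVELS = ("lower secondary", "upper secondary", "tertiary")
WILLINGNESS_LEVELS = ("good", "bad")
PROXY_LEVELS = ("none", "partner", "relative", "helper/other")

# Pool of ISO-3166 alpha-2 codes for European-style multi-country cohorts.
_COUNTRY_POOL = (
    "AT BE BG CH CY CZ DE DK EE ES FI FR GR HR HU IE IL IT "
    "LT LU LV MT NL PL PT RO SE SI SK NO UK"
).split()


class ConfigError(ValueError):
    """Invalid simulation or study configuration."""


class NoEligibleDataError(RuntimeError):
    """Eligibility filtering removed every respondent."""


@dataclass(frozen=True)
class CountryReference:
    """External dementia prevalence for one country.

    Parameters
    ----------
    country_code : str
        ISO-3166 alpha-2 code.
    p_ext : float
        External (projected) dementia prevalence among the 60+ population,
        a proportion strictly between 0 and 1.  This is both the generating
        prevalence of the synthetic cohort and the equating target of the
        prevalence-based recall cutoff.
    pop_weight_total : float
        Relative population size of the country's 60+ population; the
        per-respondent sampling weight is ``pop_weight_total / n``.
    """

    country_code: str
    p_ext: float
    pop_weight_total: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_ext < 1.0):
            raise ConfigError(
                f"p_ext must lie in (0, 1), got {self.p_ext!r} "
                f"for {self.country_code!r}"
            )
        if self.pop_weight_total <= 0:
            raise ConfigError(
                f"pop_weight_total must be positive, got {self.pop_weight_total!r}"
            )


@dataclass(frozen=True)
class IadlParams:
    """Zero-inflated Poisson parameters for the IADL limitation count.

    ``zero_prob`` is the structural-zero probability for participants
    without dementia and ``zero_prob_dementia`` the (much lower) one under
    dementia: loss of independent function is near-definitional for
    dementia, so almost all true cases report at least one limitation.
    The Poisson rate is ``exp(log_rate + log_rate_dementia * D +
    log_rate_age * z)`` with ``z = (age - 70) / 10``; counts are truncated
    to the 0-9 instrument range.
    """

    zero_prob: float = 0.70
    zero_prob_dementia: float = 0.10
    log_rate: float = 0.20
    log_rate_dementia: float = 1.50
    log_rate_age: float = 0.25

    def __post_init__(self) -> None:
        for name in ("zero_prob", "zero_prob_dementia"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")


@dataclass(frozen=True)
class AuxEffects:
    """Mean shifts of the auxiliary validity markers under dementia.

    Units are the marker's own scale: EURO-D depressive symptoms (0-12),
    animal verbal fluency (words/min), numeracy score (0-5), maximum grip
    strength (kg) and orientation to date (0-4).  Signs follow the
    epidemiological literature: more depressive symptoms, lower fluency,
    numeracy, grip and orientation under dementia.
    """

    dep_symptoms: float = 2.0
    verbal_fluency: float = -6.0
    numeracy: float = -1.0
    grip_strength: float = -6.0
    orientation: float = -1.2


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a synthetic multi-country cohort.

    Parameters
    ----------
    countries : list of CountryReference
        Countries to simulate, with their generating prevalences.
    n_per_country : int
        Respondents per country.
    reporting_rate : float or dict
        Probability that a true dementia case self-reports a physician
        diagnosis (``r_c``); a single float applies to all countries, a
        dict maps country codes to rates.  The default 0.4 corresponds to
        roughly 60% underreporting, the order observed when European
        survey self-reports are compared with OECD projections.
    recall_effect : float
        Shift (logit scale, negative) of the per-word recall success
        probability under dementia.  The default -2.0 produces a severe
        memory deficit: mean recall sums of roughly 2/20 words for cases
        against 8.5/20 for non-cases.
    country_shift : dict or None
        Per-country recall shift on the logit scale; ``None`` draws shifts
        from N(0, country_shift_sd) so that cutoffs genuinely differ by
        country.
    country_shift_sd : float
        Spread of drawn country shifts.
    """

    countries: list[CountryReference]
    n_per_country: int = 1000
    reporting_rate: float | dict[str, float] = 0.4
    recall_effect: float = -2.0
    country_shift: dict[str, float] | None = None
    country_shift_sd: float = 0.15
    iadl_params: IadlParams = field(default_factory=IadlParams)
    aux_effects: AuxEffects = field(default_factory=AuxEffects)
    age_range: tuple[float, float] = (60.0, 100.0)
    age_tilt: float = 1.0
    recall_base_immediate: float = 0.0
    recall_base_delayed: float = -0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.countries:
            raise ConfigError("at least one country is required")
        codes = [c.country_code for c in self.countries]
        if len(set(codes)) != len(codes):
            raise ConfigError("country codes must be unique")
        if self.n_per_country < 1:
            raise ConfigError("n_per_country must be >= 1")
        for code in codes:
            r = self.rate_for(code)
            if not (0.0 <= r <= 1.0):
                raise ConfigError(f"reporting rate for {code!r} must lie in [0, 1]")
        lo, hi = self.age_range
        if not (0 < lo < hi):
            raise ConfigError(f"invalid age_range {self.age_range!r}")

    def rate_for(self, country_code: str) -> float:
        """Reporting rate ``r_c`` for one country."""
        if isinstance(self.reporting_rate, dict):
            try:
                return self.reporting_rate[country_code]
            except KeyError:
                raise ConfigError(
                    f"no reporting rate configured for country {country_code!r}"
                ) from None
        return float(self.reporting_rate)


def generate_reference(
    n_countries: int,
    prevalence_range: tuple[float, float] = (0.03, 0.08),
    seed: int = 0,
) -> list[CountryReference]:
    """Draw a table of countries with external prevalence estimates.

    Prevalences are uniform over ``prevalence_range`` (the default spans
    typical projected dementia prevalences among the 60+ population of
    European countries) and relative population sizes are log-normal.
    Deterministic under ``seed``.
    """
    if n_countries < 1:
        raise ConfigError("n_countries must be >= 1")
    low, high = prevalence_range
    if not (0.0 < low <= high < 1.0):
        raise ConfigError(f"invalid prevalence range {prevalence_range!r}")
    rng = np.random.default_rng(seed)
    codes = list(_COUNTRY_POOL[:n_countries])
    # Synthesise extra two-letter codes if the pool is exhausted.
    i = 0
    while len(codes) < n_countries:
        code = f"{chr(ord('A') + i // 26)}{chr(ord('A') + i % 26)}"
        if code not in codes:
            codes.append(code)
        i += 1
    p_ext = rng.uniform(low, high, size=n_countries)
    pop = np.exp(rng.normal(0.0, 0.5, size=n_countries))
    return [
        CountryReference(code, float(p), float(w))
        for code, p, w in zip(codes, p_ext, pop)
    ]


def _age_tilted_risk(z: np.ndarray, beta: float, p_target: float) -> np.ndarray:
    """Individual dementia probabilities expit(a + beta z) with mean p_target.

    Solves for the intercept ``a`` so the country marginal prevalence equals
    the equating target exactly in expectation.
    """
    if beta == 0.0:
        return np.full_like(z, p_target, dtype=float)

    def marginal(a: float) -> float:
        return float(np.mean(expit(a + beta * z))) - p_target

    base = logit(p_target)
    lo, hi = base - 20.0, base + 20.0
    a = brentq(marginal, lo, hi, xtol=1e-12)
    return expit(a + beta * z)


def _truncated_ages(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """Right-skewed ages on [lo, hi]; Beta(1.5, 3.5) rescaled, mean ~72."""
    return lo + (hi - lo) * rng.beta(1.5, 3.5, size=n)


def _generate_country(
    rng: np.random.Generator, cfg: SimConfig, ref: CountryReference, shift: float
) -> pd.DataFrame:
    n = cfg.n_per_country
    lo, hi = cfg.age_range
    age = _truncated_ages(rng, n, lo, hi)
    z = (age - 70.0) / 10.0

    risk = _age_tilted_risk(z, cfg.age_tilt, ref.p_ext)
    dementia = rng.random(n) < risk
    reported = dementia & (rng.random(n) < cfg.rate_for(ref.country_code))

    sex = np.where(rng.random(n) < 0.563, "female", "male")
    education = rng.choice(EDUCATION_LEVELS, size=n, p=[0.40, 0.34, 0.26])

    d = dementia.astype(float)
    p_imm = expit(cfg.recall_base_immediate + shift + cfg.recall_effect * d)
    p_del = expit(cfg.recall_base_delayed + shift + cfg.recall_effect * d)
    recall_imm = rng.binomial(10, p_imm)
    recall_del = rng.binomial(10, p_del)

    ip = cfg.iadl_params
    zero_prob = np.where(dementia, ip.zero_prob_dementia, ip.zero_prob)
    rate = np.exp(ip.log_rate + ip.log_rate_dementia * d + ip.log_rate_age * z)
    iadl = np.minimum(rng.poisson(rate), 9)
    iadl[rng.random(n) < zero_prob] = 0

    # Interviewer-rated items; mildly informative about dementia.
    reading = (rng.random(n) < expit(-3.5 + 2.0 * d)).astype(int)
    willing = np.where(rng.random(n) < expit(-3.0 + 1.5 * d), "bad", "good")
    clarification = 1 + rng.binomial(5, expit(-1.5 + 1.0 * d))
    proxy_p = np.where(
        dementia[:, None],
        np.array([0.80, 0.10, 0.07, 0.03]),
        np.array([0.96, 0.02, 0.01, 0.01]),
    )
    proxy_idx = (rng.random(n)[:, None] > np.cumsum(proxy_p, axis=1)).sum(axis=1)
    proxy = np.asarray(PROXY_LEVELS)[proxy_idx]

    ax = cfg.aux_effects
    dep = np.clip(np.rint(rng.normal(2.5 + ax.dep_symptoms * d, 2.2)), 0, 12)
    fluency = np.clip(np.rint(rng.normal(20.0 + ax.verbal_fluency * d, 6.0)), 0, None)
    numeracy = np.clip(np.rint(rng.normal(3.5 + ax.numeracy * d, 1.2)), 0, 5)
    grip = np.maximum(rng.normal(35.0 + ax.grip_strength * d - 2.0 * z, 9.0), 1.0)
    orientation = np.clip(np.rint(rng.normal(3.7 + ax.orientation * d, 0.7)), 0, 4)

    return pd.DataFrame(
        {
            "country_code": ref.country_code,
            "age": np.round(age, 1),
            "sex": sex,
            "education": education,
            "recall_immediate": recall_imm,
            "recall_delayed": recall_del,
            "iadl_count": iadl,
            "self_report_dx": reported.astype(int),
            "reading_assistance": reading,
            "willingness": willing,
            "clarification": clarification,
            "proxy_present": proxy,
            "samp_weight": ref.pop_weight_total / n,
            "true_dementia": dementia.astype(int),
            "dep_symptoms": dep.astype(int),
            "verbal_fluency": fluency.astype(int),
            "numeracy": numeracy.astype(int),
            "grip_strength": np.round(grip, 1),
            "orientation": orientation.astype(int),
        }
    )


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Simulate a multi-country cohort under ``config``.

    Returns one row per respondent with the observed survey variables of
    :data:`REQUIRED_COLUMNS` plus the latent columns of
    :data:`LATENT_COLUMNS`.  Byte-identical output under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    if config.country_shift is None:
        shifts = {
            c.country_code: float(s)
            for c, s in zip(
                config.countries,
                rng.normal(0.0, config.country_shift_sd, size=len(config.countries)),
            )
        }
    else:
        shifts = {c.country_code: config.country_shift.get(c.country_code, 0.0)
                  for c in config.countries}
    frames = [
        _generate_country(rng, config, ref, shifts[ref.country_code])
        for ref in config.countries
    ]
    cohort = pd.concat(frames, ignore_index=True)
    cohort.index.name = "respondent_id"
    return cohort


def apply_eligibility(
    cohort: pd.DataFrame,
    min_cases: int = 5,
    min_age: float = 60.0,
    required_columns: tuple[str, ...] = REQUIRED_COLUMNS,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the study eligibility rules and return (table, exclusion log).

    Respondents below ``min_age`` or with any missing required field are
    dropped first; then whole countries with fewer than ``min_cases``
    self-reported diagnoses among the remaining respondents are removed.
    The log counts exclusions per reason.
    """
    missing_cols = [c for c in required_columns if c not in cohort.columns]
    if missing_cols:
        raise KeyError(f"cohort lacks required columns: {missing_cols}")

    log: dict[str, int] = {}
    n0 = len(cohort)
    kept = cohort[cohort["age"] >= min_age]
    log["below_min_age"] = n0 - len(kept)

    n1 = len(kept)
    kept = kept.dropna(subset=list(required_columns))
    log["missing_data"] = n1 - len(kept)

    cases = kept.groupby("country_code", sort=False)["self_report_dx"].sum()
    low_countries = cases[cases < min_cases].index
    n2 = len(kept)
    kept = kept[~kept["country_code"].isin(low_countries)]
    log["country_below_min_cases"] = n2 - len(kept)
    log["countries_removed"] = len(low_countries)
    log["eligible"] = len(kept)

    if kept.empty:
        raise NoEligibleDataError(
            "no eligible data after applying age/missingness/min-case filters"
        )
    return kept, log


def split_train_test(
    cohort: pd.DataFrame,
    fraction: float = 0.5,
    seed: int = 0,
    stratify_by_country: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/test partition (train receives ``fraction`` of rows).

    The parts are disjoint and exhaustive; at the default 50:50 their sizes
    differ by at most one.  Simple random by default; country-stratified
    splitting is available behind the flag.
    """
    if cohort.empty:
        raise ValueError("cannot split an empty cohort")
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction!r}")
    rng = np.random.default_rng(seed)
    if stratify_by_country:
        train_idx = []
        for _, grp in cohort.groupby("country_code", sort=True):
            perm = grp.index.to_numpy()[rng.permutation(len(grp))]
            train_idx.extend(perm[: int(np.floor(len(grp) * fraction))])
        train_mask = cohort.index.isin(train_idx)
    else:
        perm = rng.permutation(len(cohort))
        n_train = int(np.floor(len(cohort) * fraction))
        train_mask = np.zeros(len(cohort), dtype=bool)
        train_mask[perm[:n_train]] = True
    return cohort[train_mask], cohort[~train_mask]
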