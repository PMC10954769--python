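"""CSV/YAML input-output with schema validation.

Cohorts and country reference tables round-trip through plain CSV (empty
cells encode missing values); fitted cutoff sets round-trip through CSV
with ``# key=value`` metadata header lines recording the method, quantile
convention and training-set hash.  Simulation and study configurations
load from YAML.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from probdem.langa_weir import CutoffSet
from probdem.simulate import (
    LATENT_COLUMNS,
    REQUIRED_COLUMNS,
    AuxEffects,
    CountryReference,
    IadlParams,
    SimConfig,
)

__all__ = [
    "load_sim_config",
    "read_cohort_csv",
    "read_cutoffs_csv",
    "read_reference_csv",
    "write_cohort_csv",
    "write_cutoffs_csv",
    "write_reference_csv",
]

logger = logging.getLogger(__name__)

# (column, low, high) inclusive range checks applied at load.
_RANGE_CHECKS = (
    ("recall_immediate", 0, 10),
    ("recall_delayed", 0, 10),
    ("iadl_count", 0, 9),
    ("self_report_dx", 0, 1),
    ("reading_assistance", 0, 1),
    ("clarification", 1, 6),
)


class SchemaError(ValueError):
    """A loaded table violates the cohort schema."""


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Load a respondent-level cohort CSV with schema validation.

    Missing required columns raise; unknown columns are kept with a
    warning; out-of-range values are reported with their (1-based data)
    row numbers.  Empty cells become missing values.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    known = set(REQUIRED_COLUMNS) | set(LATENT_COLUMNS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("%s: ignoring unknown columns %s", path.name, unknown)

    problems: list[str] = []
    for col, lo, hi in _RANGE_CHECKS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[(vals < lo) | (vals > hi)]
        for i in bad[:5]:
            problems.append(f"row {i + 1}: {col}={df.at[i, col]!r} outside [{lo}, {hi}]")
        if len(bad) > 5:
            problems.append(f"... and {len(bad) - 5} more {col} violations")
    w = pd.to_numeric(df["samp_weight"], errors="coerce")
    bad_w = df.index[w <= 0]
    for i in bad_w[:5]:
        problems.append(f"row {i + 1}: samp_weight={df.at[i, 'samp_weight']!r} not positive")
    if problems:
        raise SchemaError(f"{path.name}: schema violations:\n" + "\n".join(problems))
    df.index.name = "respondent_id"
    return df


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table; missing values become empty cells."""
    cohort.to_csv(path, index=False, na_rep="")


def read_reference_csv(path: str | Path) -> list[CountryReference]:
    """Load a country reference table (country_code, p_ext, pop_weight_total)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    needed = {"country_code", "p_ext"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"{Path(path).name}: missing columns {sorted(missing)}")
    if df["country_code"].duplicated().any():
        dupes = sorted(df["country_code"][df["country_code"].duplicated()])
        raise SchemaError(f"duplicate country codes {dupes}")
    if "pop_weight_total" not in df.columns:
        df["pop_weight_total"] = 1.0
    return [
        CountryReference(str(r.country_code), float(r.p_ext), float(r.pop_weight_total))
        for r in df.itertuples()
    ]


def write_reference_csv(ref: list[CountryReference], path: str | Path) -> None:
    pd.DataFrame(
        {
            "country_code": [r.country_code for r in ref],
            "p_ext": [r.p_ext for r in ref],
            "pop_weight_total": [r.pop_weight_total for r in ref],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def table_hash(df: pd.DataFrame) -> str:
    """Short content hash of a table, for provenance metadata."""
    return hashlib.sha256(
        df.to_csv(index=False).encode("utf-8")
    ).hexdigest()[:16]


def write_cutoffs_csv(
    cutoffs: dict[str, CutoffSet], path: str | Path, metadata: dict | None = None
) -> None:
    """Write fitted cutoffs, one row per country, after metadata headers.

    Metadata is stored as ``# key=value`` comment lines (method, quantile
    convention, training-set hash ...) so the file remains a valid CSV.
    """
    meta = {
        "method": "langa-weir-adapted",
        "recall_rule": "score strictly below cutoff",
        "iadl_rule": "count strictly above Q3+1.5*IQR (1 if Q3=0)",
        "quantile_convention": "linear interpolation, unweighted IADL quartiles",
        **(metadata or {}),
    }
    rows = pd.DataFrame([vars(c) for c in cutoffs.values()]).sort_values("country_code")
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        # 17 significant digits so fitted values round-trip exactly
        rows.to_csv(fh, index=False, float_format="%.17g")


def read_cutoffs_csv(path: str | Path) -> tuple[dict[str, CutoffSet], dict[str, str]]:
    """Read cutoffs and their metadata back from CSV."""
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    cutoffs = {
        str(r.country_code): CutoffSet(
            country_code=str(r.country_code),
            recall_cutoff_prev=int(r.recall_cutoff_prev),
            recall_cutoff_pct=int(r.recall_cutoff_pct),
            iadl_cutoff=float(r.iadl_cutoff),
            target_prevalence=float(r.target_prevalence),
            percentile=float(r.percentile),
            fitted_on=str(r.fitted_on) if not pd.isna(r.fitted_on) else "",
        )
        for r in df.itertuples()
    }
    return cutoffs, meta


def load_sim_config(path: str | Path) -> SimConfig:
    """Build a :class:`SimConfig` from YAML.

    Countries come either from an explicit ``countries`` list of
    ``{country_code, p_ext, pop_weight_total}`` mappings or from a
    ``generate_countries: {n_countries, prevalence_range, seed}`` block.
    Remaining keys map directly onto SimConfig fields; ``iadl_params``
    and ``aux_effects`` are nested mappings.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return sim_config_from_dict(raw)


def sim_config_from_dict(raw: dict) -> SimConfig:
    from probdem.simulate import generate_reference  # cycle-free local import

    raw = dict(raw)
    if "countries" in raw:
        raw["countries"] = [
            CountryReference(
                str(c["country_code"]),
                float(c["p_ext"]),
                float(c.get("pop_weight_total", 1.0)),
            )
            for c in raw["countries"]
        ]
    elif "generate_countries" in raw:
        g = raw.pop("generate_countries")
        raw["countries"] = generate_reference(
            int(g["n_countries"]),
            tuple(g.get("prevalence_range", (0.03, 0.08))),
            int(g.get("seed", raw.get("seed", 0))),
        )
    else:
        raise SchemaError("config needs 'countries' or 'generate_countries'")
    if "iadl_params" in raw:
        raw["iadl_params"] = IadlParams(**raw["iadl_params"])
    if "aux_effects" in raw:
        raw["aux_effects"] = AuxEffects(**raw["aux_effects"])
    if "age_range" in raw:
        raw["age_range"] = tuple(raw["age_range"])
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown simulation config keys {sorted(unknown)}")
    return SimConfig(**raw)
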