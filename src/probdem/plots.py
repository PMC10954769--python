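"""Optional diagnostic plots (requires matplotlib).

Three views of a study report: the sensitivity-specificity scatter per
algorithm, the per-country prevalence comparison against the external
estimates, and the mean-underreporting dot plot with 95% CIs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_sensitivity_specificity(metrics: pd.DataFrame, path: str | Path) -> None:
    """Sensitivity (x) against specificity (y), one point per algorithm."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 5))
    for _, row in metrics.iterrows():
        ax.scatter(row["sensitivity"], row["specificity"], s=30)
        ax.annotate(row["algorithm"], (row["sensitivity"], row["specificity"]),
                    fontsize=8, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("sensitivity")
    ax.set_ylabel("specificity")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_prevalence_scatter(records: pd.DataFrame, path: str | Path) -> None:
    """Algorithm prevalence (y) against external prevalence (x) per country.

    Expects the per-country underreporting table of one or two algorithms;
    the dotted diagonal marks perfect agreement.
    """
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 5))
    for alg, grp in records.groupby("algorithm"):
        ax.scatter(grp["prevalence_ext"], grp["prevalence_alg"], s=25, label=alg)
        for _, r in grp.iterrows():
            ax.annotate(r["country_code"], (r["prevalence_ext"], r["prevalence_alg"]),
                        fontsize=7, xytext=(2, 2), textcoords="offset points")
    lim = max(records["prevalence_ext"].max(), records["prevalence_alg"].max()) * 1.1
    ax.plot([0, lim], [0, lim], ls=":", c="grey")
    ax.set_xlabel("external prevalence")
    ax.set_ylabel("survey-weighted prevalence")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_underreporting_summary(summary: pd.DataFrame, path: str | Path) -> None:
    """Dot plot of mean underreporting with 95% CI, one row per algorithm."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 0.5 + 0.4 * len(summary)))
    ys = range(len(summary))
    ax.errorbar(
        summary["mean"], list(ys),
        xerr=[summary["mean"] - summary["ci95_low"],
              summary["ci95_high"] - summary["mean"]],
        fmt="o", capsize=3,
    )
    ax.axvline(0.0, c="k", lw=1)
    ax.set_yticks(list(ys), summary["algorithm"])
    ax.set_xlabel("mean underreporting (1 - n_alg / n_ext)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
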