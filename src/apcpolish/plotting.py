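"""Figures: age-specific rates by birth cohort, and APC effect series."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; figures go to files

import matplotlib.pyplot as plt

from .intrinsic import IEResults
from .rate_table import RateTable


def plot_age_by_cohort(table: RateTable, path=None, ax=None):
    """One line per birth cohort: x = age group, y = annualized rate.

    Cohorts observed in a single cell are drawn as lone markers.  This is
    the graphical first phase of the multiphase method: a cohort whose line
    rides above its neighbours at the same ages is a candidate cohort
    effect.
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(9, 5.5))
    else:
        fig = ax.figure
    age_pos = {a.start: i for i, a in enumerate(table.ages)}
    for cohort in table.cohorts:
        series = table.cohort_series(cohort)
        xs = [age_pos[a.start] for a, _ in series]
        ys = [r for _, r in series]
        style = dict(marker="o", markersize=3, linewidth=1)
        if len(xs) == 1:
            style.update(markersize=5)
        ax.plot(xs, ys, label=cohort.label, **style)
    ax.set_xticks(range(table.n_ages))
    ax.set_xticklabels([a.label for a in table.ages], rotation=45, ha="right")
    ax.set_xlabel("Age group (years)")
    ax.set_ylabel("Rate per 100,000 person-years")
    ax.set_title(f"Age-specific rate by birth cohort ({table.label})")
    ax.legend(fontsize=6, ncol=3, title="Birth cohort")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return ax


def plot_ie_effects(results: IEResults, path=None, alpha: float = 0.05):
    """Three panels: age, period, and cohort effect series with pointwise CIs."""
    data = results.plot_data(alpha=alpha)
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for ax, (name, frame) in zip(axes, data.items()):
        x = range(len(frame))
        ax.axhline(0.0, color="grey", linewidth=0.7)
        ax.plot(x, frame["effect"], marker="o", markersize=3)
        ax.fill_between(x, frame["ci_low"], frame["ci_high"], alpha=0.25)
        ax.set_xticks(list(x))
        ax.set_xticklabels(frame["label"], rotation=60, ha="right", fontsize=6)
        ax.set_title(f"{name} effects (log scale)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return axes
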