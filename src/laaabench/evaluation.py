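"""Scoring genome scans against simulated truth.

A *true positive* is a genome-wide-significant association at a causal site;
a *false positive* is a significant association at a non-causal site that is
not in linkage disequilibrium (genotype r-squared above a threshold) with
any causal site.  Counts are averaged over the replicate causal-SNP draws of
each scenario, mirroring how power-comparison bar charts are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LDExclusionRule",
    "ScenarioResult",
    "ld_exclusion_mask",
    "count_hits",
    "average_replicates",
    "summarize",
]


@dataclass(frozen=True)
class LDExclusionRule:
    """Sites with genotype r^2 >= ``r2_threshold`` against any causal site
    are excluded from false-positive counting."""

    r2_threshold: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r^2 threshold must be in [0, 1]")


@dataclass
class ScenarioResult:
    """Replicate-averaged hit counts for one scenario cell."""

    population: str
    kind: str
    ancestry: str
    model: str
    condition: str  # "true" | "inferred"
    tp_counts: list[int]
    fp_counts: list[int]

    def __post_init__(self) -> None:
        if len(self.tp_counts) != len(self.fp_counts) or not self.tp_counts:
            raise ValueError("need matching, non-empty TP and FP count lists")

    @property
    def tp_mean(self) -> float:
        return float(np.mean(self.tp_counts))

    @property
    def fp_mean(self) -> float:
        return float(np.mean(self.fp_counts))

    @property
    def label(self) -> str:
        return f"{self.kind}-{self.ancestry}"


def ld_exclusion_mask(
    genotypes: np.ndarray,
    causal_sites: np.ndarray,
    rule: LDExclusionRule = LDExclusionRule(),
) -> np.ndarray:
    """Boolean mask of non-causal sites in LD with any causal site.

    r^2 is the squared Pearson correlation of genotype dosages across the
    cohort, computed genome-wide against every causal site.  Causal sites
    themselves are not masked (they are scored as true positives).
    """
    geno = np.asarray(genotypes, dtype=float)
    n, m = geno.shape
    causal_sites = np.asarray(causal_sites)
    centered = geno - geno.mean(axis=0)
    sd = centered.std(axis=0)
    sd_safe = np.where(sd > 0, sd, np.inf)
    z = centered / sd_safe
    r = z[:, causal_sites].T @ z / n  # (n_causal, m)
    r2_max = np.max(r**2, axis=0)
    mask = r2_max >= rule.r2_threshold
    mask[causal_sites] = False
    return mask


def count_hits(
    significant: np.ndarray,
    causal_sites: np.ndarray,
    ld_mask: np.ndarray | None = None,
) -> tuple[int, int]:
    """(TP, FP) for one scan.

    TP = significant causal sites; FP = significant sites that are neither
    causal nor masked as LD proxies of a causal site.
    """
    sig = set(np.asarray(significant).tolist())
    causal = set(np.asarray(causal_sites).tolist())
    tp = len(sig & causal)
    excluded = causal | (
        set(np.flatnonzero(ld_mask).tolist()) if ld_mask is not None else set()
    )
    fp = len(sig - excluded)
    return tp, fp


def average_replicates(
    population: str,
    kind: str,
    ancestry: str,
    model: str,
    condition: str,
    counts: list[tuple[int, int]],
) -> ScenarioResult:
    """Collect per-replicate (TP, FP) pairs into a replicate-averaged cell."""
    if not counts:
        raise ValueError("need at least one replicate")
    tp_counts = [int(c[0]) for c in counts]
    fp_counts = [int(c[1]) for c in counts]
    return ScenarioResult(
        population=population,
        kind=kind,
        ancestry=ancestry,
        model=model,
        condition=condition,
        tp_counts=tp_counts,
        fp_counts=fp_counts,
    )


def summarize(results: list[ScenarioResult]) -> pd.DataFrame:
    """Long-format summary: one row per (population, scenario, model,
    condition) with replicate-averaged TP and FP counts."""
    if not results:
        return pd.DataFrame(
            columns=[
                "population", "scenario", "kind", "ancestry", "model",
                "condition", "tp_mean", "fp_mean", "tp_counts", "fp_counts",
            ]
        )
    rows = [
        {
            "population": r.population,
            "scenario": r.label,
            "kind": r.kind,
            "ancestry": r.ancestry,
            "model": r.model,
            "condition": r.condition,
            "tp_mean": r.tp_mean,
            "fp_mean": r.fp_mean,
            "tp_counts": ",".join(map(str, r.tp_counts)),
            "fp_counts": ",".join(map(str, r.fp_counts)),
        }
        for r in results
    ]
    return pd.DataFrame(rows).sort_values(
        ["population", "kind", "ancestry", "model", "condition"], ignore_index=True
    )


def plot_summary(summary: pd.DataFrame, population: str, condition: str, path=None):
    """Paired TP/FP bar chart for one population and ancestry condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = summary[
        (summary["population"] == population) & (summary["condition"] == condition)
    ]
    if sub.empty:
        raise ValueError(f"no rows for {population}/{condition}")
    scenarios = sorted(sub["scenario"].unique())
    models = sorted(sub["model"].unique())
    fig, axes = plt.subplots(1, 2, figsize=(14, 0.45 * len(scenarios) + 2))
    for ax, col, title in zip(axes, ["tp_mean", "fp_mean"], ["True positives", "False positives"]):
        ypos = np.arange(len(scenarios))
        width = 0.8 / len(models)
        for j, model in enumerate(models):
            vals = [
                sub[(sub["scenario"] == s) & (sub["model"] == model)][col].mean()
                for s in scenarios
            ]
            ax.barh(ypos + j * width, vals, height=width, label=model)
        ax.set_yticks(ypos + 0.4 - width / 2)
        ax.set_yticklabels(scenarios)
        ax.set_title(f"{title} ({population}, {condition} ancestry)")
        ax.invert_yaxis()
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
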