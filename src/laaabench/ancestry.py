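"""Observed (inferred-like) local ancestry and its bookkeeping.

Real studies never see true local ancestry; they see the output of a
local-ancestry-inference (LAI) tool.  This module produces that "inferred"
study condition by corrupting the exact truth labels to target per-ancestry
accuracies, computes global ancestry proportions from any label matrix, and
scores observed against true labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import Cohort, LocalAncestryMatrix

__all__ = [
    "CorruptionSpec",
    "global_from_local",
    "corrupt_local_ancestry",
    "lai_accuracy",
    "overall_accuracy",
]


@dataclass(frozen=True)
class CorruptionSpec:
    """Target per-ancestry LAI accuracies and the error-block length scale.

    ``accuracy[k]`` is the probability that a site whose true ancestry is
    ``k`` keeps its label.  Errors are applied to whole blocks (mean length
    ``block_scale_morgans``) so that mislabelled runs are contiguous, the way
    LAI switch errors are.
    """

    accuracy: dict[str, float]
    block_scale_morgans: float = 0.1

    def __post_init__(self) -> None:
        for k, a in self.accuracy.items():
            if not 0.0 < a <= 1.0:
                raise ValueError(f"accuracy for {k} must be in (0,1], got {a}")
        if self.block_scale_morgans <= 0:
            raise ValueError("block scale must be positive")

    def implied_overall(self, proportions: dict[str, float]) -> float:
        """Ancestry-proportion-weighted overall accuracy, sum_k pi_k a_k."""
        return float(sum(proportions[k] * self.accuracy[k] for k in self.accuracy))


def global_from_local(
    local: LocalAncestryMatrix, samples: list[str] | None = None
) -> pd.DataFrame:
    """Global ancestry proportions per individual (symbol P).

    The proportion of source ``k`` for an individual is the fraction of the
    individual's two haplotypes' sites labelled ``k``.  Sites are equally
    weighted (the generator places sites on an even grid, making site and
    length weighting equivalent).  Rows sum to 1 exactly.
    """
    codes = local.codes
    if codes.size == 0 or (codes < 0).any():
        raise ValueError("local ancestry labels are missing or incomplete")
    n_ind = local.n_individuals
    m = codes.shape[1]
    out = np.empty((n_ind, len(local.sources)))
    per_ind = codes.reshape(n_ind, 2 * m)
    for k in range(len(local.sources)):
        out[:, k] = (per_ind == k).mean(axis=1)
    index = samples if samples is not None else [f"ind{i:04d}" for i in range(n_ind)]
    return pd.DataFrame(out, columns=list(local.sources), index=index)


def corrupt_local_ancestry(
    cohort: Cohort,
    spec: CorruptionSpec,
    seed: int = 0,
) -> LocalAncestryMatrix:
    """Corrupt the truth labels to the target per-ancestry accuracies.

    Each haplotype is cut into error blocks by a Poisson process (rate
    ``1 / block_scale_morgans`` per Morgan) overlaid on the true tract
    boundaries, so every block has a single true ancestry ``k``.  With
    probability ``1 - a_k`` the whole block is relabelled to a different
    ancestry drawn with probability proportional to the other ancestries'
    cohort-wide proportions (LAI errors gravitate toward the larger
    components).  Allele/label pairing per haplotype is untouched.
    """
    sources = cohort.sources
    for k in sources:
        if k not in spec.accuracy:
            raise ValueError(f"no target accuracy for source {k!r}")
    if len(sources) < 2:
        raise ValueError("corruption needs at least two sources")
    rng = np.random.default_rng(seed)
    truth = cohort.truth.codes
    observed = truth.copy()

    # cohort-wide ancestry proportions drive the mislabel target distribution
    pi = np.array([(truth == k).mean() for k in range(len(sources))])
    pi = pi / pi.sum()

    positions = cohort.site_positions_by_chrom()
    # genetic position of each site (uniform map assumed at generation time;
    # for corruption only relative distances matter, so use the cohort grid
    # converted at 1 cM/Mb)
    rate_per_bp = 1e-8
    block_rate = 1.0 / spec.block_scale_morgans  # breakpoints per Morgan
    acc = np.array([spec.accuracy[k] for k in sources])

    n_hap = truth.shape[0]
    offset = 0
    for chrom, pos in positions.items():
        m_c = len(pos)
        gpos = pos * rate_per_bp
        g_len = gpos[-1] + (gpos[1] - gpos[0]) if m_c > 1 else gpos[-1]
        for h in range(n_hap):
            n_cuts = rng.poisson(block_rate * g_len)
            cuts = np.sort(rng.uniform(0.0, g_len, size=n_cuts))
            cut_idx = np.searchsorted(gpos, cuts)
            # block boundaries = error-block cuts U true-tract changes
            row = truth[h, offset : offset + m_c]
            change = np.flatnonzero(np.diff(row)) + 1
            bounds = np.unique(np.concatenate([[0], cut_idx, change, [m_c]]))
            starts, ends = bounds[:-1], bounds[1:]
            keep = starts < ends
            starts, ends = starts[keep], ends[keep]
            true_k = row[starts]
            flip = rng.random(len(starts)) >= acc[true_k]
            for s, e, k in zip(starts[flip], ends[flip], true_k[flip]):
                w = pi.copy()
                w[k] = 0.0
                w /= w.sum()
                new_k = rng.choice(len(sources), p=w)
                observed[h, offset + s : offset + e] = new_k
        offset += m_c
    return LocalAncestryMatrix(observed, sources)


@dataclass(frozen=True)
class LaiAccuracyReport:
    per_ancestry: dict[str, float]
    overall: float
    proportions: dict[str, float] = field(default_factory=dict)


def lai_accuracy(
    truth: LocalAncestryMatrix, observed: LocalAncestryMatrix
) -> LaiAccuracyReport:
    """Per-ancestry and overall label accuracy of observed vs true ancestry.

    Per-ancestry accuracy is the fraction of truth-``k`` haplotype-sites
    labelled ``k`` in the observed matrix; the overall accuracy is the
    ancestry-proportion-weighted mean, which equals the plain fraction of
    correctly labelled sites.
    """
    if truth.codes.shape != observed.codes.shape:
        raise ValueError("truth and observed matrices differ in shape")
    if truth.sources != observed.sources:
        raise ValueError("truth and observed matrices differ in source lists")
    per = {}
    props = {}
    total = truth.codes.size
    for k, src in enumerate(truth.sources):
        mask = truth.codes == k
        n_k = int(mask.sum())
        props[src] = n_k / total
        per[src] = float((observed.codes[mask] == k).mean()) if n_k else float("nan")
    overall = float((observed.codes == truth.codes).mean())
    return LaiAccuracyReport(per_ancestry=per, overall=overall, proportions=props)


def overall_accuracy(
    proportions: dict[str, float], per_ancestry: dict[str, float]
) -> float:
    """Weighted overall accuracy from per-ancestry accuracies: sum_k pi_k a_k."""
    return float(sum(proportions[k] * per_ancestry[k] for k in per_ancestry))
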