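"""Synthetic genotypes for multi-way admixed cohorts.

The generator replaces a full coalescent simulation with the two ingredients
the downstream association benchmark actually exploits:

1. **Ancestral allele-frequency differentiation** between source populations,
   drawn from the Balding-Nichols model: a shared ancestral frequency ``p``
   per site and per-population frequencies
   ``p_k ~ Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k)``.
2. **Admixture linkage disequilibrium** from a recombination-driven tract
   mosaic: each admixed haplotype is a sequence of ancestry tracts whose
   breakpoints accumulate at ``g`` per Morgan per generation since each
   admixture pulse, layered newest pulse first.

Because the mosaic is generated forward from the pulse schedule, the true
local ancestry of every haplotype is known exactly by construction.  Sites
are independent within source populations (no background LD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._random import rng_for
from .presets import DemographicPreset, RecombinationMap

__all__ = [
    "AncestryTract",
    "HaplotypePool",
    "LocalAncestryMatrix",
    "Cohort",
    "draw_ancestral_frequencies",
    "sample_reference_haplotypes",
    "simulate_tracts",
    "assemble_admixed_cohort",
    "simulate_cohort",
]


@dataclass(frozen=True)
class AncestryTract:
    """Ancestry-labelled genomic interval (0-based, half-open) on one haplotype."""

    chrom: str
    start_bp: int
    end_bp: int
    ancestry: str

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError(f"empty tract: [{self.start_bp}, {self.end_bp})")


@dataclass
class HaplotypePool:
    """Phased reference haplotypes per source population.

    ``haplotypes[src]`` is a ``(2 * n_individuals, n_sites)`` 0/1 array where
    allele 1 is the reference base (``ref_allele``) and 0 the alternate.
    ``freqs`` holds the shared ancestral frequency and the per-population
    frequency of allele 1 at every site.
    """

    freqs: pd.DataFrame  # columns: "ancestral" + one per source
    haplotypes: dict[str, np.ndarray]
    ref_allele: str = "A"
    alt_allele: str = "G"

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(self.haplotypes)

    @property
    def n_sites(self) -> int:
        return len(self.freqs)


@dataclass
class LocalAncestryMatrix:
    """Per-haplotype, per-site ancestry labels.

    ``codes`` has shape ``(2 * n_individuals, n_sites)`` with values indexing
    into ``sources``; haplotype rows ``2i`` and ``2i+1`` belong to individual
    ``i``.
    """

    codes: np.ndarray
    sources: tuple[str, ...]

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.min(initial=0) < 0 or codes.max(initial=0) >= len(self.sources):
            raise ValueError("ancestry codes outside the source list")
        self.codes = codes.astype(np.int8)

    @property
    def n_haplotypes(self) -> int:
        return self.codes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0] // 2

    def dosage(self, ancestry: str) -> np.ndarray:
        """Per-individual copies (0/1/2) of ``ancestry`` at every site."""
        k = self.sources.index(ancestry)
        hit = (self.codes == k).astype(np.int8)
        return hit[0::2] + hit[1::2]

    def copy(self) -> "LocalAncestryMatrix":
        return LocalAncestryMatrix(self.codes.copy(), self.sources)


@dataclass
class Cohort:
    """An admixed cohort: phased genotypes plus exact local-ancestry truth.

    ``sites`` is a table with columns ``chrom``, ``pos`` (0-based bp) and
    ``id``; ``haplotypes`` is ``(2n, m)`` 0/1 (allele 1 = reference base) and
    ``truth`` the matching ancestry labels.  ``tracts[h]`` is the generating
    tract list of haplotype ``h``.
    """

    preset_name: str
    sources: tuple[str, ...]
    sites: pd.DataFrame
    haplotypes: np.ndarray
    truth: LocalAncestryMatrix
    samples: list[str]
    tracts: list[list[AncestryTract]] = field(default_factory=list, repr=False)
    ref_allele: str = "A"
    alt_allele: str = "G"

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def genotypes(self) -> np.ndarray:
        """Individuals x sites count (0/1/2) of allele 1 (reference base)."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    def allele1_frequency(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def site_positions_by_chrom(self) -> dict[str, np.ndarray]:
        return {
            str(c): g["pos"].to_numpy()
            for c, g in self.sites.groupby("chrom", sort=False)
        }


def draw_ancestral_frequencies(
    n_sites: int,
    sources: tuple[str, ...] | list[str],
    F_per_source: dict[str, float],
    p_range: tuple[float, float] = (0.05, 0.95),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-site, per-source allele frequencies (Balding-Nichols).

    The shared ancestral frequency ``p`` is Uniform over ``p_range``; each
    source's frequency is Beta-distributed around ``p`` with spread governed
    by its differentiation ``F``:
    ``p_k ~ Beta(p (1-F)/F, (1-p) (1-F)/F)`` so that ``E[p_k] = p`` and
    ``Var[p_k] = F p (1-p)``.

    Returns a DataFrame with column ``ancestral`` plus one column per source,
    all entries strictly inside (0, 1).
    """
    lo, hi = p_range
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("p_range must be inside (0,1)")
    for src in sources:
        if not 0.0 < F_per_source[src] < 1.0:
            raise ValueError(f"F for {src} must be in (0,1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_sites)
    out = {"ancestral": p}
    eps = 1e-12
    for src in sources:
        f_st = F_per_source[src]
        scale = (1.0 - f_st) / f_st
        pk = rng.beta(p * scale, (1.0 - p) * scale)
        out[src] = np.clip(pk, eps, 1.0 - eps)
    return pd.DataFrame(out)


def sample_reference_haplotypes(
    freqs: pd.DataFrame, n_individuals_per_source: int, seed: int = 0
) -> HaplotypePool:
    """Sample phased reference haplotypes, independent Bernoulli per site.

    Each source gets ``2 * n_individuals_per_source`` haplotypes with allele
    1 carried at site ``j`` with probability ``freqs[src][j]``.  Sites are
    independent (no background LD).
    """
    if n_individuals_per_source <= 0:
        raise ValueError("need at least one reference individual per source")
    rng = np.random.default_rng(seed)
    sources = [c for c in freqs.columns if c != "ancestral"]
    haps = {}
    n_hap = 2 * n_individuals_per_source
    for src in sources:
        pk = freqs[src].to_numpy()
        haps[src] = (rng.random((n_hap, len(pk))) < pk).astype(np.uint8)
    return HaplotypePool(freqs=freqs, haplotypes=haps)


def _merge_adjacent(tracts: list[AncestryTract]) -> list[AncestryTract]:
    merged: list[AncestryTract] = []
    for t in tracts:
        if merged and merged[-1].ancestry == t.ancestry and merged[-1].end_bp == t.start_bp:
            merged[-1] = AncestryTract(t.chrom, merged[-1].start_bp, t.end_bp, t.ancestry)
        else:
            merged.append(t)
    return merged


def simulate_tracts(
    preset: DemographicPreset,
    rmap: RecombinationMap | None = None,
    seed: int | np.random.Generator = 0,
) -> list[AncestryTract]:
    """Simulate the ancestry-tract mosaic of one admixed haplotype.

    Pulses are applied newest first.  The most recent pulse (age ``g_new``)
    lays breakpoints as a Poisson process at rate ``g_new`` per Morgan and
    labels each segment with one of its incoming sources (probability =
    pulse-time fraction) or leaves it as background.  Each older pulse adds
    breakpoints inside the remaining background at the rate increment
    ``g_old - g_new`` and labels segments the same way; background left after
    the oldest pulse takes the preset's base ancestry.  Breakpoints are drawn
    in genetic coordinates and mapped back to bp through the recombination
    map; adjacent same-ancestry segments are merged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rmap is None:
        rmap = preset.recombination_map()
    out: list[AncestryTract] = []
    pulses_newest_first = list(reversed(preset.pulses))
    for chrom in rmap.chromosomes:
        g_len = rmap.genetic_length(chrom)
        background = [(0.0, g_len)]  # genetic coordinates, Morgans
        labelled: list[tuple[float, float, str]] = []
        prev_age = 0
        for pulse in pulses_newest_first:
            rate = pulse.generations_ago - prev_age
            prev_age = pulse.generations_ago
            srcs = list(pulse.incoming)
            probs = np.array([pulse.incoming[s] for s in srcs] + [0.0])
            probs[-1] = 1.0 - probs.sum()
            choices = srcs + [None]
            new_background: list[tuple[float, float]] = []
            for a, b in background:
                n_bp = rng.poisson(rate * (b - a))
                cuts = np.sort(rng.uniform(a, b, size=n_bp))
                bounds = np.concatenate([[a], cuts, [b]])
                for lo, hi in zip(bounds[:-1], bounds[1:]):
                    lab = choices[rng.choice(len(choices), p=probs)]
                    if lab is None:
                        new_background.append((lo, hi))
                    else:
                        labelled.append((lo, hi, lab))
            background = new_background
        labelled.extend((a, b, preset.base_source) for a, b in background)
        labelled.sort()
        # genetic -> physical coordinates; snap to integer bp
        chrom_tracts: list[AncestryTract] = []
        L = rmap.chrom_length_bp(chrom)
        edges = np.array([seg[0] for seg in labelled] + [g_len])
        bp_edges = np.rint(rmap.morgan_to_bp(chrom, edges)).astype(np.int64)
        bp_edges[0], bp_edges[-1] = 0, L
        bp_edges = np.maximum.accumulate(bp_edges)
        for (a, b, lab), lo, hi in zip(labelled, bp_edges[:-1], bp_edges[1:]):
            if hi > lo:  # zero-bp segments vanish on rounding
                chrom_tracts.append(AncestryTract(chrom, int(lo), int(hi), lab))
        out.extend(_merge_adjacent(chrom_tracts))
    return out


def assemble_admixed_cohort(
    preset: DemographicPreset,
    pool: HaplotypePool,
    rmap: RecombinationMap | None = None,
    seed: int = 0,
) -> Cohort:
    """Build an admixed cohort by copying alleles along simulated tracts.

    For each of the ``2 * n_admixed`` haplotypes a tract mosaic is simulated,
    and within every tract the alleles are copied from one reference
    haplotype drawn uniformly (with replacement, per tract) from the tract's
    source pool.  The returned truth labels are the generating tracts
    expanded to per-site codes, so genotypes and truth agree exactly.
    """
    if rmap is None:
        rmap = preset.recombination_map()
    for src in preset.sources:
        if src not in pool.haplotypes or pool.haplotypes[src].shape[0] == 0:
            raise ValueError(f"empty reference pool for source {src!r}")
    rng = np.random.default_rng(seed)
    positions = preset.site_positions()
    site_rows = []
    offset = {}
    running = 0
    for chrom, pos in positions.items():
        offset[chrom] = running
        running += len(pos)
        site_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    sites = pd.concat(site_rows, ignore_index=True)
    sites["id"] = [f"snp{i}" for i in range(len(sites))]
    m = len(sites)
    if m != pool.n_sites:
        raise ValueError("preset site count does not match pool site count")

    n_hap = 2 * preset.n_admixed
    haps = np.empty((n_hap, m), dtype=np.uint8)
    truth_codes = np.empty((n_hap, m), dtype=np.int8)
    all_tracts: list[list[AncestryTract]] = []
    src_index = {s: i for i, s in enumerate(preset.sources)}
    for h in range(n_hap):
        tracts = simulate_tracts(preset, rmap, rng)
        all_tracts.append(tracts)
        for t in tracts:
            pos = positions[t.chrom]
            lo = np.searchsorted(pos, t.start_bp, side="left")
            hi = np.searchsorted(pos, t.end_bp, side="left")
            if hi == lo:
                continue
            off = offset[t.chrom]
            donor_pool = pool.haplotypes[t.ancestry]
            donor = rng.integers(donor_pool.shape[0])
            haps[h, off + lo : off + hi] = donor_pool[donor, off + lo : off + hi]
            truth_codes[h, off + lo : off + hi] = src_index[t.ancestry]

    truth = LocalAncestryMatrix(truth_codes, tuple(preset.sources))
    samples = [f"{preset.name}_{i:04d}" for i in range(preset.n_admixed)]
    return Cohort(
        preset_name=preset.name,
        sources=tuple(preset.sources),
        sites=sites,
        haplotypes=haps,
        truth=truth,
        samples=samples,
        tracts=all_tracts,
        ref_allele=pool.ref_allele,
        alt_allele=pool.alt_allele,
    )


def simulate_cohort(preset: DemographicPreset, seed: int = 0) -> Cohort:
    """One-call cohort simulation: frequencies -> pools -> admixed cohort.

    Child seeds for the three stages are derived deterministically from
    ``seed``.
    """
    freqs = draw_ancestral_frequencies(
        preset.n_sites,
        preset.sources,
        preset.differentiation,
        seed=rng_for(seed, "freqs", preset.name).integers(2**31),
    )
    pool = sample_reference_haplotypes(
        freqs,
        preset.n_reference_per_source,
        seed=rng_for(seed, "pool", preset.name).integers(2**31),
    )
    return assemble_admixed_cohort(
        preset,
        pool,
        seed=rng_for(seed, "cohort", preset.name).integers(2**31),
    )
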