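"""Demographic presets for the simulated admixed cohorts.

Two study populations are modelled:

``nama3``
    A three-way admixed population (Khoe-San / east-African / European
    sources, labelled NAMA / LWK / GBR) with final ancestry proportions
    0.75 / 0.10 / 0.15.  Admixture happened in two pulses: an older
    east-African pastoralist pulse (~2000 years ago, g = 80 generations at
    25 years per generation) and a recent European pulse (~250 years ago,
    g = 10).

``sac5``
    A five-way admixed population (NAMA / MSL / GBR / GIH / CHB sources)
    with proportions 0.350 / 0.250 / 0.175 / 0.125 / 0.100, formed by a
    single admixture event g = 16 generations ago.

Each preset also carries per-source differentiation parameters ``F`` for the
Balding-Nichols allele-frequency model, cohort sizes, and the chromosome /
genetic-map layout used at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AdmixturePulse",
    "RecombinationMap",
    "DemographicPreset",
    "nama3",
    "sac5",
    "get_preset",
    "NAMA3_LAI_ACCURACY",
    "SAC5_LAI_ACCURACY",
]

# Per-ancestry local-ancestry-inference accuracies emulated for the
# "inferred ancestry" study condition (fraction of sites of each true
# ancestry that retain their label after corruption).
NAMA3_LAI_ACCURACY: dict[str, float] = {"LWK": 0.761, "GBR": 0.884, "NAMA": 0.853}
SAC5_LAI_ACCURACY: dict[str, float] = {
    "CHB": 0.831,
    "GBR": 0.892,
    "MSL": 0.846,
    "NAMA": 0.847,
    "GIH": 0.854,
}


@dataclass(frozen=True)
class AdmixturePulse:
    """One admixture pulse ``generations_ago`` generations before present.

    ``incoming`` maps each incoming source to the fraction of the
    then-current gene pool it replaced at pulse time.  A single founding
    event for a multi-way population is a pulse with several incoming
    sources; the remainder (1 - sum of fractions) keeps the background
    ancestry of the pool the pulse entered.
    """

    generations_ago: int
    incoming: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.incoming.values())
        if not self.incoming:
            raise ValueError("pulse must have at least one incoming source")
        for src, f in self.incoming.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"pulse fraction for {src} must be in (0,1), got {f}")
        if not 0.0 < total < 1.0:
            raise ValueError(f"total incoming fraction must be in (0,1), got {total}")
        if self.generations_ago <= 0:
            raise ValueError("pulse age must be a positive generation count")

    @property
    def total_fraction(self) -> float:
        return sum(self.incoming.values())


@dataclass(frozen=True)
class RecombinationMap:
    """Piecewise-constant recombination map, per chromosome.

    ``positions[c]`` is an increasing array of breakpoint positions (bp)
    starting at 0 and ending at the chromosome length; ``rates[c]`` gives the
    rate in Morgans/bp on each interval (one fewer entry than positions).
    The default construction is uniform 1e-8 M/bp (1 cM/Mb).
    """

    positions: dict[str, np.ndarray]
    rates: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            rate = self.rates[chrom]
            if len(rate) != len(pos) - 1:
                raise ValueError(f"{chrom}: rates must have len(positions)-1 entries")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: positions must be strictly increasing")
            if np.any(rate < 0):
                raise ValueError(f"{chrom}: negative recombination rate")

    @classmethod
    def uniform(
        cls, chromosomes: dict[str, int], rate: float = 1e-8
    ) -> "RecombinationMap":
        """Uniform map: ``rate`` Morgans/bp on every chromosome."""
        positions = {
            c: np.array([0, length], dtype=float) for c, length in chromosomes.items()
        }
        rates = {c: np.array([rate], dtype=float) for c in chromosomes}
        return cls(positions=positions, rates=rates)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)

    def chrom_length_bp(self, chrom: str) -> int:
        return int(self.positions[chrom][-1])

    def genetic_length(self, chrom: str) -> float:
        """Total genetic length of ``chrom`` in Morgans."""
        pos = self.positions[chrom]
        return float(np.sum(np.diff(pos) * self.rates[chrom]))

    def bp_to_morgan(self, chrom: str, bp: np.ndarray) -> np.ndarray:
        """Cumulative genetic position (Morgans) of physical positions."""
        pos = self.positions[chrom]
        rate = self.rates[chrom]
        cum = np.concatenate([[0.0], np.cumsum(np.diff(pos) * rate)])
        idx = np.clip(np.searchsorted(pos, bp, side="right") - 1, 0, len(rate) - 1)
        return cum[idx] + (np.asarray(bp, dtype=float) - pos[idx]) * rate[idx]

    def morgan_to_bp(self, chrom: str, gpos: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`bp_to_morgan` (piecewise-linear interpolation)."""
        pos = self.positions[chrom]
        rate = self.rates[chrom]
        cum = np.concatenate([[0.0], np.cumsum(np.diff(pos) * rate)])
        idx = np.clip(np.searchsorted(cum, gpos, side="right") - 1, 0, len(rate) - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            offset = np.where(
                rate[idx] > 0,
                (np.asarray(gpos, dtype=float) - cum[idx]) / rate[idx],
                0.0,
            )
        return pos[idx] + offset


@dataclass(frozen=True)
class DemographicPreset:
    """Full specification of one simulated admixed population."""

    name: str
    sources: tuple[str, ...]
    final_proportions: dict[str, float]
    base_source: str
    pulses: tuple[AdmixturePulse, ...]  # ordered oldest -> newest
    differentiation: dict[str, float]  # Balding-Nichols F per source
    n_admixed: int = 500
    n_reference_per_source: int = 200
    n_sites: int = 10_000
    chromosome_lengths_bp: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 50_000_000 for i in range(1, 5)}
    )
    recombination_rate: float = 1e-8  # Morgans per bp (1 cM/Mb)

    def __post_init__(self) -> None:
        total = sum(self.final_proportions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"final proportions sum to {total}, expected 1")
        if set(self.final_proportions) != set(self.sources):
            raise ValueError("final_proportions keys must match sources")
        if self.base_source not in self.sources:
            raise ValueError("base_source must be one of sources")
        for pulse in self.pulses:
            unknown = set(pulse.incoming) - set(self.sources)
            if unknown:
                raise ValueError(f"pulse sources {unknown} not in preset sources")
        ages = [p.generations_ago for p in self.pulses]
        if ages != sorted(ages, reverse=True) or len(set(ages)) != len(ages):
            raise ValueError("pulses must be ordered oldest to newest")
        for k, f_st in self.differentiation.items():
            if not 0.0 < f_st < 1.0:
                raise ValueError(f"differentiation F for {k} must be in (0,1)")
        implied = self.implied_marginal_proportions()
        for k in self.sources:
            if abs(implied[k] - self.final_proportions[k]) > 1e-12:
                raise ValueError(
                    f"pulse schedule implies {k} proportion {implied[k]:.6f}, "
                    f"preset declares {self.final_proportions[k]}"
                )

    def implied_marginal_proportions(self) -> dict[str, float]:
        """Marginal ancestry fractions implied by the pulse schedule.

        A pulse replaces a fraction of the then-current gene pool, so its
        contribution to the present-day genome is that fraction thinned by
        every later pulse.
        """
        out = dict.fromkeys(self.sources, 0.0)
        survival = 1.0  # fraction of the present-day pool older than the pulse
        for pulse in reversed(self.pulses):  # newest first
            for src, f in pulse.incoming.items():
                out[src] += f * survival
            survival *= 1.0 - pulse.total_fraction
        out[self.base_source] += survival
        return out

    def recombination_map(self) -> RecombinationMap:
        return RecombinationMap.uniform(
            self.chromosome_lengths_bp, self.recombination_rate
        )

    def site_positions(self) -> dict[str, np.ndarray]:
        """Evenly spaced site positions (0-based bp), ``n_sites`` total split
        proportionally to chromosome length."""
        lengths = self.chromosome_lengths_bp
        total = sum(lengths.values())
        out: dict[str, np.ndarray] = {}
        assigned = 0
        chroms = list(lengths)
        for i, chrom in enumerate(chroms):
            if i == len(chroms) - 1:
                n = self.n_sites - assigned
            else:
                n = int(round(self.n_sites * lengths[chrom] / total))
            assigned += n
            step = lengths[chrom] / n
            out[chrom] = (np.arange(n) * step + step / 2).astype(np.int64)
        return out

    def with_sizes(self, **kwargs) -> "DemographicPreset":
        """Copy of the preset with size/layout fields overridden."""
        return replace(self, **kwargs)


def nama3(**overrides) -> DemographicPreset:
    """Three-way admixed preset (Khoe-San base, LWK then GBR pulses).

    The older pulse's fraction is the pulse-time value 0.10/0.85 that yields
    a final LWK marginal of 0.10 after thinning by the later 0.15 GBR pulse.
    """
    return DemographicPreset(
        name="nama3",
        sources=("LWK", "GBR", "NAMA"),
        final_proportions={"LWK": 0.10, "GBR": 0.15, "NAMA": 0.75},
        base_source="NAMA",
        pulses=(
            AdmixturePulse(generations_ago=80, incoming={"LWK": 0.10 / 0.85}),
            AdmixturePulse(generations_ago=10, incoming={"GBR": 0.15}),
        ),
        differentiation={"NAMA": 0.15, "LWK": 0.08, "GBR": 0.12},
        **overrides,
    )


def sac5(**overrides) -> DemographicPreset:
    """Five-way admixed preset: one founding admixture event, g = 16."""
    return DemographicPreset(
        name="sac5",
        sources=("CHB", "GBR", "MSL", "NAMA", "GIH"),
        final_proportions={
            "CHB": 0.100,
            "GBR": 0.175,
            "MSL": 0.250,
            "NAMA": 0.350,
            "GIH": 0.125,
        },
        base_source="NAMA",
        pulses=(
            AdmixturePulse(
                generations_ago=16,
                incoming={"CHB": 0.100, "GBR": 0.175, "MSL": 0.250, "GIH": 0.125},
            ),
        ),
        differentiation={
            "NAMA": 0.15,
            "MSL": 0.08,
            "GBR": 0.12,
            "GIH": 0.12,
            "CHB": 0.14,
        },
        **overrides,
    )


def get_preset(name: str, **overrides) -> DemographicPreset:
    try:
        factory = {"nama3": nama3, "sac5": sac5}[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; expected 'nama3' or 'sac5'")
    return factory(**overrides)
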