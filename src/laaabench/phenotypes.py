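"""Variance-component phenotype simulation for admixed cohorts.

Phenotypes are built in three steps: (1) simulate raw component vectors,
(2) scale each to its share of the total variance, (3) sum.  Components:

* **variant** — additive allelic effects at ``n_causal`` causal SNPs
  (dosage of the cohort major allele, standard-normal weights);
* **local** — ancestry-of-interest dosage effects at the same causal SNPs
  (true local ancestry);
* **interaction** — ancestry-specific allelic effects (copies of the major
  allele carried on an ancestry-of-interest haplotype);
* **popstructure** — a zero-mean random effect with covariance proportional
  to the genotype kinship matrix;
* **observational** — iid Gaussian noise;
* **covariates** — a linear effect of age and sex.

Three phenotype kinds are studied: AO (allelic only), APA (allelic +
ancestry) and LAAA (allelic + ancestry + interaction); their variance
budgets are fixed study conditions (genetic effects total 60%: variant 12%,
local ancestry 6% when present, interaction 4% when present, the remainder
population structure; noise 40%: observational 16%, covariates 24%; the
five-way population adds two null AO scenarios with no variant effect).

Scaling is exact: components are sequentially orthogonalized before being
standardized and weighted, so each realized variance share equals its budget
to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from ._random import child_seed
from .genotypes import Cohort, LocalAncestryMatrix

__all__ = [
    "PhenotypeSpec",
    "CausalSet",
    "PhenotypeTable",
    "KINDS",
    "N_REPLICATES",
    "budget_for",
    "enumerate_scenarios",
    "make_covariates",
    "draw_causal_set",
    "build_components",
    "scale_and_combine",
    "simulate_phenotype",
]

KINDS = ("AO", "APA", "LAAA")
N_REPLICATES = 3
COMPONENT_ORDER = (
    "variant",
    "local",
    "interaction",
    "popstructure",
    "covariates",
    "observational",
)

# Null scenarios (no genetic signal beyond structure): AO phenotypes for
# these five-way ancestries carry no variant effect at all.
_NULL_AO = {("sac5", "CHB"), ("sac5", "GIH")}


@dataclass(frozen=True)
class PhenotypeSpec:
    """One phenotype scenario: kind, ancestry of interest, variance budget."""

    kind: str
    ancestry_of_interest: str
    v_variant: float
    v_local: float
    v_interaction: float
    v_popstructure: float
    v_observational: float = 0.16
    v_covariates: float = 0.24
    n_causal: int = 10
    replicate: int = 0
    population: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown phenotype kind {self.kind!r}")
        fracs = self.fractions()
        if any(v < 0 for v in fracs.values()):
            raise ValueError("variance fractions must be non-negative")
        total = sum(fracs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"variance fractions sum to {total}, expected 1")
        if self.kind == "AO" and (self.v_local or self.v_interaction):
            raise ValueError("AO phenotypes have no ancestry or interaction share")
        if self.kind == "APA" and self.v_interaction:
            raise ValueError("APA phenotypes have no interaction share")

    def fractions(self) -> dict[str, float]:
        return {
            "variant": self.v_variant,
            "local": self.v_local,
            "interaction": self.v_interaction,
            "popstructure": self.v_popstructure,
            "covariates": self.v_covariates,
            "observational": self.v_observational,
        }

    @property
    def label(self) -> str:
        return f"{self.kind}-{self.ancestry_of_interest}"


def budget_for(population: str, kind: str, ancestry: str) -> dict[str, float]:
    """The study's variance budget for one (population, kind, ancestry) cell."""
    if kind == "AO":
        if (population, ancestry) in _NULL_AO:
            return dict(variant=0.00, local=0.0, interaction=0.0, popstructure=0.60)
        return dict(variant=0.12, local=0.0, interaction=0.0, popstructure=0.48)
    if kind == "APA":
        return dict(variant=0.12, local=0.06, interaction=0.0, popstructure=0.42)
    if kind == "LAAA":
        return dict(variant=0.12, local=0.06, interaction=0.04, popstructure=0.38)
    raise ValueError(f"unknown phenotype kind {kind!r}")


def enumerate_scenarios(
    population: str, sources: tuple[str, ...], n_replicates: int = N_REPLICATES
) -> list[PhenotypeSpec]:
    """All phenotype specs for a population: kinds x sources x replicates.

    Three kinds and three replicates give 27 specs for a three-way
    population and 45 for a five-way one.
    """
    specs = []
    for kind, ancestry, rep in product(KINDS, sources, range(n_replicates)):
        b = budget_for(population, kind, ancestry)
        specs.append(
            PhenotypeSpec(
                kind=kind,
                ancestry_of_interest=ancestry,
                v_variant=b["variant"],
                v_local=b["local"],
                v_interaction=b["interaction"],
                v_popstructure=b["popstructure"],
                replicate=rep,
                population=population,
            )
        )
    return specs


@dataclass(frozen=True)
class CausalSet:
    """Causal site indices plus raw per-channel weights."""

    sites: np.ndarray  # sorted site indices into the cohort
    w_variant: np.ndarray
    w_local: np.ndarray
    w_interaction: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sites)
        if len(set(self.sites.tolist())) != n:
            raise ValueError("causal sites must be distinct")
        for w in (self.w_variant, self.w_local, self.w_interaction):
            if len(w) != n:
                raise ValueError("weight vectors must match the causal set size")


@dataclass
class PhenotypeTable:
    """Simulated phenotype with its recorded per-component contributions."""

    spec: PhenotypeSpec
    y: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    components: dict[str, np.ndarray]
    causal: CausalSet
    seed: int

    def variance_shares(self) -> dict[str, float]:
        """Empirical variance of each scaled component over the variance of Y."""
        var_y = float(np.var(self.y))
        return {k: float(np.var(v)) / var_y for k, v in self.components.items()}

    def to_frame(self, samples: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "FID": samples,
                "IID": samples,
                "Y": self.y,
                "age": self.age,
                "sex": self.sex.astype(int),
            }
        )


def make_covariates(n: int, seed: int = 0) -> pd.DataFrame:
    """Draw demographic covariates: age ~ Uniform(20, 70), sex ~ Bernoulli(.5).

    Only their variances matter downstream (components are standardized), so
    the distributions are conventional choices.  Standardized columns are
    included for design-matrix use.
    """
    if n < 2:
        raise ValueError("need at least two individuals")
    rng = np.random.default_rng(seed)
    age = rng.uniform(20.0, 70.0, size=n)
    sex = (rng.random(n) < 0.5).astype(np.int8)
    out = pd.DataFrame({"age": age, "sex": sex})
    out["age_std"] = (age - age.mean()) / age.std()
    out["sex_std"] = (sex - sex.mean()) / (sex.std() if sex.std() > 0 else 1.0)
    return out


def _major_allele_dosages(
    cohort: Cohort, local: LocalAncestryMatrix, ancestry: str, sites: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X_x, X^i, X^i_x) per individual at the given sites (major-allele coding)."""
    from .gwas import major_allele_mask, build_dosages

    major1 = major_allele_mask(cohort)
    return build_dosages(cohort, local, ancestry, sites, major1)


def draw_causal_set(
    cohort: Cohort,
    spec: PhenotypeSpec,
    seed: int = 0,
    maf_threshold: float = 0.05,
) -> CausalSet:
    """Draw ``n_causal`` distinct causal SNPs and their raw channel weights.

    Eligible sites have cohort minor-allele frequency >= ``maf_threshold``
    and a non-constant ancestry-of-interest dosage (a constant dosage would
    make the local-ancestry channel degenerate at that site).
    """
    rng = np.random.default_rng(seed)
    geno = cohort.genotypes
    freq1 = geno.mean(axis=0) / 2.0
    maf = np.minimum(freq1, 1.0 - freq1)
    anc_dos = cohort.truth.dosage(spec.ancestry_of_interest)
    nonconstant = anc_dos.min(axis=0) != anc_dos.max(axis=0)
    eligible = np.flatnonzero((maf >= maf_threshold) & nonconstant)
    if len(eligible) < spec.n_causal:
        raise ValueError(
            f"only {len(eligible)} eligible causal sites, need {spec.n_causal}"
        )
    sites = np.sort(rng.choice(eligible, size=spec.n_causal, replace=False))
    return CausalSet(
        sites=sites,
        w_variant=rng.standard_normal(spec.n_causal),
        w_local=rng.standard_normal(spec.n_causal),
        w_interaction=rng.standard_normal(spec.n_causal),
    )


def kinship_matrix(cohort: Cohort) -> np.ndarray:
    """Genotype kinship: K = G_std G_std' / m with standardized genotypes."""
    geno = cohort.genotypes.astype(float)
    p = geno.mean(axis=0) / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    ok = sd > 0
    g_std = (geno[:, ok] - 2.0 * p[ok]) / sd[ok]
    return g_std @ g_std.T / ok.sum()


def build_components(
    cohort: Cohort,
    causal: CausalSet,
    spec: PhenotypeSpec,
    covariates: pd.DataFrame,
    seed: int = 0,
    kinship_chol: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Raw (unscaled) component vectors for one phenotype.

    The genetic channels share the causal set: variant uses major-allele
    dosage, local uses true ancestry-of-interest dosage, interaction uses
    the ancestry-specific major-allele dosage.  Channels whose budget is
    zero are returned as zero vectors.
    """
    rng = np.random.default_rng(seed)
    n = cohort.n_individuals
    fr = spec.fractions()
    x_x, x_i, x_ix = _major_allele_dosages(
        cohort, cohort.truth, spec.ancestry_of_interest, causal.sites
    )

    comp: dict[str, np.ndarray] = {}
    comp["variant"] = (
        x_x.astype(float) @ causal.w_variant if fr["variant"] > 0 else np.zeros(n)
    )
    comp["local"] = (
        x_i.astype(float) @ causal.w_local if fr["local"] > 0 else np.zeros(n)
    )
    comp["interaction"] = (
        x_ix.astype(float) @ causal.w_interaction
        if fr["interaction"] > 0
        else np.zeros(n)
    )
    if fr["popstructure"] > 0:
        if kinship_chol is None:
            K = kinship_matrix(cohort)
            kinship_chol = np.linalg.cholesky(K + 1e-6 * np.eye(n))
        comp["popstructure"] = kinship_chol @ rng.standard_normal(n)
    else:
        comp["popstructure"] = np.zeros(n)
    a1, a2 = rng.standard_normal(2)
    comp["covariates"] = (
        a1 * covariates["age_std"].to_numpy() + a2 * covariates["sex_std"].to_numpy()
    )
    comp["observational"] = rng.standard_normal(n)

    for name, v in comp.items():
        if fr[name] > 0 and float(np.var(v)) <= 0:
            raise ValueError(
                f"component {name!r} has zero variance but a positive budget"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError(f"component {name!r} contains non-finite values")
    return comp


def scale_and_combine(
    raw: dict[str, np.ndarray], spec: PhenotypeSpec, orthogonalize: bool = True
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Scale components to the variance budget and sum them into Y.

    Components are processed in a fixed order (variant, local, interaction,
    popstructure, covariates, observational); each is demeaned, residualized
    against the already-scaled components (Gram-Schmidt), standardized to
    unit empirical variance and multiplied by the square root of its budget
    share.  Y is the exact sum of the returned scaled components, has unit
    empirical variance, and every realized share equals its budget to
    numerical precision.  ``orthogonalize=False`` skips the residualization
    (shares then only approximate the budget when channels are correlated).
    """
    fr = spec.fractions()
    n = len(next(iter(raw.values())))
    scaled: dict[str, np.ndarray] = {}
    basis: list[np.ndarray] = []
    for name in COMPONENT_ORDER:
        share = fr[name]
        if share == 0.0:
            scaled[name] = np.zeros(n)
            continue
        v = raw[name] - raw[name].mean()
        if orthogonalize:
            for b in basis:
                v = v - (v @ b) / (b @ b) * b
        sd = float(np.std(v))
        if sd < 1e-10 * max(1.0, float(np.std(raw[name]))):
            raise ValueError(
                f"component {name!r} is collinear with earlier components "
                "but has a positive budget"
            )
        v = v / sd * np.sqrt(share)
        scaled[name] = v
        basis.append(v)
    y = np.sum(list(scaled.values()), axis=0)
    return y, scaled


def simulate_phenotype(
    cohort: Cohort,
    spec: PhenotypeSpec,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
    kinship_chol: np.ndarray | None = None,
    orthogonalize: bool = True,
) -> PhenotypeTable:
    """Full phenotype simulation for one spec on one cohort.

    Child seeds for covariates, the causal set and the random components are
    derived from ``seed`` together with the spec label and replicate, so
    replicates get distinct causal sets while staying reproducible.
    """
    tag = (spec.population, spec.kind, spec.ancestry_of_interest, spec.replicate)
    if covariates is None:
        covariates = make_covariates(
            cohort.n_individuals, child_seed(seed, "covariates", *tag[:1])
        )
    causal = draw_causal_set(cohort, spec, child_seed(seed, "causal", *tag))
    raw = build_components(
        cohort,
        causal,
        spec,
        covariates,
        seed=child_seed(seed, "components", *tag),
        kinship_chol=kinship_chol,
    )
    y, scaled = scale_and_combine(raw, spec, orthogonalize=orthogonalize)
    return PhenotypeTable(
        spec=spec,
        y=y,
        age=covariates["age"].to_numpy(),
        sex=covariates["sex"].to_numpy(),
        components=scaled,
        causal=causal,
        seed=seed,
    )
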