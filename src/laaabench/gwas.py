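"""Per-site linear-regression association testing for admixed cohorts.

Five nested ordinary-least-squares models are fitted at every site, all with
age and sex as demographic covariates (E1, E2):

* ``STANDARD`` — allelic dosage only: E(Y) = a0 + a1 E1 + a2 E2 + b X_x
* ``GA``       — adds global-ancestry proportions P (smallest component
  dropped to avoid collinearity with the intercept)
* ``LA``       — admixture mapping: ancestry dosage g X^i instead of X_x
* ``APA``      — allelic + ancestry dosage (b X_x + g X^i)
* ``LAAA``     — local ancestry adjusted allelic: adds the interaction
  dosage e X^i_x (copies of the major allele carried on an
  ancestry-of-interest haplotype)

Dosages are coded as counts of the cohort **major** allele: X_x in {0,1,2}
copies of the major allele, X^i copies of ancestry *i*, X^i_x copies of the
major allele on an ancestry-*i* background (so X^i_x <= min(X_x, X^i)).

Each model's headline p-value is the test of its genetic terms: the
marginal t-test of b (STANDARD, GA) or g (LA), and the joint nested F-test
of (b, g) for APA and (b, g, e) for LAAA.  Marginal per-term p-values are
always reported as well, supporting two-step source attribution.

The genome scanner uses the Frisch-Waugh-Lovell decomposition (covariates
projected out once, then per-site small solves, batched over sites), which
is algebraically identical to fitting the full design at every site; the
single-site :func:`fit_site` goes through :mod:`statsmodels` and reports
every term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import Cohort, LocalAncestryMatrix

__all__ = [
    "MODELS",
    "GENOMEWIDE_ALPHA",
    "ModelSpec",
    "TermEstimate",
    "AssociationRecord",
    "maf_filter",
    "major_allele_mask",
    "build_dosages",
    "select_ga_covariates",
    "make_design",
    "fit_site",
    "genome_scan",
    "ScanResult",
]

MODELS = ("STANDARD", "GA", "LA", "APA", "LAAA")
GENOMEWIDE_ALPHA = 5e-8

# genetic regressors per model, in design order
_GENETIC_TERMS: dict[str, tuple[str, ...]] = {
    "STANDARD": ("beta",),
    "GA": ("beta",),
    "LA": ("gamma",),
    "APA": ("beta", "gamma"),
    "LAAA": ("beta", "gamma", "eta"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which regression model to fit, and for which ancestry of interest."""

    model: str
    ancestry_of_interest: str | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.uses_local_ancestry and self.ancestry_of_interest is None:
            raise ValueError(f"{self.model} model needs an ancestry of interest")

    @property
    def uses_global_ancestry(self) -> bool:
        return self.model != "STANDARD"

    @property
    def uses_local_ancestry(self) -> bool:
        return self.model in ("LA", "APA", "LAAA")

    @property
    def genetic_terms(self) -> tuple[str, ...]:
        return _GENETIC_TERMS[self.model]


@dataclass(frozen=True)
class TermEstimate:
    term: str
    estimate: float
    se: float
    t: float
    p: float


@dataclass
class AssociationRecord:
    """Single-site fit: per-term estimates plus the model's headline p-value."""

    site: int
    chrom: str
    pos: int
    snp_id: str
    model: str
    ancestry: str | None
    terms: dict[str, TermEstimate]
    joint_p: float
    n: int
    ok: bool = True
    note: str = ""


def maf_filter(genotypes: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """Mask of sites whose minor-allele frequency is >= ``threshold``.

    The convention is *strictly less than* is removed: a site with MAF
    exactly at the threshold is kept.  Monomorphic sites (MAF 0) are always
    removed.
    """
    freq1 = np.asarray(genotypes, dtype=float).mean(axis=0) / 2.0
    maf = np.minimum(freq1, 1.0 - freq1)
    return maf >= threshold


def major_allele_mask(cohort: Cohort, site_mask: np.ndarray | None = None) -> np.ndarray:
    """True where internal allele 1 (the reference base) is the major allele.

    The major allele is defined on the analysis cohort (after any filtering,
    which does not change per-site frequencies).  An exact 50/50 tie goes to
    the alphabetically first base, which is the reference base here.
    """
    freq1 = cohort.allele1_frequency()
    del site_mask  # frequencies are per-site; mask does not affect them
    return freq1 >= 0.5


def build_dosages(
    cohort: Cohort,
    local: LocalAncestryMatrix,
    ancestry: str,
    sites: np.ndarray | None = None,
    major1: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-individual dosage triples (X_x, X^i, X^i_x) at the given sites.

    Computed per haplotype as indicator AND of (allele == major) and
    (label == ancestry), summed over the two haplotypes, which guarantees
    X^i_x <= min(X_x, X^i) with all values in {0, 1, 2}.
    """
    if ancestry not in local.sources:
        raise ValueError(f"unknown ancestry {ancestry!r}")
    if local.codes.shape != cohort.haplotypes.shape:
        raise ValueError("local ancestry matrix does not match cohort haplotypes")
    if major1 is None:
        major1 = major_allele_mask(cohort)
    hap = cohort.haplotypes
    codes = local.codes
    if sites is not None:
        hap = hap[:, sites]
        codes = codes[:, sites]
        major1 = major1[sites]
    k = local.sources.index(ancestry)
    is_major = hap == major1.astype(np.uint8)[None, :]
    is_anc = codes == k
    both = is_major & is_anc
    x_x = (is_major[0::2].astype(np.int8) + is_major[1::2]).astype(np.int8)
    x_i = (is_anc[0::2].astype(np.int8) + is_anc[1::2]).astype(np.int8)
    x_ix = (both[0::2].astype(np.int8) + both[1::2]).astype(np.int8)
    return x_x, x_i, x_ix


def select_ga_covariates(global_table: pd.DataFrame) -> pd.DataFrame:
    """Global-ancestry covariate columns with the smallest component dropped.

    Proportions sum to 1 per individual, so one column must be excluded to
    keep the design full-rank alongside the intercept; the component with
    the smallest cohort mean is dropped (ties broken by column order).
    """
    means = global_table.mean(axis=0)
    drop = means.idxmin()  # first minimum in column order
    return global_table.drop(columns=[drop])


def make_design(
    covariates: pd.DataFrame,
    spec: ModelSpec,
    global_table: pd.DataFrame | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Non-genetic design block: intercept, age, sex, and P columns if used."""
    n = len(covariates)
    cols = [np.ones(n), covariates["age_std"].to_numpy(), covariates["sex"].to_numpy()]
    names = ["intercept", "age", "sex"]
    if spec.uses_global_ancestry:
        if global_table is None:
            raise ValueError(f"{spec.model} model needs a global-ancestry table")
        kept = select_ga_covariates(global_table)
        for c in kept.columns:
            cols.append(kept[c].to_numpy())
            names.append(f"P_{c}")
    return np.column_stack(cols), names


def _genetic_columns(
    spec: ModelSpec, x_x: np.ndarray, x_i: np.ndarray, x_ix: np.ndarray
) -> dict[str, np.ndarray]:
    cols = {"beta": x_x, "gamma": x_i, "eta": x_ix}
    return {t: cols[t].astype(float) for t in spec.genetic_terms}


def fit_site(
    y: np.ndarray,
    covariates: pd.DataFrame,
    dosages: tuple[np.ndarray, np.ndarray, np.ndarray],
    spec: ModelSpec,
    global_table: pd.DataFrame | None = None,
    site_info: tuple[int, str, int, str] = (0, "chr1", 0, "snp0"),
) -> AssociationRecord:
    """Fit one site with the full design through statsmodels OLS.

    Reports every term (intercept, age, sex, P columns, genetic terms) and
    the model's headline p-value: the marginal t-test of the single genetic
    term for STANDARD/GA/LA, or the nested F-test of all genetic terms for
    APA/LAAA.  A rank-deficient genetic block flags the record instead of
    raising.
    """
    import statsmodels.api as sm

    x_x, x_i, x_ix = (np.asarray(d, dtype=float).ravel() for d in dosages)
    z, names = make_design(covariates, spec, global_table)
    gen = _genetic_columns(spec, x_x, x_i, x_ix)
    design = np.column_stack([z] + list(gen.values()))
    all_names = names + list(gen)
    site, chrom, pos, snp_id = site_info

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        return AssociationRecord(
            site=site, chrom=chrom, pos=pos, snp_id=snp_id, model=spec.model,
            ancestry=spec.ancestry_of_interest, terms={}, joint_p=float("nan"),
            n=len(y), ok=False, note="rank-deficient design",
        )
    fit = sm.OLS(y, design).fit()
    terms = {
        name: TermEstimate(
            term=name,
            estimate=float(fit.params[j]),
            se=float(fit.bse[j]),
            t=float(fit.tvalues[j]),
            p=float(fit.pvalues[j]),
        )
        for j, name in enumerate(all_names)
    }
    k = len(gen)
    if k == 1:
        joint_p = terms[spec.genetic_terms[0]].p
    else:
        restriction = np.zeros((k, design.shape[1]))
        for row, term in enumerate(spec.genetic_terms):
            restriction[row, all_names.index(term)] = 1.0
        joint_p = float(fit.f_test(restriction).pvalue)
    return AssociationRecord(
        site=site, chrom=chrom, pos=pos, snp_id=snp_id, model=spec.model,
        ancestry=spec.ancestry_of_interest, terms=terms, joint_p=joint_p, n=len(y),
    )


@dataclass
class ScanResult:
    """Genome-scan output: one row per kept site plus the significant set."""

    table: pd.DataFrame
    significant: np.ndarray  # site indices with joint_p < threshold
    model: str
    ancestry: str | None
    threshold: float
    skipped: list[int] = field(default_factory=list)

    @property
    def n_significant(self) -> int:
        return len(self.significant)


def genome_scan(
    y: np.ndarray,
    covariates: pd.DataFrame,
    cohort: Cohort,
    local: LocalAncestryMatrix,
    spec: ModelSpec,
    global_table: pd.DataFrame | None = None,
    threshold: float = GENOMEWIDE_ALPHA,
    site_mask: np.ndarray | None = None,
) -> ScanResult:
    """Associate every kept site with the phenotype under one model.

    ``site_mask`` (default: MAF >= 0.05) selects analysis sites.  The model's
    covariate block is projected out of the phenotype and the genetic dosage
    columns once (Frisch-Waugh-Lovell), then per-site normal equations are
    solved batched over sites; estimates, SEs, t/F statistics and p-values
    are identical to fitting the full design per site.  Sites whose genetic
    block is collinear after projection are flagged (``ok = False``),
    excluded from the significant set, and listed in ``skipped``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if site_mask is None:
        site_mask = maf_filter(cohort.genotypes)
    kept = np.flatnonzero(site_mask)
    m = len(kept)

    anc = spec.ancestry_of_interest or local.sources[0]
    major1 = major_allele_mask(cohort)
    x_x, x_i, x_ix = build_dosages(cohort, local, anc, kept, major1)
    gen = _genetic_columns(spec, x_x.T, x_i.T, x_ix.T)  # (m, n) each
    terms = list(gen)
    k = len(terms)

    z, _ = make_design(covariates, spec, global_table)
    q, _r = np.linalg.qr(z)
    p0 = z.shape[1]

    def residualize(v: np.ndarray) -> np.ndarray:
        # v: (..., n) -> residual of each row against the covariate block
        return v - (v @ q) @ q.T

    y_r = residualize(y)
    g_r = np.stack([residualize(gen[t]) for t in terms], axis=-1)  # (m, n, k)

    gtg = np.einsum("mnk,mnl->mkl", g_r, g_r)
    gty = np.einsum("mnk,n->mk", g_r, y_r)
    yty = float(y_r @ y_r)

    # collinear/degenerate genetic blocks: near-zero smallest eigenvalue
    eig = np.linalg.eigvalsh(gtg)
    scale = np.maximum(np.trace(gtg, axis1=1, axis2=2), 1e-300)
    bad = eig[:, 0] <= 1e-10 * scale
    gtg_safe = gtg.copy()
    gtg_safe[bad] = np.eye(k)

    coef = np.linalg.solve(gtg_safe, gty[..., None])[..., 0]
    inv = np.linalg.inv(gtg_safe)
    rss = yty - np.einsum("mk,mk->m", coef, gty)
    df = n - p0 - k
    if df <= 0:
        raise ValueError("not enough observations for the model")
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(np.maximum(np.einsum("mkk->mk", inv), 0.0) * sigma2[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = coef / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df)

    if k == 1:
        joint_p = pval[:, 0]
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            fstat = (yty - rss) / k / sigma2
        joint_p = stats.f.sf(fstat, k, df)
    joint_p = np.where(bad, np.nan, joint_p)

    data: dict[str, object] = {
        "site": kept,
        "chrom": cohort.sites["chrom"].to_numpy()[kept],
        "pos": cohort.sites["pos"].to_numpy()[kept],
        "id": cohort.sites["id"].to_numpy()[kept],
        "model": spec.model,
        "ancestry": anc if spec.uses_local_ancestry else "",
    }
    for j, t in enumerate(terms):
        data[t] = np.where(bad, np.nan, coef[:, j])
        data[f"{t}_se"] = np.where(bad, np.nan, se[:, j])
        data[f"{t}_p"] = np.where(bad, np.nan, pval[:, j])
    data["joint_p"] = joint_p
    data["n"] = n
    data["ok"] = ~bad
    table = pd.DataFrame(data)

    significant = kept[np.nan_to_num(joint_p, nan=1.0) < threshold]
    return ScanResult(
        table=table,
        significant=significant,
        model=spec.model,
        ancestry=spec.ancestry_of_interest,
        threshold=threshold,
        skipped=kept[bad].tolist(),
    )
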