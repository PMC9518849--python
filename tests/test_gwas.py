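from itertools import product

import numpy as np
import pandas as pd
import pytest

import laaabench as lb
from laaabench.genotypes import LocalAncestryMatrix
from laaabench.gwas import (
    ModelSpec,
    build_dosages,
    fit_site,
    genome_scan,
    maf_filter,
    major_allele_mask,
    make_design,
    select_ga_covariates,
)

from conftest import ols_oracle


class TestMafFilter:
    def test_boundary_convention(self):
        # rows chosen so site MAFs are 0.04, exactly 0.05, and 0.5
        geno = np.zeros((50, 3), dtype=np.int8)
        geno[:2, 0] = [2, 2]  # freq1 = 4/100 -> MAF 0.04, removed
        geno[:5, 1] = 2  # freq1 = 0.05 -> kept (strictly-less removal)
        geno[:25, 2] = 2  # freq1 = 0.5
        mask = maf_filter(geno, threshold=0.05)
        assert mask.tolist() == [False, True, True]

    def test_monomorphic_removed(self):
        geno = np.full((20, 2), 2, dtype=np.int8)
        geno[:, 1] = np.random.default_rng(0).integers(0, 3, 20)
        mask = maf_filter(geno)
        assert not mask[0]


class TestDosages:
    def test_exhaustive_two_haplotype_state_space(self):
        # every (allele, label) pair combination on two haplotypes
        states = list(product([0, 1], repeat=2))  # allele per haplotype
        labels = list(product([0, 1], repeat=2))  # ancestry-i indicator
        for (a1, a2), (l1, l2) in product(states, labels):
            cohort = _toy_cohort(np.array([[a1], [a2]], dtype=np.uint8),
                                 np.array([[l1], [l2]], dtype=np.int8))
            # force allele 1 major regardless of the toy's frequencies
            x_x, x_i, x_ix = build_dosages(
                cohort, cohort.truth, "i", major1=np.array([True])
            )
            expected_xx = (a1 == 1) + (a2 == 1)
            expected_xi = l1 + l2
            expected_xix = (a1 == 1 and l1 == 1) + (a2 == 1 and l2 == 1)
            assert (x_x[0, 0], x_i[0, 0], x_ix[0, 0]) == (
                expected_xx, expected_xi, expected_xix
            )
            assert x_ix[0, 0] <= min(x_x[0, 0], x_i[0, 0])

    @pytest.mark.parametrize(
        "haps,expected",
        [
            ([(1, 1), (1, 1)], (2, 2, 2)),  # (major on i, major on i)
            ([(1, 1), (0, 0)], (1, 1, 1)),  # (major on i, minor on j)
            ([(1, 0), (0, 1)], (1, 1, 0)),  # major on j, minor on i
        ],
    )
    def test_worked_triples(self, haps, expected):
        alleles = np.array([[haps[0][0]], [haps[1][0]]], dtype=np.uint8)
        labels = np.array([[haps[0][1]], [haps[1][1]]], dtype=np.int8)
        cohort = _toy_cohort(alleles, labels)
        x_x, x_i, x_ix = build_dosages(
            cohort, cohort.truth, "i", major1=np.array([True])
        )
        assert (x_x[0, 0], x_i[0, 0], x_ix[0, 0]) == expected

    def test_unknown_ancestry_rejected(self, nama3_small):
        _, cohort = nama3_small
        with pytest.raises(ValueError, match="unknown ancestry"):
            build_dosages(cohort, cohort.truth, "YRI")


def _toy_cohort(hap_alleles, hap_labels):
    """2-haplotype (1 individual), arbitrary-site toy cohort."""
    m = hap_alleles.shape[1]
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(m) * 10, "id": [f"s{j}" for j in range(m)]}
    )
    return lb.Cohort(
        preset_name="toy",
        sources=("j", "i"),
        sites=sites,
        haplotypes=hap_alleles,
        truth=LocalAncestryMatrix(hap_labels, ("j", "i")),
        samples=["ind0"],
    )


class TestGlobalAncestryCovariates:
    def test_three_way_drops_smallest_component(self, nama3_small):
        _, cohort = nama3_small
        table = lb.global_from_local(cohort.truth)
        kept = select_ga_covariates(table)
        # LWK (0.10) is the smallest mean component in the three-way preset
        assert set(kept.columns) == {"GBR", "NAMA"}

    def test_five_way_drops_smallest_component(self, sac5_small):
        _, cohort = sac5_small
        table = lb.global_from_local(cohort.truth)
        kept = select_ga_covariates(table)
        assert set(kept.columns) == {"GBR", "MSL", "NAMA", "GIH"}

    def test_tie_break_by_column_order(self):
        table = pd.DataFrame({"B": [0.5, 0.5], "A": [0.5, 0.5]})
        kept = select_ga_covariates(table)
        assert list(kept.columns) == ["A"]  # first column dropped on a tie


class TestFitSite:
    def test_standard_model_matches_normal_equations(self):
        # 6-observation hand dataset
        y = np.array([1.2, -0.5, 0.3, 2.0, -1.1, 0.7])
        age = np.array([25.0, 40.0, 33.0, 60.0, 51.0, 29.0])
        sex = np.array([0, 1, 0, 1, 1, 0])
        x = np.array([0, 1, 2, 2, 0, 1], dtype=float)
        cov = pd.DataFrame({"age": age, "sex": sex})
        cov["age_std"] = (age - age.mean()) / age.std()
        cov["sex_std"] = (sex - sex.mean()) / sex.std()
        rec = fit_site(y, cov, (x, x * 0, x * 0), ModelSpec("STANDARD"))
        design = np.column_stack(
            [np.ones(6), cov["age_std"], sex, x]
        )
        oracle = ols_oracle(design, y)
        assert rec.terms["beta"].estimate == pytest.approx(oracle["beta"][3], abs=1e-10)
        assert rec.terms["beta"].se == pytest.approx(oracle["se"][3], abs=1e-10)
        assert rec.terms["beta"].p == pytest.approx(oracle["p"][3], abs=1e-10)

    def test_rank_deficient_site_flagged(self, nama3_small, nama3_covariates):
        _, cohort = nama3_small
        n = cohort.n_individuals
        y = np.random.default_rng(1).standard_normal(n)
        x = np.ones(n)  # constant dosage -> collinear with intercept
        rec = fit_site(y, nama3_covariates, (x, x * 0, x * 0), ModelSpec("STANDARD"))
        assert not rec.ok
        assert np.isnan(rec.joint_p)


class TestOlsOracleEquivalence:
    def test_fifty_random_small_designs(self):
        # n = 30, 2 covariates + intercept + 2 genetic regressors
        rng = np.random.default_rng(42)
        for trial in range(50):
            n = 30
            age = rng.uniform(20, 70, n)
            sex = rng.integers(0, 2, n).astype(float)
            cov = pd.DataFrame({"age": age, "sex": sex})
            cov["age_std"] = (age - age.mean()) / age.std()
            cov["sex_std"] = (sex - sex.mean()) / (sex.std() or 1.0)
            x_x = rng.integers(0, 3, n).astype(float)
            x_i = rng.integers(0, 3, n).astype(float)
            x_ix = np.minimum(x_x, x_i)
            y = rng.standard_normal(n) + 0.3 * x_x
            p_i = rng.uniform(0.1, 0.9, n)
            gtab = pd.DataFrame({"i": p_i, "j": 1.0 - p_i})
            rec = fit_site(y, cov, (x_x, x_i, x_ix), ModelSpec("APA", "i"),
                           global_table=gtab)
            p_col = select_ga_covariates(gtab).iloc[:, 0].to_numpy()
            design = np.column_stack(
                [np.ones(n), cov["age_std"], sex, p_col, x_x, x_i]
            )
            oracle = ols_oracle(design, y, joint_cols=[4, 5])
            assert rec.terms["beta"].estimate == pytest.approx(
                oracle["beta"][4], abs=1e-8
            )
            assert rec.terms["gamma"].se == pytest.approx(oracle["se"][5], abs=1e-8)
            assert rec.terms["beta"].p == pytest.approx(oracle["p"][4], abs=1e-8)
            assert rec.joint_p == pytest.approx(oracle["joint_p"], abs=1e-8)


@pytest.fixture(scope="module")
def scan_setup(nama3_small, nama3_covariates):
    _, cohort = nama3_small
    gtab = lb.global_from_local(cohort.truth, cohort.samples)
    rng = np.random.default_rng(7)
    y = rng.standard_normal(cohort.n_individuals)
    return cohort, nama3_covariates, gtab, y


class TestGenomeScan:
    @pytest.mark.parametrize("model", ["STANDARD", "GA", "LA", "APA", "LAAA"])
    def test_scan_matches_single_site_fit(self, scan_setup, model):
        cohort, cov, gtab, y = scan_setup
        spec = ModelSpec(model, "NAMA")
        scan = genome_scan(y, cov, cohort, cohort.truth, spec, global_table=gtab)
        ok = scan.table[scan.table.ok]
        for _, row in ok.iloc[[10, 400, -1]].iterrows():
            site = int(row.site)
            dos = build_dosages(cohort, cohort.truth, "NAMA", np.array([site]))
            rec = fit_site(y, cov, dos, spec, global_table=gtab)
            for term in spec.genetic_terms:
                assert row[term] == pytest.approx(rec.terms[term].estimate, abs=1e-8)
                assert row[f"{term}_p"] == pytest.approx(rec.terms[term].p, abs=1e-8)
            assert row.joint_p == pytest.approx(rec.joint_p, abs=1e-8)

    def test_nested_models_never_increase_rss(self, scan_setup):
        # residual variance shrinks (weakly) as regressors are added
        cohort, cov, gtab, y = scan_setup
        import statsmodels.api as sm

        site = int(genome_scan(
            y, cov, cohort, cohort.truth, ModelSpec("STANDARD"), global_table=gtab
        ).table.site.iloc[123])
        dos = build_dosages(cohort, cohort.truth, "NAMA", np.array([site]))
        x_x, x_i, x_ix = (d.astype(float).ravel() for d in dos)
        z, _ = make_design(cov, ModelSpec("GA"), gtab)
        rss = []
        for cols in ([x_x], [x_x, x_i], [x_x, x_i, x_ix]):
            fit = sm.OLS(y, np.column_stack([z] + cols)).fit()
            rss.append(fit.ssr)
        assert rss[0] >= rss[1] >= rss[2]

    def test_null_phenotype_type_one_error_calibrated(self, scan_setup):
        cohort, cov, gtab, _ = scan_setup
        rng = np.random.default_rng(8)
        rates = []
        for _ in range(10):
            y = rng.standard_normal(cohort.n_individuals)
            scan = genome_scan(y, cov, cohort, cohort.truth, ModelSpec("STANDARD"))
            rates.append((scan.table.beta_p < 0.05).mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.01)

    def test_threshold_strictly_less(self, scan_setup):
        cohort, cov, gtab, y = scan_setup
        scan = genome_scan(y, cov, cohort, cohort.truth, ModelSpec("STANDARD"))
        joint = scan.table.set_index("site").joint_p
        boundary = joint.min()
        scan2 = genome_scan(
            y, cov, cohort, cohort.truth, ModelSpec("STANDARD"),
            threshold=float(boundary),
        )
        assert int(joint.idxmin()) not in set(scan2.significant.tolist())

    def test_deterministic_results(self, scan_setup):
        cohort, cov, gtab, y = scan_setup
        spec = ModelSpec("LAAA", "NAMA")
        s1 = genome_scan(y, cov, cohort, cohort.truth, spec, global_table=gtab)
        s2 = genome_scan(y, cov, cohort, cohort.truth, spec, global_table=gtab)
        pd.testing.assert_frame_equal(s1.table, s2.table)

    def test_interaction_signal_attributed_to_eta(self, nama3_small,
                                                  nama3_covariates):
        # phenotype driven purely by an ancestry-specific allelic effect:
        # at the causal site, eta should carry the smallest genetic p-value
        _, cohort = nama3_small
        cov = nama3_covariates
        gtab = lb.global_from_local(cohort.truth, cohort.samples)
        kept = np.flatnonzero(maf_filter(cohort.genotypes))
        hits = 0
        trials = 40
        rng = np.random.default_rng(9)
        x_all = build_dosages(cohort, cohort.truth, "NAMA", kept)
        var_ix = x_all[2].astype(float).var(axis=0)
        candidates = kept[var_ix > 0.2]
        for t in range(trials):
            site = int(rng.choice(candidates))
            dos = build_dosages(cohort, cohort.truth, "NAMA", np.array([site]))
            y = 1.2 * dos[2].astype(float).ravel() + rng.standard_normal(
                cohort.n_individuals
            )
            rec = fit_site(y, cov, dos, ModelSpec("LAAA", "NAMA"), global_table=gtab)
            ps = {t2: rec.terms[t2].p for t2 in ("beta", "gamma", "eta")}
            if min(ps, key=ps.get) == "eta":
                hits += 1
        assert hits / trials >= 0.5


class TestModelSpec:
    def test_local_models_need_ancestry(self):
        with pytest.raises(ValueError, match="ancestry"):
            ModelSpec("LAAA")

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            ModelSpec("MIXED")

    def test_global_ancestry_usage_flags(self):
        assert not ModelSpec("STANDARD").uses_global_ancestry
        assert ModelSpec("GA").uses_global_ancestry
        assert ModelSpec("LAAA", "NAMA").uses_local_ancestry
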