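import numpy as np
import pytest

import laaabench as lb


@pytest.fixture(scope="session")
def nama3_small():
    """Small three-way cohort shared across tests (120 ind x 2500 sites)."""
    preset = lb.nama3(n_admixed=120, n_reference_per_source=150, n_sites=2500)
    return preset, lb.simulate_cohort(preset, seed=11)


@pytest.fixture(scope="session")
def sac5_small():
    """Small five-way cohort shared across tests (120 ind x 2500 sites)."""
    preset = lb.sac5(n_admixed=120, n_reference_per_source=150, n_sites=2500)
    return preset, lb.simulate_cohort(preset, seed=13)


@pytest.fixture(scope="session")
def nama3_covariates(nama3_small):
    _, cohort = nama3_small
    return lb.make_covariates(cohort.n_individuals, seed=7)


def ols_oracle(design: np.ndarray, y: np.ndarray, joint_cols=None):
    """Independent normal-equations least-squares reference.

    Solves beta = (X'X)^-1 X'y explicitly and derives SEs, t-based p-values
    and (optionally) the nested F-test of the columns in ``joint_cols``.
    """
    from scipy import stats

    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = design.shape
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = xtx_inv @ design.T @ y
    resid = y - design @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    tval = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df)
    out = {"beta": beta, "se": se, "t": tval, "p": pval, "rss": rss, "df": df}
    if joint_cols is not None:
        keep = [j for j in range(p) if j not in set(joint_cols)]
        x0 = design[:, keep]
        b0 = np.linalg.inv(x0.T @ x0) @ x0.T @ y
        rss0 = float((y - x0 @ b0) @ (y - x0 @ b0))
        k = len(joint_cols)
        fstat = (rss0 - rss) / k / sigma2
        out["joint_f"] = fstat
        out["joint_p"] = float(stats.f.sf(fstat, k, df))
    return out
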