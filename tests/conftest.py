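import math

import numpy as np
import pandas as pd
import pytest

from mrmediate.io import CANONICAL_COLUMNS, GwasTable, HarmonizedSet


def make_table(trait_id, rows, trait_type="quantitative", trait_level="none"):
    """Build a GwasTable from compact row tuples.

    Row: (variant_id, chrom, pos, ea, oa, eaf, beta, se, pvalue, n).
    """
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    return GwasTable(trait_id, df, trait_type, trait_level)


def make_harmonized(beta_exp, beta_out, se_out, se_exp=None, ids=None):
    beta_exp = np.asarray(beta_exp, float)
    if se_exp is None:
        se_exp = np.full_like(beta_exp, 1e-6)
    if ids is None:
        ids = [f"rs{i}" for i in range(len(beta_exp))]
    return HarmonizedSet(
        exposure_id="exp",
        outcome_id="out",
        variant_id=np.array(ids, dtype=object),
        beta_exp=beta_exp,
        se_exp=np.asarray(se_exp, float),
        beta_out=np.asarray(beta_out, float),
        se_out=np.asarray(se_out, float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def wls_normal_equations(X, y, w):
    """Independent weighted least squares via the normal equations.

    Returns (coef, se) where se uses the estimated residual scale
    (weighted RSS / (n - p)), i.e. the plain WLS covariance.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    W = np.diag(np.asarray(w, float))
    xtwx = X.T @ W @ X
    coef = np.linalg.solve(xtwx, X.T @ W @ y)
    resid = y - X @ coef
    n, p = X.shape
    scale = float(resid @ W @ resid) / (n - p) if n > p else math.nan
    cov = scale * np.linalg.inv(xtwx)
    return coef, np.sqrt(np.diag(cov))
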