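"""Heterogeneity, pleiotropy and influence diagnostics.

Cochran's Q about the IVW or Egger fit quantifies between-instrument
heterogeneity (a symptom of pleiotropy); the Egger intercept tests for
*directional* pleiotropy; leave-one-out refits expose single influential
instruments. Detected heterogeneity switches the primary IVW to
multiplicative random effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import IVW, InsufficientInstrumentsError, MREgger, _ivw_beta
from .io import HarmonizedSet


@dataclass
class HeterogeneityResult:
    method: str  # ivw | egger
    Q: float
    df: int
    pvalue: float


@dataclass
class PleiotropyResult:
    intercept: float
    se: float
    pvalue: float


@dataclass
class LeaveOneOutResult:
    """One IVW refit per excluded variant, with influence flags.

    A row is flagged influential when dropping that variant flips the
    sign of the full-set estimate or moves it across p = 0.05.
    """

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame  # columns: excluded, beta, se, pvalue, influential
    full_beta: float
    full_pvalue: float

    @property
    def any_influential(self) -> bool:
        return bool(self.table["influential"].any())


def cochran_q(h: HarmonizedSet, method: str = "ivw") -> HeterogeneityResult:
    """Weighted residual sum of squares about the chosen fit.

    df = k-1 for the through-origin IVW fit, k-2 for Egger (one more
    free parameter); the p-value is the upper chi-square tail.
    """
    if method == "ivw":
        if h.k < 2:
            raise InsufficientInstrumentsError("Cochran's Q (ivw) needs k >= 2")
        fit = IVW(mode="fixed").fit(h)
    elif method == "egger":
        if h.k < 3:
            raise InsufficientInstrumentsError("Cochran's Q (egger) needs k >= 3")
        fit = MREgger().fit(h)
    else:
        raise ValueError(f"unknown method {method!r}")
    q, df = fit.Q_, fit.Q_df_
    p = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(method=method, Q=float(q), df=int(df), pvalue=max(p, np.finfo(float).tiny))


def choose_ivw_mode(het: HeterogeneityResult, alpha: float = 0.05) -> str:
    """Random effects when heterogeneity is detected (p < alpha), else fixed."""
    if het.method != "ivw":
        raise ValueError("mode choice must be based on the IVW heterogeneity test")
    return "multiplicative_random" if het.pvalue < alpha else "fixed"


def egger_intercept_test(h: HarmonizedSet) -> PleiotropyResult:
    """Directional-pleiotropy test: the MR-Egger intercept with t(k-2) p."""
    fit = MREgger().fit(h)
    return PleiotropyResult(
        intercept=fit.intercept_, se=fit.intercept_se_, pvalue=fit.intercept_pvalue_
    )


def leave_one_out(h: HarmonizedSet, mode: str = "fixed") -> LeaveOneOutResult:
    """Refit IVW k times, excluding one instrument each time."""
    if h.k < 3:
        raise InsufficientInstrumentsError("leave-one-out needs k >= 3")
    full = IVW(mode=mode).fit(h)
    rows = []
    for vid in h.variant_id:
        sub = h.drop([vid])
        fit = IVW(mode=mode).fit(sub)
        sign_flip = np.sign(fit.beta_) != np.sign(full.beta_) and fit.beta_ != 0
        crossed = (fit.pvalue_ < 0.05) != (full.pvalue_ < 0.05)
        rows.append(
            {
                "excluded": vid,
                "beta": fit.beta_,
                "se": fit.se_,
                "pvalue": fit.pvalue_,
                "influential": bool(sign_flip or crossed),
            }
        )
    return LeaveOneOutResult(
        exposure_id=h.exposure_id,
        outcome_id=h.outcome_id,
        table=pd.DataFrame(rows),
        full_beta=full.beta_,
        full_pvalue=full.pvalue_,
    )


def sensitivity_row(h: HarmonizedSet) -> dict:
    """One row of the sensitivity report: Q (IVW & Egger) + Egger intercept."""
    row = {"exposure_id": h.exposure_id, "outcome_id": h.outcome_id, "k": h.k}
    het_ivw = cochran_q(h, "ivw")
    row.update(Q_ivw=het_ivw.Q, Q_ivw_df=het_ivw.df, Q_ivw_p=het_ivw.pvalue)
    row["Q_ivw_star"] = het_ivw.pvalue < 0.05
    if h.k >= 3:
        het_egger = cochran_q(h, "egger")
        pleio = egger_intercept_test(h)
        row.update(
            Q_egger=het_egger.Q,
            Q_egger_df=het_egger.df,
            Q_egger_p=het_egger.pvalue,
            Q_egger_star=het_egger.pvalue < 0.05,
            intercept=pleio.intercept,
            intercept_se=pleio.se,
            intercept_p=pleio.pvalue,
            intercept_star=pleio.pvalue < 0.05,
        )
    else:
        row.update(
            Q_egger=np.nan, Q_egger_df=0, Q_egger_p=np.nan, Q_egger_star=False,
            intercept=np.nan, intercept_se=np.nan, intercept_p=np.nan,
            intercept_star=False,
        )
    return row
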