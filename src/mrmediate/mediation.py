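"""Two-step MR mediation: product-of-coefficients decomposition.

Three univariable MR estimates feed each decomposition: the exposure's
effect on the mediator (beta1), the mediator's effect on the outcome
(beta2, estimated with the mediator's own instruments), and the
exposure's total effect on the outcome (beta_all). The mediated
(indirect) effect is beta1*beta2, the direct effect is
beta_all - beta1*beta2, and the proportion mediated is
beta1*beta2 / beta_all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .estimators import MrEstimate
from .io import ConfigurationError


class UndefinedProportionError(ZeroDivisionError):
    """The total effect is zero, so the mediated proportion is undefined."""


@dataclass
class MediationResult:
    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta1: float
    se1: float
    pvalue1: float
    beta2: float
    se2: float
    pvalue2: float
    beta_all: float
    se_all: float
    pvalue_all: float
    mediated: float
    direct: float
    proportion: float
    se_mediated: float
    ci_mediated: tuple[float, float]
    sign_consistent: bool = True

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion

    def to_row(self) -> dict:
        return {
            "exposure_id": self.exposure_id,
            "mediator_id": self.mediator_id,
            "outcome_id": self.outcome_id,
            "beta1": self.beta1,
            "se1": self.se1,
            "beta2": self.beta2,
            "se2": self.se2,
            "beta_all": self.beta_all,
            "se_all": self.se_all,
            "mediated": self.mediated,
            "se_mediated": self.se_mediated,
            "direct": self.direct,
            "proportion_pct": self.proportion_pct,
            "sign_consistent": self.sign_consistent,
        }


@dataclass
class MediationScreenConfig:
    alpha_step1: float = 0.05
    alpha_step2: float = 0.05
    alpha_total: float = 0.05
    require_sign_consistency: bool = True

    def __post_init__(self):
        for a in (self.alpha_step1, self.alpha_step2, self.alpha_total):
            if not (0.0 < a < 1.0):
                raise ConfigurationError("mediation alphas must be in (0,1)")


def two_step_mediation(
    est1: MrEstimate, est2: MrEstimate, est_all: MrEstimate
) -> MediationResult:
    """Decompose the total effect using the product of coefficients.

    ``se_mediated`` is the delta-method SE assuming independence of the
    two steps (they come from non-overlapping GWAS):
    sqrt(beta2^2 se1^2 + beta1^2 se2^2). When ``beta_all`` is zero the
    proportion is NaN (mediated and direct are still defined).
    """
    b1, b2, ball = est1.beta, est2.beta, est_all.beta
    mediated = b1 * b2
    direct = ball - mediated
    proportion = mediated / ball if ball != 0.0 else math.nan
    se_med = math.sqrt(b2**2 * est1.se**2 + b1**2 * est2.se**2)
    ci = (mediated - 1.959963984540054 * se_med, mediated + 1.959963984540054 * se_med)
    return MediationResult(
        exposure_id=est1.exposure_id,
        mediator_id=est2.exposure_id or est1.outcome_id,
        outcome_id=est_all.outcome_id,
        beta1=b1, se1=est1.se, pvalue1=est1.pvalue,
        beta2=b2, se2=est2.se, pvalue2=est2.pvalue,
        beta_all=ball, se_all=est_all.se, pvalue_all=est_all.pvalue,
        mediated=mediated,
        direct=direct,
        proportion=proportion,
        se_mediated=se_med,
        ci_mediated=ci,
        sign_consistent=(math.copysign(1.0, mediated) == math.copysign(1.0, ball))
        if mediated != 0.0 and ball != 0.0
        else True,
    )


def mediation_screen(
    taxa_estimates: dict,
    mediator_estimates: dict,
    total_estimates: dict,
    cfg: MediationScreenConfig | None = None,
) -> list[MediationResult]:
    """Enumerate (taxon, metabolite, outcome) triples passing all three gates.

    ``taxa_estimates`` maps (taxon, metabolite) -> MrEstimate (beta1),
    ``mediator_estimates`` maps (metabolite, outcome) -> MrEstimate (beta2),
    ``total_estimates`` maps (taxon, outcome) -> MrEstimate (beta_all).
    A triple is emitted when p1 < alpha_step1, p2 < alpha_step2 and
    p_all < alpha_total; sign-inconsistent triples are emitted but
    flagged when ``require_sign_consistency`` is set.
    """
    cfg = cfg or MediationScreenConfig()
    for key in taxa_estimates:
        if not (isinstance(key, tuple) and len(key) == 2):
            raise ConfigurationError("taxa_estimates keys must be (taxon, metabolite)")
    results = []
    for (taxon, metabolite), e1 in taxa_estimates.items():
        for (met2, outcome), e2 in mediator_estimates.items():
            if met2 != metabolite:
                continue
            e_all = total_estimates.get((taxon, outcome))
            if e_all is None:
                continue
            if not (
                e1.pvalue < cfg.alpha_step1
                and e2.pvalue < cfg.alpha_step2
                and e_all.pvalue < cfg.alpha_total
            ):
                continue
            results.append(two_step_mediation(e1, e2, e_all))
    return results


def mediation_ledger(results) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
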