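"""MR estimators: Wald ratio, IVW, MR-Egger, weighted median/mode, MR-PRESSO.

Each estimator is a scikit-learn-style class: construct with
hyperparameters, call ``fit``, read trailing-underscore attributes
(``beta_``, ``se_``, ``pvalue_``, ...). ``fit`` accepts either a
:class:`~mrmediate.io.HarmonizedSet` as ``X`` or raw arrays
``fit(beta_exp, beta_out, se_y=..., se_x=...)``. Module-level functions
(:func:`ivw`, :func:`egger`, ...) are thin wrappers returning an
:class:`MrEstimate` record.

Notation: for instrument j, ``bx`` is the SNP-exposure effect with
standard error ``sx``; ``by`` the SNP-outcome effect with standard error
``sy``. The causal effect theta solves by ~= theta * bx across
instruments; the estimators differ in how they weight instruments and
what invalid-instrument patterns they tolerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .io import HarmonizedSet

__all__ = [
    "MrEstimate",
    "MrEstimatorBase",
    "WaldRatio",
    "IVW",
    "MREgger",
    "WeightedMedian",
    "WeightedMode",
    "MRPresso",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
    "mr_presso",
    "estimate_all",
]


class DegenerateInstrumentError(ValueError):
    """The instrument configuration leaves the causal effect unidentified."""


class InsufficientInstrumentsError(ValueError):
    """The method needs more SNPs than the harmonized set provides."""


@dataclass
class MrEstimate:
    """One method's causal estimate, on the log-odds (or SD) scale."""

    method: str
    beta: float
    se: float
    pvalue: float
    k: int
    exposure_id: str = ""
    outcome_id: str = ""
    primary: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - 1.959963984540054 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + 1.959963984540054 * self.se))

    def to_row(self) -> dict:
        row = {
            "exposure_id": self.exposure_id,
            "outcome_id": self.outcome_id,
            "method": self.method,
            "k": self.k,
            "beta": self.beta,
            "se": self.se,
            "pvalue": self.pvalue,
            "OR": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "primary": self.primary,
        }
        row["extra"] = ";".join(f"{k}={v}" for k, v in self.extra.items())
        return row


def _unpack(X, y=None, se_y=None, se_x=None):
    """Accept a HarmonizedSet or raw arrays; return (bx, sx, by, sy, ids)."""
    if isinstance(X, HarmonizedSet):
        return X.beta_exp, X.se_exp, X.beta_out, X.se_out, X.variant_id
    bx = np.asarray(X, dtype=float).reshape(-1)
    if y is None or se_y is None:
        raise ValueError("raw-array fit requires y (beta_out) and se_y")
    by = np.asarray(y, dtype=float).reshape(-1)
    sy = np.asarray(se_y, dtype=float).reshape(-1)
    sx = None if se_x is None else np.asarray(se_x, dtype=float).reshape(-1)
    if not (len(bx) == len(by) == len(sy)) or (sx is not None and len(sx) != len(bx)):
        raise ValueError("input arrays must have equal length")
    if np.any(sy <= 0) or (sx is not None and np.any(sx <= 0)):
        raise ValueError("standard errors must be > 0")
    ids = np.array([f"snp{i}" for i in range(len(bx))], dtype=object)
    return bx, sx, by, sy, ids


def _norm_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _ivw_beta(bx, by, w):
    denom = float(np.sum(w * bx**2))
    if denom == 0.0:
        raise DegenerateInstrumentError("all exposure effects are zero")
    return float(np.sum(w * bx * by)) / denom, denom


def cochran_q_ivw(bx, by, sy) -> float:
    """Cochran's Q about the through-origin IVW fit (k-1 df)."""
    w = 1.0 / sy**2
    beta, _ = _ivw_beta(bx, by, w)
    return float(np.sum(w * (by - beta * bx) ** 2))


class MrEstimatorBase(BaseEstimator):
    """Shared fit plumbing and the OR/CI presentation helpers."""

    method: str = "base"
    _min_k: int = 1

    def fit(self, X, y=None, se_y=None, se_x=None):
        bx, sx, by, sy, ids = _unpack(X, y, se_y, se_x)
        if len(bx) < self._min_k:
            raise InsufficientInstrumentsError(
                f"{self.method} requires k >= {self._min_k}, got {len(bx)}"
            )
        self.k_ = int(len(bx))
        self.variant_id_ = ids
        self._fit(bx, sx, by, sy)
        return self

    def _fit(self, bx, sx, by, sy):  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta_))

    def to_estimate(self, exposure_id: str = "", outcome_id: str = "", primary=False) -> MrEstimate:
        return MrEstimate(
            method=self.method,
            beta=float(self.beta_),
            se=float(self.se_),
            pvalue=float(self.pvalue_),
            k=self.k_,
            exposure_id=exposure_id,
            outcome_id=outcome_id,
            primary=primary,
            extra=dict(getattr(self, "extra_", {})),
        )


class WaldRatio(MrEstimatorBase):
    """Single-instrument ratio estimate by/bx with first-order SE sy/|bx|."""

    method = "wald"
    _min_k = 1

    def _fit(self, bx, sx, by, sy):
        if self.k_ != 1:
            raise InsufficientInstrumentsError("Wald ratio requires exactly k=1")
        if bx[0] == 0.0:
            raise DegenerateInstrumentError("exposure effect is zero")
        self.beta_ = float(by[0] / bx[0])
        self.se_ = float(sy[0] / abs(bx[0]))
        self.pvalue_ = _norm_p(self.beta_ / self.se_)
        self.extra_ = {}


class IVW(MrEstimatorBase):
    """Inverse-variance weighted estimate: weighted regression through the origin.

    ``mode="fixed"`` uses the analytic fixed-effects SE; with
    ``mode="multiplicative_random"`` the SE is inflated by
    sqrt(Q/(k-1)), floored at 1, so detected heterogeneity widens but
    never narrows the interval. p-values are normal-based.
    """

    method = "ivw"
    _min_k = 2

    def __init__(self, mode: str = "fixed"):
        self.mode = mode

    def _fit(self, bx, sx, by, sy):
        if self.mode not in ("fixed", "multiplicative_random"):
            raise ValueError(f"unknown IVW mode {self.mode!r}")
        w = 1.0 / sy**2
        beta, denom = _ivw_beta(bx, by, w)
        se_fixed = denom**-0.5
        q = float(np.sum(w * (by - beta * bx) ** 2))
        self.Q_ = q
        self.Q_df_ = self.k_ - 1
        if self.mode == "multiplicative_random":
            se = se_fixed * max(1.0, np.sqrt(q / (self.k_ - 1)))
        else:
            se = se_fixed
        self.beta_ = beta
        self.se_ = float(se)
        self.pvalue_ = _norm_p(beta / se)
        self.extra_ = {"Q": q, "Q_df": self.Q_df_}
        self.method = f"ivw_{'fe' if self.mode == 'fixed' else 'mre'}"


class MREgger(MrEstimatorBase):
    """Weighted regression of by on bx with a free intercept.

    Instruments are oriented so every bx >= 0 (both signs flipped where
    needed; the model is invariant to this, the intercept's meaning is
    not). A non-zero intercept estimates the average directional
    pleiotropic effect; the slope remains a consistent causal estimate
    under the InSIDE assumption. Inference is t(k-2) with the residual
    scale floored at 1 (multiplicative random effects, never deflating
    below the fixed-effects SE).
    """

    method = "egger"
    _min_k = 3

    def _fit(self, bx, sx, by, sy):
        sign = np.where(bx < 0, -1.0, 1.0)
        bxo, byo = bx * sign, by * sign
        w = 1.0 / sy**2
        res = sm.WLS(byo, sm.add_constant(bxo), weights=w).fit()
        scale = float(np.sqrt(res.scale))
        infl = 1.0 / min(1.0, scale)  # floor the dispersion at 1
        df = self.k_ - 2
        icept, slope = res.params
        icept_se, slope_se = res.bse * infl
        self.beta_ = float(slope)
        self.se_ = float(slope_se)
        self.pvalue_ = float(2.0 * stats.t.sf(abs(slope / slope_se), df))
        self.intercept_ = float(icept)
        self.intercept_se_ = float(icept_se)
        self.intercept_pvalue_ = float(2.0 * stats.t.sf(abs(icept / icept_se), df))
        fitted = icept + slope * bxo
        self.Q_ = float(np.sum(w * (byo - fitted) ** 2))
        self.Q_df_ = df
        self.extra_ = {
            "egger_intercept": self.intercept_,
            "intercept_se": self.intercept_se_,
            "intercept_p": self.intercept_pvalue_,
        }


def _weighted_median_point(ratios, weights):
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, r))


class WeightedMedian(MrEstimatorBase):
    """Weighted median of the per-SNP ratio estimates.

    Consistent as long as valid instruments carry >= 50% of the weight.
    Weights are inverse-variance weights of each ratio,
    w_j = (sy_j/|bx_j|)^-2; the estimate interpolates the weighted
    empirical quantile function at 0.5. The SE comes from a parametric
    bootstrap (bx, by resampled from their sampling distributions), so
    ``se_x`` / a HarmonizedSet is required.
    """

    method = "weighted_median"
    _min_k = 3

    def __init__(self, n_boot: int = 1000, seed: int = 0):
        self.n_boot = n_boot
        self.seed = seed

    def _fit(self, bx, sx, by, sy):
        if np.any(bx == 0):
            raise DegenerateInstrumentError("zero exposure effect gives infinite ratio")
        if sx is None:
            raise ValueError("weighted median bootstrap requires exposure SEs")
        ratios = by / bx
        weights = (sy / np.abs(bx)) ** -2
        self.beta_ = _weighted_median_point(ratios, weights)
        rng = np.random.default_rng(self.seed)
        bxs = rng.normal(bx, sx, size=(self.n_boot, self.k_))
        bys = rng.normal(by, sy, size=(self.n_boot, self.k_))
        boot = np.empty(self.n_boot)
        for i in range(self.n_boot):
            bxi = bxs[i]
            bxi = np.where(bxi == 0, np.finfo(float).tiny, bxi)
            boot[i] = _weighted_median_point(bys[i] / bxi, (sy / np.abs(bxi)) ** -2)
        self.se_ = float(np.std(boot, ddof=1))
        self.pvalue_ = _norm_p(self.beta_ / self.se_)
        self.extra_ = {}


def _mode_bandwidth(ratios, weights, phi):
    s = _weighted_sd(ratios, weights)
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
    spread = min(s, iqr / 1.349) if iqr > 0 else s
    return phi * 0.9 * spread * len(ratios) ** (-1 / 5)


def _weighted_sd(x, w):
    w = w / w.sum()
    mu = float(np.sum(w * x))
    return float(np.sqrt(np.sum(w * (x - mu) ** 2)))


def _mode_point(ratios, weights, phi, grid_size):
    h = _mode_bandwidth(ratios, weights, phi)
    if h <= 0 or not np.isfinite(h):
        return float(ratios[0]), np.nan
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    wn = weights / weights.sum()
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ wn
    return float(grid[int(np.argmax(dens))]), h


class WeightedMode(MrEstimatorBase):
    """Mode of the weighted kernel density over the per-SNP ratios.

    Consistent when the largest homogeneous cluster of instruments is
    valid (ZEMPA). Bandwidth is the weighted Silverman rule scaled by
    ``bandwidth_factor`` (phi); the density is evaluated on a fixed fine
    grid and the argmax taken. SE via parametric bootstrap.
    """

    method = "weighted_mode"
    _min_k = 3

    def __init__(self, bandwidth_factor: float = 1.0, n_boot: int = 1000, seed: int = 0,
                 grid_size: int = 2048):
        self.bandwidth_factor = bandwidth_factor
        self.n_boot = n_boot
        self.seed = seed
        self.grid_size = grid_size

    def _fit(self, bx, sx, by, sy):
        if np.any(bx == 0):
            raise DegenerateInstrumentError("zero exposure effect gives infinite ratio")
        if sx is None:
            raise ValueError("weighted mode bootstrap requires exposure SEs")
        ratios = by / bx
        weights = (sy / np.abs(bx)) ** -2
        self.beta_, self.bandwidth_ = _mode_point(
            ratios, weights, self.bandwidth_factor, self.grid_size
        )
        rng = np.random.default_rng(self.seed)
        bxs = rng.normal(bx, sx, size=(self.n_boot, self.k_))
        bys = rng.normal(by, sy, size=(self.n_boot, self.k_))
        boot = np.empty(self.n_boot)
        for i in range(self.n_boot):
            bxi = bxs[i]
            bxi = np.where(bxi == 0, np.finfo(float).tiny, bxi)
            boot[i], _ = _mode_point(
                bys[i] / bxi, (sy / np.abs(bxi)) ** -2,
                self.bandwidth_factor, self.grid_size,
            )
        self.se_ = float(np.std(boot, ddof=1))
        self.pvalue_ = _norm_p(self.beta_ / self.se_)
        self.extra_ = {}


def _loo_thetas(bx, by, w):
    """Leave-one-out IVW slopes, vectorized over the left-out index."""
    s1 = np.sum(w * bx * by)
    s2 = np.sum(w * bx**2)
    return (s1 - w * bx * by) / (s2 - w * bx**2)


class MRPresso(MrEstimatorBase):
    """MR pleiotropy residual sum and outlier test.

    The global test compares the observed weighted residual sum of
    squares (residuals taken about leave-one-out IVW predictions, so a
    SNP never predicts itself) against a parametric null simulated under
    the fitted model. Per-SNP contributions give outlier p-values,
    Bonferroni-adjusted; ``beta_`` is the IVW estimate after removing
    flagged outliers (the outlier-corrected estimate), falling back to
    the raw IVW when nothing is flagged. The distortion test compares
    the correction against removals of random same-size subsets.
    """

    method = "presso_corrected"
    _min_k = 4

    def __init__(self, n_sim: int = 1000, seed: int = 0, outlier_sig: float = 0.05):
        self.n_sim = n_sim
        self.seed = seed
        self.outlier_sig = outlier_sig

    def _fit(self, bx, sx, by, sy):
        if self.n_sim < 100:
            raise ValueError("n_sim must be >= 100")
        if sx is None:
            raise ValueError("MR-PRESSO requires exposure SEs")
        k = self.k_
        w = 1.0 / sy**2
        theta_loo = _loo_thetas(bx, by, w)
        res_obs = by - theta_loo * bx
        rss_terms_obs = w * res_obs**2
        rss_obs = float(np.sum(rss_terms_obs))

        rng = np.random.default_rng(self.seed)
        bx_sim = rng.normal(bx, sx, size=(self.n_sim, k))
        by_sim = rng.normal(theta_loo * bx, sy, size=(self.n_sim, k))
        s1 = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
        s2 = np.sum(w * bx_sim**2, axis=1, keepdims=True)
        theta_loo_sim = (s1 - w * bx_sim * by_sim) / (s2 - w * bx_sim**2)
        rss_terms_sim = w * (by_sim - theta_loo_sim * bx_sim) ** 2
        rss_sim = rss_terms_sim.sum(axis=1)

        self.global_rss_ = rss_obs
        self.global_pvalue_ = float(
            (np.sum(rss_sim >= rss_obs) + 1.0) / (self.n_sim + 1.0)
        )

        snp_p = (np.sum(rss_terms_sim >= rss_terms_obs, axis=0) + 1.0) / (self.n_sim + 1.0)
        snp_p_adj = np.minimum(snp_p * k, 1.0)
        outliers = snp_p_adj < self.outlier_sig
        self.outlier_pvalues_ = snp_p_adj
        self.outlier_ids_ = list(self.variant_id_[outliers])

        raw_beta, raw_denom = _ivw_beta(bx, by, w)
        self.raw_beta_ = raw_beta
        n_out = int(outliers.sum())
        if 0 < n_out <= k - 2:
            keep = ~outliers
            beta_c, denom_c = _ivw_beta(bx[keep], by[keep], w[keep])
            self.beta_ = beta_c
            self.se_ = denom_c**-0.5
            # distortion null: random subsets of the same size removed
            d_obs = beta_c - raw_beta
            d_null = np.empty(self.n_sim)
            idx = np.arange(k)
            for i in range(self.n_sim):
                drop = rng.choice(idx, size=n_out, replace=False)
                keep_i = np.setdiff1d(idx, drop, assume_unique=True)
                b_i, _ = _ivw_beta(bx[keep_i], by[keep_i], w[keep_i])
                d_null[i] = b_i - raw_beta
            self.distortion_pvalue_ = float(
                (np.sum(np.abs(d_null) >= abs(d_obs)) + 1.0) / (self.n_sim + 1.0)
            )
        else:
            self.beta_ = raw_beta
            self.se_ = raw_denom**-0.5
            self.distortion_pvalue_ = float("nan")
        self.pvalue_ = _norm_p(self.beta_ / self.se_)
        self.extra_ = {
            "global_p": self.global_pvalue_,
            "outlier_ids": ",".join(map(str, self.outlier_ids_)),
            "distortion_p": self.distortion_pvalue_,
        }


# ---------------------------------------------------------------------------
# functional wrappers


def wald_ratio(h: HarmonizedSet) -> MrEstimate:
    return WaldRatio().fit(h).to_estimate(h.exposure_id, h.outcome_id)


def ivw(h: HarmonizedSet, mode: str = "fixed") -> MrEstimate:
    return IVW(mode=mode).fit(h).to_estimate(h.exposure_id, h.outcome_id)


def egger(h: HarmonizedSet) -> MrEstimate:
    return MREgger().fit(h).to_estimate(h.exposure_id, h.outcome_id)


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MrEstimate:
    est = WeightedMedian(n_boot=n_boot, seed=seed).fit(h)
    return est.to_estimate(h.exposure_id, h.outcome_id)


def weighted_mode(
    h: HarmonizedSet, bandwidth_factor: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> MrEstimate:
    est = WeightedMode(bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seed).fit(h)
    return est.to_estimate(h.exposure_id, h.outcome_id)


def mr_presso(
    h: HarmonizedSet, n_sim: int = 1000, seed: int = 0, outlier_sig: float = 0.05
) -> MrEstimate:
    est = MRPresso(n_sim=n_sim, seed=seed, outlier_sig=outlier_sig).fit(h)
    return est.to_estimate(h.exposure_id, h.outcome_id)


def estimate_all(
    h: HarmonizedSet,
    n_boot: int = 1000,
    n_sim: int = 1000,
    seed: int = 0,
    het_alpha: float = 0.05,
) -> tuple[list[MrEstimate], dict[str, str]]:
    """Run every applicable estimator; the IVW (or Wald at k=1) is primary.

    The IVW mode follows the heterogeneity rule: multiplicative random
    effects when Cochran's Q is significant at ``het_alpha``, fixed
    effects otherwise. Individual method failures are recorded in the
    returned error map, never fatal.
    """
    estimates: list[MrEstimate] = []
    errors: dict[str, str] = {}
    if h.k == 1:
        estimates.append(
            WaldRatio().fit(h).to_estimate(h.exposure_id, h.outcome_id, primary=True)
        )
        return estimates, errors

    from .sensitivity import choose_ivw_mode, cochran_q  # local: avoid cycle

    het = cochran_q(h, method="ivw")
    mode = choose_ivw_mode(het, alpha=het_alpha)
    estimates.append(
        IVW(mode=mode).fit(h).to_estimate(h.exposure_id, h.outcome_id, primary=True)
    )
    candidates = [
        MREgger(),
        WeightedMedian(n_boot=n_boot, seed=seed),
        WeightedMode(n_boot=n_boot, seed=seed + 1),
        MRPresso(n_sim=n_sim, seed=seed + 2),
    ]
    for est in candidates:
        try:
            estimates.append(est.fit(h).to_estimate(h.exposure_id, h.outcome_id))
        except (InsufficientInstrumentsError, DegenerateInstrumentError, ValueError) as e:
            errors[est.method] = str(e)
    return estimates, errors


def estimates_to_frame(estimates: Sequence[MrEstimate]):
    import pandas as pd

    return pd.DataFrame([e.to_row() for e in estimates])
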