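"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the shape of a microbiome/metabolite MR study:
an exposure GWAS of moderate size (16S abundance, n ~ 18,000), a
metabolite GWAS (n ~ 7,800) and large case-control outcome GWAS with
effects on the log-odds scale. Per instrument j with allele frequency
p_j, the summary-level sampling SE is 1/sqrt(2 n p_j (1-p_j)); observed
effects are drawn around their generative means, so every downstream
method can be validated against known truth without individual-level
genotypes.

Generative model for SNP j:

    gamma_j  ~ |N(0, gamma_sd)| + gamma_min        SNP -> exposure
    beta_exp_j ~ N(gamma_j, se_exp_j)
    beta_out_j ~ N(theta*gamma_j + alpha_j + eta_j, se_out_j)

with alpha_j ~ N(pleiotropy mean, sd) a direct (pleiotropic) outcome
effect and eta_j ~ N(0, het_sd) extra heterogeneity. A stated fraction
of variants receives palindromic (A/T or C/G) allele pairs to exercise
harmonization.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instruments import LdMatrix
from .io import CANONICAL_COLUMNS, ConfigurationError, GwasTable

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class MediationParams:
    beta1_true: float
    beta2_true: float
    direct_true: float

    @property
    def total(self) -> float:
        return self.beta1_true * self.beta2_true + self.direct_true

    @property
    def proportion(self) -> float:
        return self.beta1_true * self.beta2_true / self.total


@dataclass
class LdBlock:
    n_snps: int
    r2: float


@dataclass
class SimulationConfig:
    """Generative parameters; defaults mirror the study shapes emulated.

    ``n_exposure`` defaults to the MiBioGen-scale 18,340; ``n_outcome``
    to an early-AMD-scale 105,248 (14,034 cases + 91,214 controls);
    ``n_mediator`` to the metabolome GWAS 7,824. Instrument effects
    default to |N(0, 0.08)| + 0.02.
    """

    n_snps: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure: int = 18_340
    n_outcome: int = 105_248
    n_mediator: int = 7_824
    theta: float = 0.0
    mediation: MediationParams | None = None
    pleiotropy: tuple[float, float] = (0.0, 0.0)
    het_sd: float = 0.0
    ld_blocks: list[LdBlock] | None = None
    seed: int = 0
    gamma_sd: float = 0.08
    gamma_min: float = 0.02
    palindromic_fraction: float = 0.10

    def __post_init__(self):
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for n in (self.n_exposure, self.n_outcome, self.n_mediator):
            if n < 100:
                raise ConfigurationError("sample sizes must be >= 100")
        if not (0.0 <= self.palindromic_fraction <= 1.0):
            raise ConfigurationError("palindromic_fraction must be in [0,1]")


def strong_instruments(**overrides) -> SimulationConfig:
    """Preset for 'strong instruments' scenarios.

    Chosen so the mean instrument F is in the hundreds and two-sample
    regression dilution (of order mean 1/F) is negligible relative to
    Monte-Carlo error at a few hundred replicates.
    """
    base = dict(gamma_sd=0.15, gamma_min=0.10, n_exposure=200_000)
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class SimulationTruth:
    """Ground truth echoed alongside generated tables."""

    config: SimulationConfig
    gamma: np.ndarray
    alpha: np.ndarray
    maf: np.ndarray
    theta: float
    gamma_mediator: np.ndarray | None = None

    @property
    def true_total(self) -> float:
        m = self.config.mediation
        return m.total if m is not None else self.theta

    @property
    def true_proportion(self) -> float:
        m = self.config.mediation
        if m is None:
            return math.nan
        return m.proportion

    def to_json(self) -> str:
        d = dataclasses.asdict(self.config)
        if self.config.mediation is not None:
            d["mediation"] = dataclasses.asdict(self.config.mediation)
        if self.config.ld_blocks is not None:
            d["ld_blocks"] = [dataclasses.asdict(b) for b in self.config.ld_blocks]
        payload = {
            "config": d,
            "gamma": self.gamma.tolist(),
            "alpha": self.alpha.tolist(),
            "maf": self.maf.tolist(),
            "theta": self.theta,
            "gamma_mediator": None
            if self.gamma_mediator is None
            else self.gamma_mediator.tolist(),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "SimulationTruth":
        payload = json.loads(s)
        cfgd = payload["config"]
        if cfgd.get("mediation") is not None:
            cfgd["mediation"] = MediationParams(**cfgd["mediation"])
        if cfgd.get("ld_blocks") is not None:
            cfgd["ld_blocks"] = [LdBlock(**b) for b in cfgd["ld_blocks"]]
        cfgd["maf_range"] = tuple(cfgd["maf_range"])
        cfgd["pleiotropy"] = tuple(cfgd["pleiotropy"])
        cfg = SimulationConfig(**cfgd)
        return cls(
            config=cfg,
            gamma=np.array(payload["gamma"]),
            alpha=np.array(payload["alpha"]),
            maf=np.array(payload["maf"]),
            theta=payload["theta"],
            gamma_mediator=None
            if payload["gamma_mediator"] is None
            else np.array(payload["gamma_mediator"]),
        )


def _se(n: int, maf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _alleles(rng: np.random.Generator, k: int, palindromic_fraction: float):
    pal = rng.random(k) < palindromic_fraction
    ea = np.empty(k, dtype=object)
    oa = np.empty(k, dtype=object)
    for j in range(k):
        pairs = _PALINDROMIC_PAIRS if pal[j] else _NONPALINDROMIC_PAIRS
        ea[j], oa[j] = pairs[rng.integers(len(pairs))]
    return ea, oa


def _positions(k: int, spacing_kb: float = 20_000.0):
    """Spread SNPs along chromosomes 1..22 with > 10,000 kb between them."""
    chroms, pos = [], []
    per_chrom = 10
    for j in range(k):
        chroms.append(str(j // per_chrom % 22 + 1))
        pos.append(int((j % per_chrom + 1) * spacing_kb * 1000))
    return np.array(chroms, dtype=object), np.array(pos)


def _table(trait_id, trait_type, trait_level, vids, chroms, pos, ea, oa, maf,
           beta, se, n) -> GwasTable:
    z = beta / se
    from scipy import stats

    pvals = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    df = pd.DataFrame(
        {
            "variant_id": vids,
            "chrom": chroms,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pvalue": pvals,
            "n": float(n),
        }
    )[CANONICAL_COLUMNS]
    return GwasTable(trait_id, df, trait_type, trait_level)


def _draw_instruments(rng, cfg: SimulationConfig, k: int):
    maf = rng.uniform(*cfg.maf_range, size=k)
    gamma = np.abs(rng.normal(0.0, cfg.gamma_sd, size=k)) + cfg.gamma_min
    return maf, gamma


def simulate_two_sample(
    cfg: SimulationConfig,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    trait_level: str = "genus",
) -> tuple[GwasTable, GwasTable, SimulationTruth]:
    """Exposure and outcome summary tables sharing cfg.n_snps instruments."""
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_snps
    maf, gamma = _draw_instruments(rng, cfg, k)
    alpha = rng.normal(cfg.pleiotropy[0], cfg.pleiotropy[1], size=k)
    eta = rng.normal(0.0, cfg.het_sd, size=k) if cfg.het_sd > 0 else np.zeros(k)

    se_x = _se(cfg.n_exposure, maf)
    se_y = _se(cfg.n_outcome, maf)
    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(cfg.theta * gamma + alpha + eta, se_y)

    vids = np.array([f"rs{j + 1}" for j in range(k)], dtype=object)
    chroms, pos = _positions(k)
    ea, oa = _alleles(rng, k, cfg.palindromic_fraction)

    exposure = _table(exposure_id, "quantitative", trait_level, vids, chroms, pos,
                      ea, oa, maf, beta_x, se_x, cfg.n_exposure)
    outcome = _table(outcome_id, "binary", "none", vids, chroms, pos,
                     ea, oa, maf, beta_y, se_y, cfg.n_outcome)
    truth = SimulationTruth(config=cfg, gamma=gamma, alpha=alpha, maf=maf,
                            theta=cfg.theta)
    return exposure, outcome, truth


def simulate_mediation_triplet(
    cfg: SimulationConfig,
    exposure_id: str = "taxon",
    mediator_id: str = "metabolite",
    outcome_id: str = "disease",
) -> tuple[GwasTable, GwasTable, GwasTable, SimulationTruth]:
    """Exposure, mediator and outcome tables with a planted mediated path.

    The mediator table contains the exposure's instruments (with effects
    beta1*gamma, for step 1) *and* its own independently drawn
    instrument set (for step 2, as the mediator-as-exposure analysis
    uses mediator-specific instruments). The outcome table covers both
    SNP sets: total effect (beta1*beta2 + direct) per exposure
    instrument, beta2 per mediator instrument.
    """
    if cfg.mediation is None:
        raise ConfigurationError("cfg.mediation must be set")
    med = cfg.mediation
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_snps

    maf_x, gamma_x = _draw_instruments(rng, cfg, k)
    maf_m, gamma_m = _draw_instruments(rng, cfg, k)
    alpha = rng.normal(cfg.pleiotropy[0], cfg.pleiotropy[1], size=k)

    vids_x = np.array([f"rs{j + 1}" for j in range(k)], dtype=object)
    vids_m = np.array([f"rs{k + j + 1}" for j in range(k)], dtype=object)
    chroms, pos = _positions(2 * k)
    ea, oa = _alleles(rng, 2 * k, cfg.palindromic_fraction)

    se_x = _se(cfg.n_exposure, maf_x)
    se_m_at_x = _se(cfg.n_mediator, maf_x)
    se_m_at_m = _se(cfg.n_mediator, maf_m)
    se_y_at_x = _se(cfg.n_outcome, maf_x)
    se_y_at_m = _se(cfg.n_outcome, maf_m)

    beta_x = rng.normal(gamma_x, se_x)
    beta_m_at_x = rng.normal(med.beta1_true * gamma_x, se_m_at_x)
    beta_m_at_m = rng.normal(gamma_m, se_m_at_m)
    beta_y_at_x = rng.normal(med.total * gamma_x + alpha, se_y_at_x)
    beta_y_at_m = rng.normal(med.beta2_true * gamma_m, se_y_at_m)

    exposure = _table(exposure_id, "quantitative", "family",
                      vids_x, chroms[:k], pos[:k], ea[:k], oa[:k],
                      maf_x, beta_x, se_x, cfg.n_exposure)
    mediator = _table(
        mediator_id, "quantitative", "none",
        np.concatenate([vids_x, vids_m]), chroms, pos, ea, oa,
        np.concatenate([maf_x, maf_m]),
        np.concatenate([beta_m_at_x, beta_m_at_m]),
        np.concatenate([se_m_at_x, se_m_at_m]),
        cfg.n_mediator,
    )
    outcome = _table(
        outcome_id, "binary", "none",
        np.concatenate([vids_x, vids_m]), chroms, pos, ea, oa,
        np.concatenate([maf_x, maf_m]),
        np.concatenate([beta_y_at_x, beta_y_at_m]),
        np.concatenate([se_y_at_x, se_y_at_m]),
        cfg.n_outcome,
    )
    truth = SimulationTruth(config=cfg, gamma=gamma_x, alpha=alpha, maf=maf_x,
                            theta=med.total, gamma_mediator=gamma_m)
    return exposure, mediator, outcome, truth


def simulate_ld_block(
    cfg: SimulationConfig, trait_id: str = "exposure"
) -> tuple[GwasTable, LdMatrix]:
    """Correlated-SNP fixture for clumping: block-diagonal r^2 structure.

    Within a block, SNPs sit 100 kb apart (well inside the 10,000 kb
    window) with the block's r^2 between every pair; consecutive blocks
    are separated by 20,000 kb (outside the window).
    """
    if not cfg.ld_blocks:
        raise ConfigurationError("cfg.ld_blocks must be set")
    rng = np.random.default_rng(cfg.seed)
    sizes = [b.n_snps for b in cfg.ld_blocks]
    k = sum(sizes)
    maf, gamma = _draw_instruments(rng, cfg, k)
    se = _se(cfg.n_exposure, maf)
    beta = rng.normal(gamma, se)
    vids = np.array([f"rs{j + 1}" for j in range(k)], dtype=object)

    chroms = np.array(["1"] * k, dtype=object)
    pos = np.empty(k, dtype=int)
    r2 = np.eye(k)
    start_bp, j = 1_000_000, 0
    for block in cfg.ld_blocks:
        idx = np.arange(j, j + block.n_snps)
        pos[idx] = start_bp + np.arange(block.n_snps) * 100_000
        for a in idx:
            for b in idx:
                if a != b:
                    r2[a, b] = block.r2
        start_bp = int(pos[idx[-1]]) + 20_000 * 1000
        j += block.n_snps

    table = _table(trait_id, "quantitative", "genus", vids, chroms, pos,
                   *_alleles(rng, k, 0.0), maf, beta, se, cfg.n_exposure)
    return table, LdMatrix(list(vids), r2)
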