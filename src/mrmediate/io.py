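"""Reading, writing and harmonizing GWAS summary-statistic tables.

Two-sample MR works entirely from per-variant summary associations: an
effect size (log-odds for binary traits, SD units for quantitative ones),
its standard error, the allele the effect is reported for, and a p-value.
Before any estimator can run, the exposure and outcome tables must be
*harmonized* -- expressed with respect to the same effect allele at every
instrument, with strand flips resolved and strand-ambiguous (palindromic)
variants handled explicitly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset(_COMPLEMENT)


class SummaryStatsError(ValueError):
    """Base class for summary-statistics input problems."""


class ConfigurationError(SummaryStatsError):
    """A required column or key is missing or inconsistent."""


class EmptyInputError(SummaryStatsError):
    """No valid rows survived parsing or filtering."""


class EmptyHarmonizationError(SummaryStatsError):
    """All instruments were dropped during harmonization."""

    def __init__(self, message: str, drop_counts: Mapping[str, int]):
        super().__init__(message)
        self.drop_counts = dict(drop_counts)


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP-trait association from a GWAS summary table.

    ``beta`` is the per-allele effect of ``effect_allele``; ``eaf`` and
    ``n`` are optional (NaN when absent), as in MiBioGen-style releases.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float = math.nan
    n: float = math.nan

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: se must be > 0, got {self.se}")
        ea, oa = self.effect_allele, self.other_allele
        if ea not in _VALID_ALLELES or oa not in _VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: alleles must be single A/C/G/T")
        if ea == oa:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.variant_id}: pvalue must be in (0,1]")
        if not math.isnan(self.eaf) and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.variant_id}: eaf must be in [0,1]")

    @property
    def is_palindromic(self) -> bool:
        return self.other_allele == _COMPLEMENT[self.effect_allele]


@dataclass
class GwasTable:
    """A full summary-statistics table for one trait.

    ``trait_level`` carries the bacterial taxonomy level (phylum .. genus)
    for microbiome traits and ``"none"`` otherwise; it drives the
    per-level Bonferroni correction downstream.
    """

    trait_id: str
    df: pd.DataFrame
    trait_type: str = "quantitative"
    trait_level: str = "none"

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ConfigurationError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_level not in ("phylum", "class", "order", "family", "genus", "none"):
            raise ConfigurationError(f"unknown trait_level {self.trait_level!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"table {self.trait_id}: missing columns {missing}")
        if self.df["variant_id"].duplicated().any():
            dups = self.df.loc[self.df["variant_id"].duplicated(), "variant_id"].tolist()
            raise ConfigurationError(f"table {self.trait_id}: duplicate variant ids {dups[:5]}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[AssociationRecord]:
        return [
            AssociationRecord(
                variant_id=r.variant_id,
                chrom=str(r.chrom),
                pos=int(r.pos),
                effect_allele=r.effect_allele,
                other_allele=r.other_allele,
                beta=float(r.beta),
                se=float(r.se),
                pvalue=float(r.pvalue),
                eaf=float(r.eaf) if pd.notna(r.eaf) else math.nan,
                n=float(r.n) if pd.notna(r.n) else math.nan,
            )
            for r in self.df.itertuples(index=False)
        ]

    def subset(self, variant_ids: Iterable[str]) -> "GwasTable":
        ids = list(variant_ids)
        sub = self.df[self.df["variant_id"].isin(ids)].copy()
        return GwasTable(self.trait_id, sub, self.trait_type, self.trait_level)


@dataclass
class HarmonizedSet:
    """Exposure and outcome effects aligned to a shared effect allele.

    The parallel arrays are the input to every MR estimator. ``se_exp``
    is retained because the bootstrap and MR-PRESSO need the exposure
    sampling variance, not only the outcome one.
    """

    exposure_id: str
    outcome_id: str
    variant_id: np.ndarray
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    n_dropped_palindromic: int = 0
    n_flipped: int = 0
    drop_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        for name in ("beta_exp", "se_exp", "beta_out", "se_out"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        k = len(self.variant_id)
        if k < 1:
            raise EmptyHarmonizationError("harmonized set is empty", self.drop_counts)
        for name in ("beta_exp", "se_exp", "beta_out", "se_out"):
            if len(getattr(self, name)) != k:
                raise ValueError("parallel arrays must have equal length")
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ValueError("all standard errors must be > 0")

    @property
    def k(self) -> int:
        return len(self.variant_id)

    def drop(self, variant_ids: Iterable[str]) -> "HarmonizedSet":
        """Return a copy without the given variants (e.g. PRESSO outliers)."""
        drop = set(variant_ids)
        keep = np.array([v not in drop for v in self.variant_id])
        return HarmonizedSet(
            self.exposure_id,
            self.outcome_id,
            self.variant_id[keep],
            self.beta_exp[keep],
            self.se_exp[keep],
            self.beta_out[keep],
            self.se_out[keep],
            self.n_dropped_palindromic,
            self.n_flipped,
            dict(self.drop_counts),
        )


def read_gwas_table(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "quantitative",
    trait_level: str = "none",
) -> GwasTable:
    """Read a tab-separated GWAS summary table into a :class:`GwasTable`.

    ``column_map`` maps canonical names to the file's header names, e.g.
    ``{"beta": "BETA", "se": "SE", "pvalue": "P"}``. Rows violating the
    record invariants (se <= 0, bad alleles, p outside (0,1], eaf outside
    [0,1]) are dropped with a logged count. gzip files are handled
    transparently by pandas.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    mandatory = [c for c in CANONICAL_COLUMNS if c not in ("eaf", "n")]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing mandatory columns {missing}")
    for col in ("eaf", "n"):
        if col not in df.columns:
            df[col] = math.nan
    df = df[CANONICAL_COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("pos", "eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    ok = (
        df["se"].gt(0)
        & df["beta"].notna()
        & df["pos"].notna()
        & df["pvalue"].gt(0)
        & df["pvalue"].le(1)
        & df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & (df["eaf"].isna() | (df["eaf"].ge(0) & df["eaf"].le(1)))
    )
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("%s: dropped %d rows violating record invariants", path, n_bad)
    df = df[ok].reset_index(drop=True)
    df["pos"] = df["pos"].astype(int)
    if df.empty:
        raise EmptyInputError(f"{path}: no valid rows")
    tid = trait_id if trait_id is not None else str(path)
    return GwasTable(tid, df, trait_type, trait_level)


def write_gwas_table(table: GwasTable, path) -> None:
    """Write a table back out with the canonical header, full precision."""
    df = table.df[CANONICAL_COLUMNS].copy()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _alignment(exp_ea, exp_oa, out_ea, out_oa):
    """Classify outcome alleles relative to exposure alleles.

    Returns one of ``"same"``, ``"swap"``, ``"mismatch"``; strand
    complements are folded into same/swap (GWAS strand is arbitrary).
    """
    comp_ea, comp_oa = _COMPLEMENT[out_ea], _COMPLEMENT[out_oa]
    if (out_ea, out_oa) == (exp_ea, exp_oa) or (comp_ea, comp_oa) == (exp_ea, exp_oa):
        return "same"
    if (out_oa, out_ea) == (exp_ea, exp_oa) or (comp_oa, comp_ea) == (exp_ea, exp_oa):
        return "swap"
    return "mismatch"


def harmonize(
    exposure: GwasTable,
    outcome: GwasTable,
    instrument_ids: Sequence[str],
    palindrome_policy: str = "drop_ambiguous",
    eaf_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect alleles.

    Rules, in order, per instrument:

    * absent from the outcome table -> dropped (``missing_in_outcome``);
    * palindromic (A/T or C/G) exposure pair: with ``drop_all`` always
      dropped; with ``drop_ambiguous`` the allele-frequency signs decide
      orientation, and the SNP is dropped when either eaf is missing or
      falls inside ``eaf_window`` (strand unresolvable);
    * outcome alleles equal (possibly strand-complemented) -> kept as is;
      swapped -> outcome beta sign flipped and eaf complemented;
    * anything else -> dropped (``mismatch``).
    """
    if len(instrument_ids) == 0:
        raise ConfigurationError("instrument_ids must be non-empty")
    if palindrome_policy not in ("drop_all", "drop_ambiguous"):
        raise ConfigurationError(f"unknown palindrome_policy {palindrome_policy!r}")
    exp = exposure.df.set_index("variant_id")
    missing_exp = [v for v in instrument_ids if v not in exp.index]
    if missing_exp:
        raise ConfigurationError(
            f"instruments not present in exposure table: {missing_exp[:5]}"
        )
    out = outcome.df.set_index("variant_id")

    lo, hi = eaf_window
    rows = []
    counts = {"missing_in_outcome": 0, "palindromic": 0, "mismatch": 0}
    n_flipped = 0
    for vid in instrument_ids:
        e = exp.loc[vid]
        if vid not in out.index:
            counts["missing_in_outcome"] += 1
            continue
        o = out.loc[vid]
        exp_pal = _COMPLEMENT[e.effect_allele] == e.other_allele
        if exp_pal:
            if palindrome_policy == "drop_all":
                counts["palindromic"] += 1
                continue
            # orientation from allele frequencies only
            e_eaf, o_eaf = e.eaf, o.eaf
            ambiguous = (
                pd.isna(e_eaf)
                or pd.isna(o_eaf)
                or lo <= e_eaf <= hi
                or lo <= o_eaf <= hi
            )
            if ambiguous:
                counts["palindromic"] += 1
                continue
            if (e_eaf - 0.5) * (o_eaf - 0.5) > 0:
                rows.append((vid, e.beta, e.se, o.beta, o.se))
            else:
                rows.append((vid, e.beta, e.se, -o.beta, o.se))
                n_flipped += 1
            continue
        kind = _alignment(e.effect_allele, e.other_allele, o.effect_allele, o.other_allele)
        if kind == "same":
            rows.append((vid, e.beta, e.se, o.beta, o.se))
        elif kind == "swap":
            rows.append((vid, e.beta, e.se, -o.beta, o.se))
            n_flipped += 1
        else:
            counts["mismatch"] += 1
    if not rows:
        raise EmptyHarmonizationError(
            f"no instruments survived harmonization for {exposure.trait_id} -> "
            f"{outcome.trait_id}",
            counts,
        )
    vids, bx, sx, by, sy = zip(*rows)
    return HarmonizedSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        variant_id=np.array(vids, dtype=object),
        beta_exp=np.array(bx, float),
        se_exp=np.array(sx, float),
        beta_out=np.array(by, float),
        se_out=np.array(sy, float),
        n_dropped_palindromic=counts["palindromic"],
        n_flipped=n_flipped,
        drop_counts=counts,
    )
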