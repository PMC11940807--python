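"""Instrument selection: p-value screen, greedy LD clumping, F filter.

An MR instrument must be (i) robustly associated with the exposure,
(ii) approximately independent of the other instruments, and (iii) strong
enough to avoid weak-instrument bias. The three stages here implement
those requirements as they are conventionally applied to microbiome and
metabolite GWAS: a per-trait significance screen (p < 1e-5 for taxa,
p < 5e-6 for metabolites), greedy p-value-ranked clumping at r^2 < 0.001
within a 10,000 kb window, and a per-SNP F > 10 cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AssociationRecord, ConfigurationError, GwasTable


class NoInstrumentsError(ValueError):
    """Every candidate was removed; ``stage`` names the culprit."""

    def __init__(self, message: str, stage: str):
        super().__init__(message)
        self.stage = stage


class LdAmbiguityError(ValueError):
    """A candidate shares a window with another but is absent from the LD matrix."""


@dataclass
class LdMatrix:
    """Squared-correlation (r^2) matrix over a set of variants."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        if self.r2.shape != (n, n):
            raise ValueError("r2 matrix shape must match variant_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 entries must lie in [0,1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def identity(cls, variant_ids) -> "LdMatrix":
        ids = list(variant_ids)
        return cls(ids, np.eye(len(ids)))

    @classmethod
    def read(cls, path) -> "LdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float))

    def write(self, path) -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t", float_format="%.17g"
        )


@dataclass
class SelectionParams:
    p_threshold: float = 1e-5
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0
    f_min: float = 10.0
    apply_f_filter: bool = True


@dataclass
class InstrumentSet:
    exposure_id: str
    records: list[AssociationRecord]
    f_stats: list[float]
    selection_params: SelectionParams = field(default_factory=SelectionParams)

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


def select_by_pvalue(table: GwasTable, p_threshold: float) -> list[AssociationRecord]:
    """Records with p strictly below the threshold, ascending by p."""
    if not (0.0 < p_threshold <= 1.0):
        raise ConfigurationError("p_threshold must be in (0,1]")
    hits = [r for r in table.records if r.pvalue < p_threshold]
    return sorted(hits, key=lambda r: (r.pvalue, r.variant_id))


def f_statistic(record: AssociationRecord) -> float:
    """Single-SNP instrument-strength F, the large-sample (beta/se)^2."""
    return (record.beta / record.se) ** 2


def _within_window(a: AssociationRecord, b: AssociationRecord, window_kb: float) -> bool:
    return a.chrom == b.chrom and abs(a.pos - b.pos) <= window_kb * 1000.0


def ld_clump(
    candidates: list[AssociationRecord],
    ld: LdMatrix | None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
) -> list[AssociationRecord]:
    """Greedy p-value-ranked clumping.

    Repeatedly keep the smallest-p remaining candidate (ties broken by
    variant id) and discard every remaining candidate on the same
    chromosome within ``window_kb`` whose r^2 with it is >= the
    threshold. ``ld=None`` treats every pair as r^2 = 0. A candidate
    missing from a supplied LD matrix is only an error if it shares a
    chromosome+window with another candidate (otherwise it is trivially
    independent).
    """
    pool = sorted(candidates, key=lambda r: (r.pvalue, r.variant_id))
    kept: list[AssociationRecord] = []
    while pool:
        lead = pool.pop(0)
        kept.append(lead)
        survivors = []
        for r in pool:
            if not _within_window(lead, r, window_kb):
                survivors.append(r)
                continue
            if ld is None:
                survivors.append(r)
                continue
            if lead.variant_id not in ld or r.variant_id not in ld:
                missing = lead.variant_id if lead.variant_id not in ld else r.variant_id
                raise LdAmbiguityError(
                    f"{missing} shares a window with another candidate but is "
                    "absent from the LD matrix"
                )
            if ld.r2_between(lead.variant_id, r.variant_id) < r2_threshold:
                survivors.append(r)
        pool = survivors
    return kept


def build_instrument_set(
    table: GwasTable,
    ld: LdMatrix | None = None,
    params: SelectionParams | None = None,
) -> InstrumentSet:
    """p-value screen -> LD clump -> F filter, with stage-attributed failure."""
    params = params or SelectionParams()
    hits = select_by_pvalue(table, params.p_threshold)
    if not hits:
        raise NoInstrumentsError(
            f"{table.trait_id}: no SNP with p < {params.p_threshold}", "pvalue"
        )
    clumped = ld_clump(hits, ld, params.r2_threshold, params.window_kb)
    if not clumped:  # pragma: no cover - clumping never empties a non-empty pool
        raise NoInstrumentsError(f"{table.trait_id}: clumping removed all SNPs", "clump")
    if params.apply_f_filter:
        strong = [r for r in clumped if f_statistic(r) > params.f_min]
        if not strong:
            raise NoInstrumentsError(
                f"{table.trait_id}: no instrument with F > {params.f_min}", "f_filter"
            )
    else:
        strong = clumped
    return InstrumentSet(
        exposure_id=table.trait_id,
        records=strong,
        f_stats=[f_statistic(r) for r in strong],
        selection_params=params,
    )
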