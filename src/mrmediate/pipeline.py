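"""Study orchestration: bidirectional screens, multiplicity, full runs.

A study manifest lists exposure tables (bacterial taxa with their
taxonomy level), optional mediator (metabolite) tables, and one or more
binary outcome tables. ``run_full_study`` drives instruments ->
harmonization -> estimation -> sensitivity -> per-level Bonferroni
classification, then the mediation screen over qualifying triples.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import estimate_all, estimates_to_frame
from .instruments import (
    LdMatrix,
    NoInstrumentsError,
    SelectionParams,
    build_instrument_set,
)
from .io import (
    ConfigurationError,
    EmptyHarmonizationError,
    GwasTable,
    harmonize,
    read_gwas_table,
)
from .mediation import MediationScreenConfig, mediation_ledger, mediation_screen
from .sensitivity import leave_one_out, sensitivity_row

logger = logging.getLogger(__name__)

DEFAULT_UNKNOWN_TAXON_PATTERN = r"(?i)unknown"


def bonferroni_threshold(n_level: int) -> float:
    """Per-taxonomy-level threshold 0.05/n for n independent taxa."""
    if n_level < 1:
        raise ConfigurationError("n_level must be >= 1")
    return 0.05 / n_level


def classify_result(pvalue: float, threshold: float) -> str:
    """Three tiers: significant (p < 0.05/n), suggestive (p < 0.05), null."""
    if threshold > 0.05:
        raise ConfigurationError("threshold must be <= 0.05")
    if pvalue < threshold:
        return "significant"
    if pvalue < 0.05:
        return "suggestive"
    return "null"


@dataclass
class StudyParams:
    p_threshold_exposure: float = 1e-5
    p_threshold_metabolite: float = 5e-6
    p_threshold_reverse: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    f_min: float = 10.0
    f_filter_taxa: bool = False  # stated only for metabolites
    f_filter_metabolites: bool = True
    het_alpha: float = 0.05
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    palindrome_policy: str = "drop_ambiguous"
    mediation: MediationScreenConfig = field(default_factory=MediationScreenConfig)
    n_level_override: dict = field(default_factory=dict)
    unknown_taxon_pattern: str = DEFAULT_UNKNOWN_TAXON_PATTERN

    def exposure_selection(self, kind: str = "taxon") -> SelectionParams:
        if kind == "taxon":
            return SelectionParams(self.p_threshold_exposure, self.clump_r2,
                                   self.clump_kb, self.f_min, self.f_filter_taxa)
        if kind == "metabolite":
            return SelectionParams(self.p_threshold_metabolite, self.clump_r2,
                                   self.clump_kb, self.f_min,
                                   self.f_filter_metabolites)
        if kind == "outcome":
            return SelectionParams(self.p_threshold_reverse, self.clump_r2,
                                   self.clump_kb, self.f_min, False)
        raise ConfigurationError(f"unknown exposure kind {kind!r}")


@dataclass
class StudyManifest:
    exposures: list[GwasTable]
    outcomes: list[GwasTable]
    mediators: list[GwasTable] = field(default_factory=list)
    ld: LdMatrix | None = None
    params: StudyParams = field(default_factory=StudyParams)
    out_dir: Path | None = None

    def __post_init__(self):
        if not self.exposures or not self.outcomes:
            raise ConfigurationError("manifest needs at least one exposure and one outcome")
        pat = re.compile(self.params.unknown_taxon_pattern)
        kept = [t for t in self.exposures if not pat.search(t.trait_id)]
        n_removed = len(self.exposures) - len(kept)
        if n_removed:
            logger.info("removed %d unknown taxa by pattern %r", n_removed,
                        self.params.unknown_taxon_pattern)
        if not kept:
            raise ConfigurationError("unknown-taxon filter removed every exposure")
        self.exposures = kept

    @classmethod
    def from_yaml(cls, path) -> "StudyManifest":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        base = path.parent

        def load(entry, default_type):
            p = base / entry["path"]
            if not p.exists():
                raise ConfigurationError(f"manifest references missing file {p}")
            return read_gwas_table(
                p,
                column_map=entry.get("column_map"),
                trait_id=entry.get("trait_id", p.stem),
                trait_type=entry.get("trait_type", default_type),
                trait_level=entry.get("trait_level", "none"),
            )

        exposures = [load(e, "quantitative") for e in doc["exposures"]]
        outcomes = [load(e, "binary") for e in doc["outcomes"]]
        mediators = [load(e, "quantitative") for e in doc.get("mediators", [])]
        ld = LdMatrix.read(base / doc["ld_matrix"]) if doc.get("ld_matrix") else None
        pdoc = doc.get("params", {})
        med = pdoc.pop("mediation", None)
        params = StudyParams(**pdoc)
        if med:
            params.mediation = MediationScreenConfig(**med)
        out_dir = Path(doc["out_dir"]) if doc.get("out_dir") else None
        return cls(exposures, outcomes, mediators, ld, params, out_dir)


@dataclass
class PairResult:
    exposure_id: str
    outcome_id: str
    status: str  # ok | not-assessable
    reason: str = ""
    estimates: list = field(default_factory=list)
    sensitivity: dict | None = None
    loo: object | None = None

    @property
    def primary(self):
        for e in self.estimates:
            if e.primary:
                return e
        return None


def _run_pair(exposure: GwasTable, outcome: GwasTable, ld, selection: SelectionParams,
              params: StudyParams) -> PairResult:
    try:
        inst = build_instrument_set(exposure, ld, selection)
        h = harmonize(exposure, outcome, inst.variant_ids,
                      palindrome_policy=params.palindrome_policy)
    except (NoInstrumentsError, EmptyHarmonizationError) as e:
        return PairResult(exposure.trait_id, outcome.trait_id, "not-assessable", str(e))
    estimates, errors = estimate_all(
        h, n_boot=params.n_boot, n_sim=params.n_sim, seed=params.seed,
        het_alpha=params.het_alpha,
    )
    sens = sensitivity_row(h) if h.k >= 2 else None
    loo = leave_one_out(h) if h.k >= 3 else None
    res = PairResult(exposure.trait_id, outcome.trait_id, "ok",
                     estimates=estimates, sensitivity=sens, loo=loo)
    if errors:
        res.reason = "; ".join(f"{m}: {msg}" for m, msg in errors.items())
    return res


def run_bidirectional(exposure: GwasTable, outcome: GwasTable,
                      manifest: StudyManifest) -> dict:
    """Forward (exposure -> outcome) and reverse (outcome -> exposure) runs.

    The reverse direction screens instruments at the genome-wide disease
    threshold. A direction with no usable instruments is reported
    not-assessable; the other still runs.
    """
    p = manifest.params
    kind = "metabolite" if exposure.trait_level == "none" else "taxon"
    forward = _run_pair(exposure, outcome, manifest.ld, p.exposure_selection(kind), p)
    reverse = _run_pair(outcome, exposure, manifest.ld, p.exposure_selection("outcome"), p)
    return {"forward": forward, "reverse": reverse}


@dataclass
class StudyReport:
    results: pd.DataFrame
    sensitivity: pd.DataFrame
    mediation: pd.DataFrame
    loo: pd.DataFrame
    pairs: list[PairResult]
    metadata: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(out / "results.tsv", sep="\t", index=False)
        self.sensitivity.to_csv(out / "sensitivity.tsv", sep="\t", index=False)
        self.mediation.to_csv(out / "mediation.tsv", sep="\t", index=False)
        self.loo.to_csv(out / "leave_one_out.tsv", sep="\t", index=False)
        with open(out / "run_metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=1)


def run_full_study(manifest: StudyManifest) -> StudyReport:
    """Every exposure x outcome pair, classification, then mediation."""
    p = manifest.params
    pairs: list[PairResult] = []
    for exposure in manifest.exposures:
        for outcome in manifest.outcomes:
            kind = "metabolite" if exposure.trait_level == "none" else "taxon"
            pairs.append(_run_pair(exposure, outcome, manifest.ld,
                                   p.exposure_selection(kind), p))

    # per-taxonomy-level Bonferroni on the primary estimates
    level_counts: dict[str, int] = {}
    for t in manifest.exposures:
        level_counts[t.trait_level] = level_counts.get(t.trait_level, 0) + 1
    level_counts.update(p.n_level_override)
    level_of = {t.trait_id: t.trait_level for t in manifest.exposures}

    rows, sens_rows, loo_rows = [], [], []
    total_estimates = {}
    for pr in pairs:
        if pr.status != "ok":
            rows.append({"exposure_id": pr.exposure_id, "outcome_id": pr.outcome_id,
                         "status": "not-assessable", "reason": pr.reason})
            continue
        level = level_of.get(pr.exposure_id, "none")
        thr = bonferroni_threshold(level_counts.get(level, 1))
        primary = pr.primary
        total_estimates[(pr.exposure_id, pr.outcome_id)] = primary
        for e in pr.estimates:
            row = e.to_row()
            row["status"] = "ok"
            row["reason"] = pr.reason
            row["level"] = level
            row["bonferroni_threshold"] = thr
            row["classification"] = (
                classify_result(e.pvalue, thr) if e.primary else ""
            )
            rows.append(row)
        if pr.sensitivity is not None:
            sens_rows.append(pr.sensitivity)
        if pr.loo is not None:
            t = pr.loo.table.copy()
            t.insert(0, "exposure_id", pr.exposure_id)
            t.insert(1, "outcome_id", pr.outcome_id)
            loo_rows.append(t)

    # mediation screen: taxon -> mediator (beta1), mediator -> outcome (beta2)
    med_df = pd.DataFrame()
    if manifest.mediators:
        step1, step2 = {}, {}
        for taxon in manifest.exposures:
            for mediator in manifest.mediators:
                kind = "metabolite" if taxon.trait_level == "none" else "taxon"
                pr = _run_pair(taxon, mediator, manifest.ld,
                               p.exposure_selection(kind), p)
                if pr.status == "ok" and pr.primary is not None:
                    step1[(taxon.trait_id, mediator.trait_id)] = pr.primary
        for mediator in manifest.mediators:
            for outcome in manifest.outcomes:
                pr = _run_pair(mediator, outcome, manifest.ld,
                               p.exposure_selection("metabolite"), p)
                if pr.status == "ok" and pr.primary is not None:
                    step2[(mediator.trait_id, outcome.trait_id)] = pr.primary
        totals = {k: v for k, v in total_estimates.items() if v is not None}
        med_results = mediation_screen(step1, step2, totals, p.mediation)
        med_df = mediation_ledger(med_results)

    report = StudyReport(
        results=pd.DataFrame(rows),
        sensitivity=pd.DataFrame(sens_rows),
        mediation=med_df,
        loo=pd.concat(loo_rows, ignore_index=True) if loo_rows else pd.DataFrame(),
        pairs=pairs,
        metadata={
            "package_version": __version__,
            "numpy_version": np.__version__,
            "seed": p.seed,
            "params": {k: v for k, v in vars(p).items()
                       if isinstance(v, (int, float, str, bool))},
            "n_exposures": len(manifest.exposures),
            "n_outcomes": len(manifest.outcomes),
            "n_mediators": len(manifest.mediators),
            "level_counts": level_counts,
        },
    )
    if manifest.out_dir is not None:
        report.write(manifest.out_dir)
    return report
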