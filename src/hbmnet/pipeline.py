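"""End-to-end orchestration: full runs, stratified runs, sensitivity analysis.

All numeric defaults in :class:`RunConfig` are the reference analysis
constants: censoring filter 0.40, 10 lambdas down to 10% of the maximum,
StARS threshold 0.1, EBIC gamma 0.5, 1000 bootstrap iterations, 4 walktrap
steps.  Every stage draws its randomness from the single run seed through a
documented derivation (stage seed = run seed + fixed stage offset).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .communities import compare_partitions
from .datatypes import BiomarkerMatrix, DataError, validate_covariates
from .descriptives import describe, pearson_matrix
from .glasso import lambda_path, empirical_covariance
from .io import write_processed
from .model import ExposureNetwork
from .network import edge_list, write_graphml
from .preprocess import (
    filter_by_censoring,
    impute_censored_ml,
    impute_missing_chained,
    log_transform,
    preprocess,
    select_single_biomarker,
    standardize_dilution,
)

#: seed offsets per pipeline stage (all randomness flows from the run seed)
STAGE_SEED_OFFSETS = {"preprocess": 0, "stars": 1, "bootstrap": 2, "simulate": 3}


@dataclass
class RunConfig:
    """Run settings; defaults are the reference analysis constants."""

    censor_threshold: float = 0.40
    n_lambdas: int = 10
    lambda_min_ratio: float = 0.1
    stars_threshold: float = 0.1
    ebic_gamma: float = 0.5
    bootstrap_iterations: int = 1000
    walktrap_steps: int = 4
    dilution_mode: str = "divide"
    correction_covariates: Sequence[str] = ("age", "bmi", "smoking")
    network: str = "unweighted"  # "unweighted" (StARS) or "weighted" (EBIC+bootstrap)
    single_biomarker_map: Optional[dict] = None
    min_stratum_n: int = 30
    #: optional urine validity pre-filter: keep creatinine in [0.3, 3] g/L
    urine_validity_filter: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["correction_covariates"] = list(self.correction_covariates)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StratificationRule:
    """Split a cohort into exactly two strata on one determinant."""

    variable: str
    kind: str = "median"            # "median" | "threshold" | "category_map"
    threshold: Optional[float] = None
    mapping: Optional[dict] = None  # category value -> stratum name
    names: Sequence[str] = ("low", "high")

    def split(self, covariates: pd.DataFrame) -> dict:
        if self.variable not in covariates:
            raise DataError(f"stratification variable {self.variable!r} not found")
        x = covariates[self.variable]
        if x.isna().any():
            raise DataError(f"stratification variable {self.variable!r} has missing values")
        if self.kind == "median":
            cut = float(x.median())
            masks = {self.names[0]: x <= cut, self.names[1]: x > cut}
        elif self.kind == "threshold":
            if self.threshold is None:
                raise DataError("threshold rule requires a threshold")
            masks = {self.names[0]: x <= self.threshold, self.names[1]: x > self.threshold}
        elif self.kind == "category_map":
            if not self.mapping:
                raise DataError("category_map rule requires a mapping")
            strata = x.map(self.mapping)
            if strata.isna().any():
                raise DataError("category_map leaves some subjects unassigned")
            names = sorted(strata.unique())
            if len(names) != 2:
                raise DataError("stratification must produce exactly 2 strata")
            masks = {name: strata == name for name in names}
        else:
            raise DataError(f"unknown stratification kind {self.kind!r}")
        return masks


@dataclass
class RunResult:
    processed: object
    report: object
    results: object          # ExposureNetworkResults
    descriptives: pd.DataFrame
    correlation: pd.DataFrame
    manifest: dict
    outdir: Optional[Path] = None


def _apply_urine_filter(bm: BiomarkerMatrix, covariates: pd.DataFrame):
    keep = covariates["creatinine"].between(0.3, 3.0)
    return bm.subset(rows=bm.subjects[keep]), covariates.loc[keep]


def imputed_concentrations(
    bm: BiomarkerMatrix, covariates: pd.DataFrame, config: RunConfig
) -> BiomarkerMatrix:
    """Dilution-standardised, imputed concentration-scale matrix.

    This is the input to the descriptive table: select -> filter ->
    standardise -> log -> impute censored -> impute missing -> back-transform.
    """
    covariates = validate_covariates(covariates, bm.subjects)
    bm, _ = select_single_biomarker(bm, config.single_biomarker_map or {})
    bm, _ = filter_by_censoring(bm, config.censor_threshold)
    mode = config.dilution_mode if config.dilution_mode == "divide" else "none"
    bm = standardize_dilution(bm, covariates, mode=mode)
    bm = log_transform(bm)
    if bm.censored.to_numpy().any():
        bm, _ = impute_censored_ml(bm, seed=config.seed + STAGE_SEED_OFFSETS["preprocess"])
    bm, _, _ = impute_missing_chained(bm, covariates)
    out = bm.copy()
    out.values = np.exp(out.values)
    out.thresholds = np.exp(out.thresholds)
    out.log_scale = False
    return out


def run_full(
    bm: BiomarkerMatrix,
    covariates: pd.DataFrame,
    config: Optional[RunConfig] = None,
    outdir=None,
    correction_covariates: Optional[Sequence[str]] = None,
) -> RunResult:
    """Execute preprocessing -> descriptives -> network -> communities.

    Writes every artefact plus a manifest when ``outdir`` is given.  A stage
    failure is re-raised annotated with the stage name; artefacts produced by
    earlier stages are preserved on disk.
    """
    config = config or RunConfig()
    correction = list(
        correction_covariates
        if correction_covariates is not None
        else config.correction_covariates
    )
    covariates = validate_covariates(covariates, bm.subjects)
    if config.urine_validity_filter:
        bm, covariates = _apply_urine_filter(bm, covariates)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    stage = "preprocessing"
    try:
        processed, report = preprocess(
            bm,
            covariates,
            single_biomarker_map=config.single_biomarker_map,
            censor_threshold=config.censor_threshold,
            dilution_mode=config.dilution_mode,
            correction_covariates=correction,
            seed=config.seed + STAGE_SEED_OFFSETS["preprocess"],
        )
        if outdir is not None:
            write_processed(processed, outdir)

        stage = "descriptives"
        conc = imputed_concentrations(bm, covariates, config)
        table = describe(conc)
        corr = pearson_matrix(processed)
        if outdir is not None:
            table.to_csv(outdir / "descriptives.csv")
            corr.to_csv(outdir / "correlation.csv")

        stage = "network"
        model = ExposureNetwork(processed)
        path = lambda_path(
            empirical_covariance(model.data), config.n_lambdas, config.lambda_min_ratio
        )
        if config.network == "unweighted":
            results = model.fit(
                method="stars",
                seed=config.seed + STAGE_SEED_OFFSETS["stars"],
                stars_threshold=config.stars_threshold,
                walktrap_steps=config.walktrap_steps,
                path=path,
            )
        elif config.network == "weighted":
            method = "bootstrap" if config.bootstrap_iterations > 0 else "ebic"
            results = model.fit(
                method=method,
                seed=config.seed + STAGE_SEED_OFFSETS["bootstrap"],
                ebic_gamma=config.ebic_gamma,
                bootstrap_iterations=config.bootstrap_iterations,
                walktrap_steps=config.walktrap_steps,
                path=path,
            )
        else:
            raise DataError(f"unknown network type {config.network!r}")

        stage = "communities"
        if outdir is not None:
            write_graphml(results.graph, outdir / "network.graphml")
            results.edge_list().to_csv(outdir / "edges.csv", index=False)
            (outdir / "communities.json").write_text(
                json.dumps(
                    {str(k): int(v) for k, v in results.partition.assignment.items()},
                    indent=1,
                )
            )
            (outdir / "summary.txt").write_text(results.summary() + "\n")
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    manifest = {
        "package": "hbmnet",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_subjects": int(bm.n_subjects),
        "biomarkers_analysed": list(processed.biomarkers),
        "excluded_biomarkers": report.excluded_biomarkers,
        "correction_covariates": report.correction_covariates,
        "selected_lambda": float(results.selected_lambda),
        "n_edges": int(results.n_edges),
        "n_communities": int(results.partition.n_communities),
        "modularity": float(results.partition.modularity),
    }
    if outdir is not None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return RunResult(processed, report, results, table, corr, manifest, outdir)


def run_stratified(
    bm: BiomarkerMatrix,
    covariates: pd.DataFrame,
    rule: StratificationRule,
    config: Optional[RunConfig] = None,
    outdir=None,
) -> dict:
    """Run the pipeline independently in two strata and compare partitions.

    Filtering and below-LOQ imputation happen separately per stratum, and the
    stratification variable is removed from the correction covariates.
    """
    config = config or RunConfig()
    covariates = validate_covariates(covariates, bm.subjects)
    masks = rule.split(covariates)
    correction = [c for c in config.correction_covariates if c != rule.variable]
    outdir = Path(outdir) if outdir is not None else None

    runs = {}
    for name, mask in masks.items():
        n = int(mask.sum())
        if n < config.min_stratum_n:
            raise DataError(
                f"stratum {name!r} has {n} subjects (< minimum {config.min_stratum_n})"
            )
        sub_dir = outdir / f"stratum_{name}" if outdir is not None else None
        runs[name] = run_full(
            bm.subset(rows=bm.subjects[mask.to_numpy()]),
            covariates.loc[mask.to_numpy()],
            config,
            outdir=sub_dir,
            correction_covariates=correction,
        )

    names = list(runs)
    comparison = compare_partitions(
        runs[names[0]].results.partition, runs[names[1]].results.partition
    )
    report = {
        "rule": {"variable": rule.variable, "kind": rule.kind,
                 "threshold": rule.threshold},
        "strata": {
            name: {
                "n_subjects": run.manifest["n_subjects"],
                "n_edges": run.manifest["n_edges"],
                "n_communities": run.manifest["n_communities"],
                "correction_covariates": run.manifest["correction_covariates"],
            }
            for name, run in runs.items()
        },
        "comparison": comparison,
    }
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "stratified_report.json").write_text(
            json.dumps(report, indent=1, default=str)
        )
    return {"runs": runs, "report": report}


def creatinine_sensitivity(
    bm: BiomarkerMatrix,
    covariates: pd.DataFrame,
    config: Optional[RunConfig] = None,
    outdir=None,
) -> dict:
    """Compare networks across the three creatinine adjustment modes.

    Runs the pipeline with dilution modes ``divide``, ``covariate`` and
    ``none`` and reports pairwise edge-set Jaccard similarity and partition
    adjusted Rand index.
    """
    config = config or RunConfig()
    if "creatinine" not in covariates:
        raise DataError("creatinine column required for the sensitivity analysis")
    modes = ("divide", "covariate", "none")
    outdir = Path(outdir) if outdir is not None else None
    runs = {}
    for mode in modes:
        cfg = RunConfig(**{**config.to_dict(), "dilution_mode": mode})
        sub = outdir / f"mode_{mode}" if outdir is not None else None
        runs[mode] = run_full(bm, covariates, cfg, outdir=sub)

    def edge_set(run):
        return {frozenset(e) for e in run.results.graph.edges()}

    pairwise = {}
    for i, a in enumerate(modes):
        for b in modes[i + 1:]:
            ea, eb = edge_set(runs[a]), edge_set(runs[b])
            union = ea | eb
            jac = len(ea & eb) / len(union) if union else 1.0
            ari = compare_partitions(
                runs[a].results.partition, runs[b].results.partition
            )["adjusted_rand"]
            pairwise[f"{a}_vs_{b}"] = {"edge_jaccard": jac, "adjusted_rand": ari}
    report = {
        "modes": {
            m: {"n_edges": runs[m].manifest["n_edges"],
                "n_communities": runs[m].manifest["n_communities"]}
            for m in modes
        },
        "pairwise": pairwise,
    }
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "sensitivity_report.json").write_text(json.dumps(report, indent=1))
    return {"runs": runs, "report": report}
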