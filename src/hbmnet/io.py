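"""Reading and writing cohort files.

A cohort on disk is three CSV files plus an optional truth JSON:

* ``values.csv`` — subjects x biomarkers; censored cells hold the token
  ``"<LOD"`` or ``"<LOQ"``, missing cells are empty.  (A flag-matrix dialect
  is accepted as an alternative: plain numeric ``values.csv`` with NaN in
  unobserved cells plus a boolean ``censored.csv``.)
* ``covariates.csv`` — one row per subject (age, sex, bmi, smoking, isced,
  fish_consumption, creatinine, blood_lipids, ...).
* ``metadata.csv`` — one row per biomarker: ``biomarker, lod, loq, matrix,
  units, lipid_soluble`` (optionally ``substance``, ``family``).
* ``truth.json`` — planted precision matrix, community labels and generator
  settings, present only for synthetic cohorts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import BiomarkerMatrix, DataError
from .synthetic import SyntheticTruth

CENSOR_TOKENS = ("<LOD", "<LOQ")


def write_cohort(
    bm: BiomarkerMatrix,
    covariates: pd.DataFrame,
    outdir,
    truth: Optional[SyntheticTruth] = None,
) -> dict:
    """Write a cohort to ``outdir``; returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    values = bm.values.astype(object).copy()
    values[bm.censored] = "<LOD"
    values[bm.missing] = ""
    paths = {
        "values": outdir / "values.csv",
        "covariates": outdir / "covariates.csv",
        "metadata": outdir / "metadata.csv",
    }
    values.to_csv(paths["values"])
    covariates.to_csv(paths["covariates"])
    bm.meta.to_csv(paths["metadata"])
    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(json.dumps(truth_to_dict(truth), indent=1))
    return paths


def truth_to_dict(truth: SyntheticTruth) -> dict:
    return {
        "precision_true": np.asarray(truth.precision_true).tolist(),
        "community_labels": np.asarray(truth.community_labels).tolist(),
        "covariate_effects": (
            truth.covariate_effects.to_dict() if truth.covariate_effects is not None else None
        ),
        "lod": truth.lod.to_dict() if truth.lod is not None else None,
        "dilution_sd": truth.dilution_sd,
        "missing_rate": truth.missing_rate,
        "seed": truth.seed,
        "diag_inflation": truth.diag_inflation,
    }


def read_truth(path) -> SyntheticTruth:
    d = json.loads(Path(path).read_text())
    return SyntheticTruth(
        precision_true=np.asarray(d["precision_true"], dtype=float),
        community_labels=np.asarray(d["community_labels"], dtype=int),
        covariate_effects=(
            pd.DataFrame(d["covariate_effects"]) if d.get("covariate_effects") else None
        ),
        lod=pd.Series(d["lod"]) if d.get("lod") else None,
        dilution_sd=d.get("dilution_sd", 0.0),
        missing_rate=d.get("missing_rate", 0.0),
        seed=d.get("seed", 0),
        diag_inflation=d.get("diag_inflation", 0.0),
    )


def read_cohort(indir):
    """Read a cohort directory; returns (BiomarkerMatrix, covariates)."""
    indir = Path(indir)
    censored_path = indir / "censored.csv"
    return read_biomarker_matrix(
        indir / "values.csv",
        indir / "metadata.csv",
        censored_path if censored_path.exists() else None,
    ), pd.read_csv(indir / "covariates.csv", index_col=0)


def read_biomarker_matrix(values_path, meta_path, censored_path=None) -> BiomarkerMatrix:
    """Read a values CSV in either censoring dialect."""
    meta = pd.read_csv(meta_path, index_col=0)
    if "lipid_soluble" in meta:
        meta["lipid_soluble"] = meta["lipid_soluble"].astype(bool)
    raw = pd.read_csv(values_path, index_col=0, dtype=str, keep_default_na=False)
    raw = raw.apply(lambda col: col.str.strip())
    token = raw.isin(CENSOR_TOKENS)
    loq_token = raw.eq("<LOQ")
    empty = raw.eq("") | raw.apply(lambda col: col.str.lower()).isin(["nan", "na"])
    values = raw.mask(token | empty).apply(pd.to_numeric)

    if censored_path is not None:
        censored = pd.read_csv(censored_path, index_col=0).astype(bool)
        if not censored.columns.equals(values.columns):
            raise DataError("censored flag matrix columns do not match values")
        missing = values.isna() & ~censored
    else:
        censored = token
        missing = empty
    bm = BiomarkerMatrix(values, censored, missing, meta)
    if loq_token.to_numpy().any() and "loq" in meta:
        # cells censored at LOQ get that limit as their threshold
        thr = bm.thresholds.to_numpy()
        loq = meta["loq"].astype(float).reindex(values.columns).to_numpy()
        mask = loq_token.to_numpy()
        thr[mask] = np.broadcast_to(loq, values.shape)[mask]
        bm.thresholds = pd.DataFrame(thr, index=values.index, columns=values.columns)
    return bm


def write_processed(pm, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "processed": outdir / "processed.csv",
        "provenance": outdir / "provenance.json",
    }
    pm.values.to_csv(paths["processed"])
    paths["provenance"].write_text(json.dumps(pm.provenance, indent=1, default=str))
    return paths
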