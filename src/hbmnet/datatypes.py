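"""Core data containers for human-biomonitoring (HBM) network analysis.

The central object is :class:`BiomarkerMatrix`: a subjects × biomarkers
concentration table together with per-cell censoring/missingness flags and
per-biomarker metadata (LOD, LOQ, sample matrix, units).  Values below the
limit of detection (LOD) or quantification (LOQ) are *left-censored*: the
laboratory reports only that the true concentration lies below the limit, so
the cell carries a flag and no value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

#: recognised sample matrices
MATRICES = ("urine", "blood", "serum", "plasma", "cord_blood", "cord_blood_plasma")

#: short display codes for sample matrices, used in node labels ("Pb (CB)")
MATRIX_ABBREV = {
    "urine": "U",
    "blood": "B",
    "serum": "S",
    "plasma": "P",
    "cord_blood": "CB",
    "cord_blood_plasma": "CBP",
}

META_COLUMNS = ["lod", "loq", "matrix", "units", "lipid_soluble"]


class DataError(ValueError):
    """Raised when input data violate a documented invariant."""


@dataclass
class BiomarkerMatrix:
    """Subjects × biomarkers concentrations with censoring metadata.

    Parameters
    ----------
    values : DataFrame
        Concentrations (or log-concentrations if ``log_scale``); NaN where a
        cell is censored or missing.
    censored : DataFrame of bool
        True where the measurement fell below its LOD/LOQ.
    missing : DataFrame of bool
        True where the measurement is absent for other reasons (e.g.
        insufficient sample volume).  A cell is at most one of
        censored / missing.
    meta : DataFrame
        Indexed by biomarker; columns ``lod, loq, matrix, units,
        lipid_soluble`` (and optionally ``substance``, ``family``).
    thresholds : DataFrame, optional
        Per-cell censoring threshold.  Defaults to the per-biomarker limit
        broadcast across subjects; creatinine standardisation makes it
        subject-specific.
    log_scale : bool
        Whether ``values`` (and ``thresholds``) are on the natural-log scale.
    """

    values: pd.DataFrame
    censored: pd.DataFrame
    missing: pd.DataFrame
    meta: pd.DataFrame
    thresholds: Optional[pd.DataFrame] = None
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.censored = self.censored.astype(bool)
        self.missing = self.missing.astype(bool)
        if self.thresholds is None:
            self.thresholds = self._default_thresholds()
        self.validate()

    # -- construction helpers -------------------------------------------------

    def _default_thresholds(self) -> pd.DataFrame:
        # the threshold a censored cell was reported against: LOQ where given
        # and larger than LOD, else LOD
        lod = self.meta["lod"].astype(float)
        loq = self.meta["loq"].astype(float) if "loq" in self.meta else lod
        limit = loq.where(loq.notna(), lod)
        return pd.DataFrame(
            np.broadcast_to(limit.to_numpy(), self.values.shape).copy(),
            index=self.values.index,
            columns=self.values.columns,
        )

    @classmethod
    def from_values(
        cls,
        values: pd.DataFrame,
        meta: pd.DataFrame,
        censored: Optional[pd.DataFrame] = None,
        missing: Optional[pd.DataFrame] = None,
        **kwargs,
    ) -> "BiomarkerMatrix":
        shape = values.shape
        if censored is None:
            censored = pd.DataFrame(
                np.zeros(shape, dtype=bool), index=values.index, columns=values.columns
            )
        if missing is None:
            missing = values.isna() & ~censored
        return cls(values, censored, missing, meta, **kwargs)

    # -- invariants -----------------------------------------------------------

    def validate(self) -> None:
        v, c, m = self.values, self.censored, self.missing
        if not (v.shape == c.shape == m.shape):
            raise DataError("values/censored/missing shapes differ")
        if not (v.columns.equals(c.columns) and v.columns.equals(m.columns)):
            raise DataError("column labels of flags do not match values")
        unknown = set(v.columns) - set(self.meta.index)
        if unknown:
            raise DataError(f"biomarkers without metadata: {sorted(unknown)}")
        both = (c & m).to_numpy()
        if both.any():
            raise DataError("a cell is flagged both censored and missing")
        observed = v.to_numpy()[~(c | m).to_numpy()]
        if not self.log_scale and np.any(observed <= 0):
            raise DataError("observed concentrations must be positive")
        lod = self.meta.get("lod")
        loq = self.meta.get("loq")
        if lod is not None and loq is not None:
            bad = (lod.astype(float) > loq.astype(float)).fillna(False)
            if bad.any():
                raise DataError(f"LOD > LOQ for {list(self.meta.index[bad])}")
        bad_matrix = set(self.meta["matrix"].dropna()) - set(MATRICES)
        if bad_matrix:
            raise DataError(f"unknown sample matrix: {sorted(bad_matrix)}")

    # -- convenience ----------------------------------------------------------

    @property
    def biomarkers(self) -> list:
        return list(self.values.columns)

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_biomarkers(self) -> int:
        return self.values.shape[1]

    def is_urinary(self) -> pd.Series:
        return self.meta.loc[self.biomarkers, "matrix"].eq("urine")

    def is_lipid_soluble_blood(self) -> pd.Series:
        meta = self.meta.loc[self.biomarkers]
        in_blood = meta["matrix"].isin(
            ["blood", "serum", "plasma", "cord_blood", "cord_blood_plasma"]
        )
        return in_blood & meta["lipid_soluble"].fillna(False).astype(bool)

    def copy(self) -> "BiomarkerMatrix":
        return BiomarkerMatrix(
            self.values.copy(),
            self.censored.copy(),
            self.missing.copy(),
            self.meta.copy(),
            thresholds=self.thresholds.copy(),
            log_scale=self.log_scale,
        )

    def subset(self, columns=None, rows=None) -> "BiomarkerMatrix":
        cols = list(columns) if columns is not None else self.biomarkers
        idx = rows if rows is not None else self.values.index
        return BiomarkerMatrix(
            self.values.loc[idx, cols].copy(),
            self.censored.loc[idx, cols].copy(),
            self.missing.loc[idx, cols].copy(),
            self.meta.loc[cols].copy(),
            thresholds=self.thresholds.loc[idx, cols].copy(),
            log_scale=self.log_scale,
        )

    def display_labels(self) -> dict:
        """Node labels annotated with the sample matrix, e.g. ``"Pb (CB)"``."""
        out = {}
        for b in self.biomarkers:
            mat = self.meta.loc[b, "matrix"]
            abbr = MATRIX_ABBREV.get(mat, "?")
            out[b] = f"{b} ({abbr})"
        return out


def validate_covariates(covariates: pd.DataFrame, subjects: pd.Index) -> pd.DataFrame:
    """Check a determinants table: one row per subject, positive creatinine."""
    if not covariates.index.equals(pd.Index(subjects)):
        if len(covariates) != len(subjects):
            raise DataError("covariate table not aligned to biomarker matrix")
        covariates = covariates.set_axis(subjects, axis=0)
    if "creatinine" in covariates:
        creat = covariates["creatinine"]
        bad = creat.notna() & (creat <= 0)
        if bad.any():
            raise DataError(
                f"non-positive creatinine for subjects {list(covariates.index[bad])}"
            )
    return covariates


@dataclass
class ProcessedMatrix:
    """Fully processed analysis matrix: standardised residual log-concentrations.

    Columns have mean ~0 and standard deviation ~1; no censored or missing
    cells remain.  ``provenance`` records every preprocessing step applied,
    with its parameters, in order.
    """

    values: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise DataError("processed matrix contains missing values")

    @property
    def biomarkers(self) -> list:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def record(self, step: str, **params) -> None:
        self.provenance.append({"step": step, **params})
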