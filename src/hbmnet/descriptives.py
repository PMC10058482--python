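"""Descriptive statistics tables and Pearson correlation structure.

The descriptive table mirrors the reporting convention for HBM datasets:
per biomarker the number of values and missing values, percentage below LOD
and LOQ (computed on the pre-imputation flags), mean, standard deviation,
standard error, geometric mean and percentiles P05-P95.  Statistics are
computed on imputed, dilution-standardised concentrations.

Percentile convention: linear interpolation between order statistics
(R ``quantile`` type 7, the default of the cited quantile function): with
sorted values x_(1) <= ... <= x_(n) and target fraction q, let
h = (n-1)q + 1; the percentile is x_(floor(h)) + (h - floor(h)) *
(x_(floor(h)+1) - x_(floor(h))).  This is numpy's default, so results are
reproducible bit-identically across implementations.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import BiomarkerMatrix, DataError, ProcessedMatrix
from .preprocess import censoring_summary

PERCENTILES = (5, 10, 25, 50, 75, 90, 95)


def describe(bm: BiomarkerMatrix) -> pd.DataFrame:
    """Descriptive table on (possibly imputed) concentration-scale values.

    Requires positive concentrations (the geometric mean is
    exp(mean(ln x))).  Cells still flagged missing are excluded from the
    statistics; censored cells enter through their imputed values when
    present.
    """
    if bm.log_scale:
        raise DataError("describe() expects concentration-scale values")
    cens = censoring_summary(bm)
    rows = {}
    for b in bm.biomarkers:
        x = bm.values[b].dropna().to_numpy(dtype=float)
        if x.size == 0:
            raise DataError(f"biomarker {b!r} has no values to describe")
        if np.any(x <= 0):
            raise DataError(f"biomarker {b!r} has non-positive values")
        n = x.size
        sd = float(np.std(x, ddof=1)) if n > 1 else np.nan
        row = {
            "n": n,
            "n_missing": int(bm.missing[b].sum()),
            "pct_below_lod": 100.0 * cens.loc[b, "frac_below_lod"],
            "pct_below_loq": 100.0 * cens.loc[b, "frac_below_loq"],
            "mean": float(np.mean(x)),
            "sd": sd,
            "se": sd / np.sqrt(n) if n > 1 else np.nan,
            "geometric_mean": float(np.exp(np.mean(np.log(x)))),
        }
        for p in PERCENTILES:
            row[f"P{p:02d}"] = float(np.percentile(x, p))  # linear interpolation
        rows[b] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "biomarker"
    return out


def pearson_matrix(pm, family_order: Optional[list] = None) -> pd.DataFrame:
    """Pearson correlation matrix of the processed columns.

    Optionally reorders rows/columns by a biomarker-family grouping for
    heatmap display.  Requires >= 3 subjects and non-constant columns.
    """
    values = pm.values if isinstance(pm, ProcessedMatrix) else pm
    if len(values) < 3:
        raise DataError("need at least 3 subjects for a correlation matrix")
    constant = values.std(ddof=0) == 0
    if constant.any():
        raise DataError(f"constant columns: {list(values.columns[constant])}")
    corr = values.corr(method="pearson")
    if family_order is not None:
        order = [b for b in family_order if b in corr.index]
        order += [b for b in corr.index if b not in order]
        corr = corr.loc[order, order]
    return corr


def correlation_heatmap(corr: pd.DataFrame, path=None, ax=None):
    """Render the correlation matrix as a heatmap (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(0.4 * len(corr) + 2,) * 2)
    else:
        fig = ax.figure
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(corr)), corr.index, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8, label="Pearson r")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
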