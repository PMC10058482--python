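import numpy as np
import pandas as pd
import pytest

from hbmnet import BiomarkerMatrix, CohortConfig, generate_cohort


def make_bm(values, censored=None, missing=None, lod=None, matrix="urine",
            log_scale=False, lipid_soluble=False):
    """Hand-build a small BiomarkerMatrix from array-likes."""
    values = pd.DataFrame(values) if not isinstance(values, pd.DataFrame) else values
    values.columns = [str(c) for c in values.columns]
    p = values.shape[1]
    shape = values.shape

    def as_flags(x):
        if x is None:
            return pd.DataFrame(np.zeros(shape, bool), index=values.index,
                                columns=values.columns)
        return pd.DataFrame(np.asarray(x, bool), index=values.index,
                            columns=values.columns)

    if lod is None:
        lod = [0.0 if log_scale else 1e-6] * p
    meta = pd.DataFrame(
        {
            "lod": lod,
            "loq": lod,
            "matrix": [matrix] * p if isinstance(matrix, str) else matrix,
            "units": ["ug/L"] * p,
            "lipid_soluble": [lipid_soluble] * p,
        },
        index=values.columns,
    )
    return BiomarkerMatrix(values, as_flags(censored), as_flags(missing), meta,
                           log_scale=log_scale)


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-subject, 9-biomarker cohort with 3 planted ring communities."""
    cfg = CohortConfig(
        n_subjects=200, n_biomarkers=9, n_communities=3,
        censor_quantile=0.15, missing_rate=0.02, dilution_sd=0.4, seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Censoring- and missingness-free cohort for exactness checks."""
    cfg = CohortConfig(
        n_subjects=300, n_biomarkers=9, n_communities=3,
        censor_quantile=0.0, missing_rate=0.0, dilution_sd=0.3, seed=11,
    )
    return generate_cohort(cfg)
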