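import numpy as np
import pytest

from abmiref.reference import load_packaged_reference
from abmiref.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def ref():
    """Packaged multiethnic ABMI reference (60-240 months)."""
    return load_packaged_reference()


@pytest.fixture(scope="session")
def schedule(ref):
    return ref.exponents


@pytest.fixture(scope="session")
def clean_cohort():
    """Moderate uncontaminated cohort (shared across read-only tests)."""
    cfg = CohortConfig(n_per_cell=12, seed=7)
    df, labels, screening = generate_cohort(cfg)
    return df, labels, screening


@pytest.fixture(scope="session")
def dirty_cohort():
    """Cohort with every contamination category injected."""
    cfg = CohortConfig(
        n_per_cell=12,
        seed=42,
        frac_height_decrease=0.02,
        frac_implausible=0.01,
        frac_missing=0.05,
        frac_weight_outlier=0.02,
    )
    df, labels, screening = generate_cohort(cfg)
    return df, labels, screening


@pytest.fixture(scope="session")
def boys_month_sim(ref):
    """Per-month draws from the packaged boys' curves (the fitter's truth)."""
    from abmiref.lms import inverse_z
    from abmiref.reference import lms_at

    rng = np.random.default_rng(0)
    months = np.arange(60, 241)
    pts = {m: lms_at(ref, "M", float(m)) for m in months}
    ages = np.repeat(months, 100).astype(float)
    z = np.clip(rng.normal(size=len(ages)), -5, 5)
    y = np.array([inverse_z(zz, pts[m]) for zz, m in zip(z, ages.astype(int))])
    return ages, y, pts
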