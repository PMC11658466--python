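import numpy as np
import pytest

from panelforge import CohortSpec, NormalizedMatrix, ProteomicDataset, generate_cohort


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """A fast, well-powered cohort: 40+40 subjects, 60 analytes, strong
    planted group effects and two severity-correlated analytes."""
    return CohortSpec(
        n_case=40,
        n_control=40,
        n_analytes=60,
        n_qc_fail=5,
        planted_group_effects=((3, 1.5), (7, -1.5), (11, 2.0)),
        planted_severity_effects=((20, 0.6), (25, -0.5)),
        duplicate_pairs=4,
        duplicate_cv=0.10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture()
def tiny_dataset() -> ProteomicDataset:
    """Hand-built 4-sample, 2-analyte dataset."""
    return ProteomicDataset(
        sample_ids=["s1", "s2", "s3", "s4"],
        group=np.array(["case", "case", "control", "control"], dtype=object),
        analyte_ids=["A", "B"],
        rfu=np.array([[10.0, 5.0], [100.0, 5.5], [1000.0, 4.5], [100.0, 5.0]]),
        qc_pass=np.array([True, True]),
        severity=np.array([12.0, 18.0, np.nan, np.nan]),
    )


def make_normalized(z: np.ndarray, analyte_ids=None) -> NormalizedMatrix:
    """Wrap a raw matrix as a NormalizedMatrix without transforming it."""
    z = np.asarray(z, dtype=float)
    n, m = z.shape
    return NormalizedMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        analyte_ids=analyte_ids or [f"P{j}" for j in range(m)],
        z=z,
    )
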