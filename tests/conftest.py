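import numpy as np
import pytest
from hypothesis import settings

import phenobar as pb

settings.register_profile("suite", max_examples=100, derandomize=True,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_records():
    return pb.study_compound_table()


@pytest.fixture(scope="session")
def experimental_set(study_records):
    return (pb.experimental_drugs(study_records)
            + pb.experimental_counterions(study_records))


@pytest.fixture(scope="session")
def simulated_wells(experimental_set):
    return pb.simulate_screen(experimental_set, seed=11)


@pytest.fixture(scope="session")
def normalized(simulated_wells):
    return pb.normalize_screen(simulated_wells)


@pytest.fixture(scope="session")
def class_of(study_records):
    return {c.compound_id: c.class_label for c in study_records}


@pytest.fixture(scope="session")
def barcodes(normalized, class_of):
    return pb.barcode_matrix(normalized, class_of)


@pytest.fixture(scope="session")
def prepped(barcodes):
    culled, _ = pb.cull_model_descriptors(barcodes)
    return pb.standardize(culled)


@pytest.fixture(scope="session")
def prepped_drugs(prepped):
    keep = [r for r, l in zip(prepped.row_ids, prepped.class_labels)
            if l is not pb.ClassLabel.CI]
    return prepped.select_rows(keep)


def random_feature_matrix(rng: np.random.Generator, n: int, p: int,
                          missing_rate: float = 0.0) -> pb.FeatureMatrix:
    values = rng.normal(size=(n, p))
    if missing_rate:
        values[rng.random((n, p)) < missing_rate] = np.nan
    return pb.FeatureMatrix(
        row_ids=[f"r{i}" for i in range(n)],
        column_names=[f"c{j}" for j in range(p)],
        values=values)
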