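import numpy as np
import pytest

import tpeflim as tf


@pytest.fixture(scope="session")
def table():
    return tf.load_reference_table()


@pytest.fixture(scope="session")
def instrument():
    return tf.InstrumentModel()


@pytest.fixture(scope="session")
def reference_frame():
    """One seeded draw of the full 399-cell synthetic feature table."""
    return tf.sample_reference_dataset(seed=123)


@pytest.fixture(scope="session")
def m1_cell():
    """A cell at the in vivo M1 class means (tau1=196, tau2=1698, a1/a2=5)."""
    return tf.CellSample(true_tau1=196.0, true_tau2=1698.0,
                         true_a1=5.0 / 6.0, true_a2=1.0 / 6.0,
                         group_label=0, class_name="M1 macrophages",
                         intensity=686.0)


@pytest.fixture(scope="session")
def m2_cell():
    """A cell at the in vivo M2 class means (tau1=442, tau2=2458, a1/a2=1.2)."""
    return tf.CellSample(true_tau1=442.0, true_tau2=2458.0,
                         true_a1=1.2 / 2.2, true_a2=1.0 / 2.2,
                         group_label=1, class_name="M2 macrophages",
                         intensity=360.0)


def training_matrix(df):
    X = df[tf.FEATURE_NAMES].to_numpy(float)
    y = df["label"].to_numpy(int)
    return X, y


@pytest.fixture(scope="session")
def training_data(reference_frame):
    return training_matrix(reference_frame)
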