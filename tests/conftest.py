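import numpy as np
import pandas as pd
import pytest

from offsig.screen import PlateSet


def make_plateset(records):
    """Build a PlateSet from (plate, row, col, compound, role, lum) tuples."""
    df = pd.DataFrame(records, columns=[
        "plate_id", "row", "col", "compound_id", "role", "luminescence"])
    df["cell_line"] = "CL1"
    df["replicate"] = 1
    return PlateSet(df)


@pytest.fixture
def tiny_plate():
    """One plate: 2 vehicle wells (9000, 11000) and 4 sample wells."""
    return make_plateset([
        ("P1", "A", 1, "", "vehicle", 9000.0),
        ("P1", "A", 2, "", "vehicle", 11000.0),
        ("P1", "B", 1, "cpdX", "sample", 5000.0),
        ("P1", "B", 2, "cpdX", "sample", 5000.0),
        ("P1", "C", 1, "cpdY", "sample", 10000.0),
        ("P1", "C", 2, "cpdY", "sample", 0.0),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
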