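import numpy as np
import pytest

from fieldqsar import (FieldConfig, SyntheticSpec, assemble_fields,
                       column_filter, generate)


@pytest.fixture(scope="session")
def small_set():
    """A 12-compound synthetic aligned series with its planted truth."""
    spec = SyntheticSpec(n_compounds=12, noise_sd=0.1, seed=7)
    mols, acts, truth = generate(spec)
    return mols, acts, truth


@pytest.fixture(scope="session")
def small_fm(small_set):
    """Filtered CoMFA S+E field matrix of the 12-compound series."""
    mols, acts, truth = small_set
    cfg = FieldConfig(fields_enabled=("S", "E"))
    fm = assemble_fields(mols, truth.lattice, cfg, method="comfa")
    return column_filter(fm, 2.0)


@pytest.fixture(scope="session")
def small_xy(small_set, small_fm):
    _, acts, _ = small_set
    y = np.array([a.pic50 for a in acts])
    return small_fm, y
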