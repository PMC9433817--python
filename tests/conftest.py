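import numpy as np
import pytest

from repsat import (PopulationModel, UmiRead, generate_germline_set,
                    simulate_population)


@pytest.fixture(scope="session")
def germline():
    return generate_germline_set(5, 3, seed=7)


@pytest.fixture(scope="session")
def population(germline):
    return simulate_population(germline, PopulationModel(n_clones=200, seed=11))


def make_read(sequence, quality=37, umi="ACGTACGTACGT", read_id="r0", truth=None):
    """Convenience constructor: uniform quality unless an array is given."""
    if np.isscalar(quality):
        quality = np.full(len(sequence), quality, dtype=np.int16)
    return UmiRead(read_id=read_id, umi=umi, sequence=sequence,
                   qualities=np.asarray(quality), truth_clone_id=truth)
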