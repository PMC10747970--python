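import numpy as np
import pytest

from gaitagree.types import PairedSeries, parameter_spec


def make_series(ref, test, parameter="speed"):
    ref = np.asarray(ref, dtype=float)
    return PairedSeries(
        parameter=parameter_spec(parameter),
        subject_ids=tuple(f"S{i + 1:02d}" for i in range(ref.size)),
        ref_values=ref,
        test_values=np.asarray(test, dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
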