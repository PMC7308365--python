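import sys
from pathlib import Path

import pytest

# make tests/oracles.py importable regardless of invocation directory
sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture(scope="session")
def warm_kernel():
    """Trigger numba compilation once so timings elsewhere are clean."""
    from nichesim import ModelParams, init_full, run

    run(ModelParams(delta=0.5), init_full(8), t_max=2.0, seed=0)
    return True
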