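import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pmmkin import PerturbationFrame, gen_toy_qc


@pytest.fixture
def toy_qc():
    return gen_toy_qc(n_states=3, n_atoms=8, seed=42)


@pytest.fixture
def zero_frame(toy_qc):
    return PerturbationFrame(
        time=0.0,
        site_potentials=np.zeros(toy_qc.n_atoms),
        field=np.zeros(3),
    )
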