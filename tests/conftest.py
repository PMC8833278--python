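import numpy as np
import pytest

from pbsautoplan.beamspot import MachineModel
from pbsautoplan.phantom import PhantomSpec, generate_phantom, generate_toy_case


@pytest.fixture(scope="session")
def toy_case():
    return generate_toy_case()


@pytest.fixture(scope="session")
def phantom_case():
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def machine():
    return MachineModel()


def brute_force_dilate(mask: np.ndarray, margin_mm: float, spacing_mm: float) -> np.ndarray:
    """Oracle Euclidean dilation: enumerate integer offsets with
    ||(i,j,k)|| * spacing <= margin and union the shifted masks."""
    k = int(np.floor(margin_mm / spacing_mm + 1e-9))
    out = np.zeros_like(mask, dtype=bool)
    for i in range(-k, k + 1):
        for j in range(-k, k + 1):
            for l in range(-k, k + 1):
                if np.sqrt(i * i + j * j + l * l) * spacing_mm <= margin_mm + 1e-9:
                    out |= np.roll(mask, (i, j, l), axis=(0, 1, 2))
    return out
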