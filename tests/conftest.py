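import numpy as np
import pytest

from lesionjoint import JointModel, ModelConfig, PhantomParams
from lesionjoint.synthetic_data import generate_dataset


@pytest.fixture(scope="session")
def tiny_cfg() -> ModelConfig:
    """Smallest legal instantiation (16^3 grid) — exercises every layer."""
    return ModelConfig(input_size=(16, 16, 16), shared_channels=4,
                       cls_channels=(4, 8, 8), swin_heads=2)


@pytest.fixture(scope="session")
def desk_cfg() -> ModelConfig:
    return ModelConfig.desk()


@pytest.fixture(scope="session")
def tiny_model(tiny_cfg) -> JointModel:
    return JointModel(tiny_cfg, seed=11)


@pytest.fixture(scope="session")
def phantom_cases():
    """Six 32^3 phantoms (3 per class) shared across tests."""
    return generate_dataset(3, PhantomParams(grid_size=32), seed=123)


def fd_gradient(f, x0: np.ndarray, eps: float = 1e-2) -> np.ndarray:
    """Central finite-difference gradient of a scalar-valued function."""
    from lesionjoint.nn.tensor import Tensor

    num = np.zeros(x0.shape)
    it = np.nditer(x0, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x0.copy()
        xp[i] += eps
        xm = x0.copy()
        xm[i] -= eps
        num[i] = (float(f(Tensor(xp)).data) - float(f(Tensor(xm)).data)) / (2 * eps)
    return num
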