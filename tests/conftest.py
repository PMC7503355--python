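import numpy as np
import pandas as pd
import pytest

from md2qsar.core import Trajectory
from md2qsar.qsar import load_table2


@pytest.fixture(scope="session")
def table2():
    return load_table2()


def toy_trajectory(coords, radii=None, charges=None, eps=None, sigma=None,
                   groups=None, names=None, resids=None, resnames=None):
    """Assemble a Trajectory from raw arrays with simple defaults."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    n = coords.shape[1]
    atoms = pd.DataFrame(
        {
            "serial": np.arange(1, n + 1),
            "name": names if names is not None else ["CB"] * n,
            "resid": resids if resids is not None else np.arange(1, n + 1),
            "resname": resnames if resnames is not None else ["LEU"] * n,
            "group": groups if groups is not None else ["protein"] * n,
            "radius": radii if radii is not None else np.full(n, 1.9),
            "charge": charges if charges is not None else np.zeros(n),
            "lj_epsilon": eps if eps is not None else np.zeros(n),
            "lj_sigma": sigma if sigma is not None else np.full(n, 0.35),
        }
    )
    return Trajectory(atoms=atoms, coords=coords)
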