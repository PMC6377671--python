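import numpy as np
import pytest

from memins.bilayer import build_bilayer_model
from memins.trajectory import Trajectory


@pytest.fixture(scope="session")
def popc():
    return build_bilayer_model("POPC")


@pytest.fixture(scope="session")
def dmpc():
    return build_bilayer_model("DMPC")


def make_trajectory(
    z_series,
    times=None,
    drug_xy=(25.0, 25.0),
    lipid_coords=None,
    lipid_roles=None,
    box=(50.0, 50.0, 70.0),
):
    """Hand-built single-drug-atom trajectory for detection/contact tests."""
    z = np.asarray(z_series, dtype=float)
    n = len(z)
    times = np.asarray(times if times is not None else np.arange(n), dtype=float)
    drug = np.zeros((n, 1, 3))
    drug[:, 0, 0] = drug_xy[0]
    drug[:, 0, 1] = drug_xy[1]
    drug[:, 0, 2] = z
    if lipid_coords is None:
        lipid_coords = np.empty((n, 0, 3))
        lipid_roles = np.empty(0, dtype="U8")
    else:
        lipid_coords = np.asarray(lipid_coords, dtype=float)
        if lipid_coords.ndim == 2:
            lipid_coords = np.repeat(lipid_coords[None], n, axis=0)
        lipid_roles = np.asarray(lipid_roles, dtype="U8")
    return Trajectory(
        times=times,
        drug_coords=drug,
        lipid_coords=lipid_coords,
        lipid_roles=lipid_roles,
        lipid_leaflets=np.full(lipid_coords.shape[1], "U", dtype="U1"),
        box=np.asarray(box, dtype=float),
    )
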