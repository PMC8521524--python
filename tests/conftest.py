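import numpy as np
import pytest

from absb.cest import ExchangeModel
from absb.saltbridge import CarboxylateGroup, GuanidiniumGroup


@pytest.fixture
def free_arg_model() -> ExchangeModel:
    """Two-site exchange model at the free-arginine reference parameters."""
    return ExchangeModel(k_ex=356.0, delta_omega=1214.0, center_ppm=71.0)


def make_guanidinium(residue_index: int = 5) -> GuanidiniumGroup:
    """Idealised planar guanidinium centred at the origin (bond 1.33 A)."""
    bond = 1.33
    angles = np.deg2rad([0.0, 120.0, 240.0])
    ne, nh1, nh2 = (bond * np.array([np.cos(a), np.sin(a), 0.0]) for a in angles)
    return GuanidiniumGroup(
        residue_index=residue_index, cz=np.zeros(3), ne=ne, nh1=nh1, nh2=nh2
    )


def make_carboxylate(o1, o2, residue_index: int = 7, residue_name: str = "ASP"):
    """Carboxylate with the carbon completed between the given oxygens."""
    o1 = np.asarray(o1, dtype=float)
    o2 = np.asarray(o2, dtype=float)
    mid = 0.5 * (o1 + o2)
    axis = o2 - o1
    half = 0.5 * np.linalg.norm(axis)
    h = np.sqrt(max(1.25**2 - half**2, 0.04))
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-9:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    return CarboxylateGroup(
        residue_index=residue_index,
        residue_name=residue_name,
        carbon=mid + h * perp,
        o1=o1,
        o2=o2,
    )


@pytest.fixture
def guanidinium() -> GuanidiniumGroup:
    return make_guanidinium()
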