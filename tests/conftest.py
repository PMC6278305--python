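import numpy as np
import pytest
from hypothesis import settings

from nitrigeom.structures_io import ActiveSite, AtomRecord, HisNitrogen
from nitrigeom.synthetic_data import SiteSpec, make_site, random_rotation

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20180)


@pytest.fixture
def canonical_site():
    """Noise-free site in the canonical ligand frame (no random pose)."""
    return make_site(
        SiteSpec(
            theta_target=30.0,
            psi_target=20.0,
            cu_distance=2.2,
            phi_target=85.0,
            randomize_pose=False,
        )
    )


@pytest.fixture
def rigid_motion(rng):
    def _make():
        return random_rotation(rng), rng.uniform(-50.0, 50.0, size=3)

    return _make


def planar_site(his_azimuths_deg=(170.0, 85.0, -85.0), cu_o=None):
    """Hand-built site with Cu at the origin, nitrite N on +x, His in the
    xy-plane at the given angles from the Cu->N direction."""
    cu = np.zeros(3)
    nit_n = np.array([2.0, 0.0, 0.0])
    half = np.radians(115.0 / 2.0)
    bond = 1.25
    o1 = nit_n + bond * np.array([np.cos(np.pi - half), np.sin(np.pi - half), 0.0])
    o2 = nit_n + bond * np.array([np.cos(np.pi - half), -np.sin(np.pi - half), 0.0])
    his = []
    for num, ang in zip((99, 134, 289), np.radians(his_azimuths_deg)):
        his.append(
            HisNitrogen(num, "NE2", 2.0 * np.array([np.cos(ang), np.sin(ang), 0.0]))
        )
    return ActiveSite(cu=cu, his_n=his, nitrite_n=nit_n, nitrite_o1=o1, nitrite_o2=o2)


def atom(chain, resname, resnum, name, element, pos, occ=1.0, b=0.0, altloc="", model=1):
    return AtomRecord(
        chain_id=chain,
        residue_name=resname,
        residue_number=resnum,
        atom_name=name,
        element=element,
        position=np.asarray(pos, dtype=float),
        occupancy=occ,
        b_factor=b,
        altloc=altloc,
        model_index=model,
    )
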