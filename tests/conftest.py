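import numpy as np
import pytest

from rangeadapt.core_io import DecoderSpec, UnitTuning, direction_from_angles
from rangeadapt.synthetic import MechanismSpec, SimConfig, simulate_session


@pytest.fixture(scope="session")
def small_units():
    """Four hand-built units, including a mirrored pair across the xy-plane."""
    return [
        UnitTuning("up", 20.0, 8.0, direction_from_angles(-135.0, 45.0)),
        UnitTuning("dn", 20.0, 8.0, direction_from_angles(-130.0, -45.0)),
        UnitTuning("mid", 18.0, 6.0, direction_from_angles(20.0, 5.0)),
        UnitTuning("deep", 18.0, 6.0, direction_from_angles(100.0, -60.0)),
    ]


def make_session(kind="null", noise="none", seed=0, loop="open", n_units=12,
                 units=None, trials3=(2, 2), trials2=(2, 2), **mech_kwargs):
    """Compact session factory used across the suite."""
    mech = MechanismSpec(kind=kind, **mech_kwargs)
    cfg = SimConfig(
        n_units=n_units if units is None else len(units),
        noise=noise,
        seed=seed,
        loop=loop,
        mechanism=mech,
        trials_per_target_3d=trials3,
        trials_per_target_2d=trials2,
        # baselines above the largest depth keep the 0 Hz floor inactive in
        # noiseless identity checks
        b0_range=(16.0, 25.0),
        m_range=(3.0, 12.0),
    )
    return simulate_session(cfg, units=units)


@pytest.fixture(scope="session")
def noiseless_null_session():
    return make_session()


@pytest.fixture(scope="session")
def noiseless_dra_session():
    return make_session(kind="dra", completeness=1.0, n_units=20)
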