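import numpy as np
import pytest

import epsighost as eg


@pytest.fixture(scope="session")
def small_cfg() -> eg.SequenceConfig:
    """Desk-scale acquisition: 32x32 matrix, 48 echoes in one train.

    Same bandwidth/FOV as the full protocol, so all derived gradients and
    temporal offsets keep their physical values; only matrix sizes shrink.
    """
    return eg.SequenceConfig(
        n_read=32, n_phase=32, n_trains=1, echoes_per_train=48, delta_te_eff=0.8
    )


@pytest.fixture(scope="session")
def water_disc(small_cfg) -> eg.Phantom:
    """Decay-free on-resonance water disc: lines are exact DFT deltas."""
    return eg.make_water_oil_phantom(small_cfg, oil_density=0.0, t2_water=np.inf)


@pytest.fixture(scope="session")
def ets_single(small_cfg, water_disc) -> eg.EchoTrainSet:
    return eg.simulate(water_disc, small_cfg)


@pytest.fixture(scope="session")
def voi10(small_cfg) -> eg.VOI:
    dy = small_cfg.fov_phase / small_cfg.n_phase
    dx = small_cfg.fov_read / small_cfg.n_read
    return eg.disc_voi((small_cfg.n_phase, small_cfg.n_read), (dy, dx), radius_mm=10.0)
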