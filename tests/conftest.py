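"""Shared fixtures: small deterministic phantoms and SMS measurement chains."""

import numpy as np
import pytest

from smshsl import (AcquisitionSpec, CAIPISchedule, caipi_modulate, collapse,
                    encode_slice, ifft2c, make_phantom)
from smshsl.recon import rss_combine


class SMSScenario:
    """A fully simulated SMS experiment with ground truth."""

    def __init__(self, nx=32, ns=2, nc=6, ti_ms=(50, 850, 2850), noise_sd=0.0, seed=1):
        self.scene = make_phantom(nx=nx, ny=nx, n_slices=ns, n_coils=nc, seed=seed)
        self.acq = AcquisitionSpec(ti_ms=list(ti_ms), tr_ms=3000.0,
                                   noise_sd=noise_sd, seed=seed)
        self.schedule = CAIPISchedule(ns)
        self.slices = [encode_slice(self.scene, s, self.acq) for s in range(ns)]
        self.modulated = [caipi_modulate(self.slices[s], s, self.schedule)
                          for s in range(ns)]
        self.collapsed = collapse(self.modulated, noise_sd=noise_sd, seed=seed)
        self.truth_rss = [rss_combine(ifft2c(s.data), axis=2) for s in self.slices]

    @property
    def ti_ms(self):
        return self.acq.ti_ms


@pytest.fixture(scope="session")
def sms2():
    """Noiseless 32×32 two-slice scenario (cheap, reused across tests)."""
    return SMSScenario(nx=32, ns=2, nc=6)


@pytest.fixture(scope="session")
def sms3():
    """Noiseless 40×40 three-slice scenario with five TIs."""
    return SMSScenario(nx=40, ns=3, nc=8, ti_ms=(50, 650, 1250, 1850, 2850))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def recon_cfg():
    """Solver settings for unit-scale synthetic data at desk size."""
    from smshsl import ReconConfig
    return ReconConfig(outer_iters=60, cg_iters=8, rank_R=None, alpha=1.0,
                       stop_tol=1e-6, solver_dtype="complex64")


@pytest.fixture(scope="session")
def sms2_recon(sms2, recon_cfg):
    """Group reconstruction of the two-slice scenario (shared across tests)."""
    from smshsl.recon import reconstruct_group
    return reconstruct_group(sms2.collapsed, sms2.slices, sms2.schedule, recon_cfg)
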