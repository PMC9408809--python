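import numpy as np
import pytest

import myodti as m


@pytest.fixture(scope="session")
def default_phantom() -> m.PhantomStudy:
    """Default noisy phantom shared across tests (read-only)."""
    return m.make_lv_phantom(m.PhantomConfig(seed=11))


@pytest.fixture(scope="session")
def noise_free_phantom() -> m.PhantomStudy:
    """Phantom with noise-free DWI/LGE/T1 for exact-recovery checks."""
    cfg = m.PhantomConfig(
        seed=12, snr=np.inf, lge_intensity=(100.0, 0.0, 300.0, 1e-9), t1_noise_ms=0.0
    )
    return m.make_lv_phantom(cfg)


@pytest.fixture(scope="session")
def annulus_64() -> dict:
    """Analytic annulus geometry on a 64x64 grid at 2 mm pixels."""
    yy, xx = np.meshgrid(np.arange(64) - 31.5, np.arange(64) - 31.5, indexing="ij")
    r = np.hypot(yy * 2.0, xx * 2.0)
    theta = np.degrees(np.arctan2(yy, xx))
    return {"r": r, "theta": theta, "mask_20_30": (r >= 20) & (r <= 30)}
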