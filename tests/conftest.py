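import numpy as np
import pytest

from bolddelay import BoldSeries, SyntheticConfig, generate_subject


def brute_force_lag(x, ref, max_lag, tr):
    """Independent oracle: exhaustive integer-shift argmax of the Pearson r.

    Uses np.corrcoef per shift; ties broken toward the smallest |lag| by
    visiting shifts in (|d|, d) order and keeping strict improvements only.
    """
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    n = ref.size
    d_max = int(round(max_lag / tr))
    best = None
    for d in sorted(range(-d_max, d_max + 1), key=lambda d: (abs(d), d)):
        if d >= 0:
            xv, rv = x[d:], ref[: n - d]
        else:
            xv, rv = x[: n + d], ref[-d:]
        if rv.size < 3 or np.std(xv) == 0 or np.std(rv) == 0:
            continue
        r = np.corrcoef(xv, rv)[0, 1]
        if best is None or r > best[1]:
            best = (d * tr, r)
    return best if best is not None else (np.nan, np.nan)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale subject: small grid, short scan, noise-free recovery grid."""
    return SyntheticConfig(grid_shape=(20, 20, 10), voxel_size=(3.0, 3.0, 4.0),
                           n_frames=300, lesion_fraction=0.08, snr=10.0,
                           motion_amplitude=0.1, seed=42)


@pytest.fixture(scope="session")
def small_subject(small_cfg):
    return generate_subject(small_cfg)


@pytest.fixture(scope="session")
def noisefree_subject(small_cfg):
    import dataclasses
    import math
    cfg = dataclasses.replace(small_cfg, snr=math.inf, motion_amplitude=0.0, seed=7)
    return generate_subject(cfg)


@pytest.fixture()
def toy_series():
    """4-voxel series with an everywhere-true brain mask, for arithmetic checks."""
    def make(data, voxel_size=(1.0, 1.0, 1.0), tr=1.0, brain_mask=None):
        data = np.asarray(data, dtype=float)
        if brain_mask is None:
            brain_mask = np.ones(data.shape[:3], dtype=bool)
        return BoldSeries(data=data, voxel_size=voxel_size, tr=tr,
                          brain_mask=brain_mask)
    return make
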