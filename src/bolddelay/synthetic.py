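"""Synthetic 4D BOLD cohorts with known hemodynamic-lag ground truth.

The generator emulates the physical premise of BOLD-delay perfusion mapping:
a systemic low-frequency oscillation (sLFO, 0.01-0.15 Hz) travels with the
blood and reaches each voxel with a spatially smooth delay.  A stroke-like
perfusion lesion is an ellipsoidal region whose delays are several seconds
longer than the normal range; the venous-sinus reference region sits outside
the parenchyma and carries the undelayed signal.  Every subject comes with
the true lag field, lesion and DWI-core masks, a vascular-territory atlas
and a motion trace, so each downstream stage can be tested against truth.

Fractional delays are applied as frequency-domain phase ramps, which are
exact for band-limited signals — no interpolation bias at TR = 0.4 s.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .preprocess import BoldSeries, MotionTrace

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SubjectBundle",
    "generate_slfo",
    "delay_series",
    "generate_subject",
    "generate_cohort",
    "derive_subject_seeds",
]

#: lag search window used downstream; configured lag ranges must stay inside it
TRACKING_LIMIT_S = 20.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic subject / cohort.

    Defaults mirror the acquisition being emulated: TR = 0.4 s, 850 frames
    (340 s multiband EPI), sLFO band 0.01-0.15 Hz.  The grid is desk-scale
    (32 x 32 x 16 voxels at 3 x 3 x 4 mm) but keeps genuine 3D morphology.
    Normal-tissue lags span -2..+2 s; lesion lags 3..10 s, comfortably above
    the delineation thresholds (2.3 / 4.6 s) and inside the +/-20 s tracking
    range.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 4.0)
    tr: float = 0.4
    n_frames: int = 850
    slfo_band: tuple[float, float] = (0.01, 0.15)
    lag_range_normal: tuple[float, float] = (-2.0, 2.0)
    lag_range_lesion: tuple[float, float] = (3.0, 10.0)
    lesion_fraction: float = 0.06
    snr: float = 10.0
    n_territories: int = 3
    motion_amplitude: float = 0.2
    motion_coupling: float = 0.0
    lag_smoothness_vox: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive integers, got {self.grid_shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.tr <= 0 or self.n_frames <= 0:
            raise ValueError("tr and n_frames must be positive")
        nyq = 0.5 / self.tr
        lo, hi = self.slfo_band
        if not (0.0 < lo < hi < nyq):
            raise ValueError(
                f"slfo_band {self.slfo_band} must lie strictly inside (0, Nyquist={nyq:g})"
            )
        for name, (a, b) in (("lag_range_normal", self.lag_range_normal),
                             ("lag_range_lesion", self.lag_range_lesion)):
            if not (a < b):
                raise ValueError(f"{name} must be an increasing pair")
            if a <= -TRACKING_LIMIT_S or b >= TRACKING_LIMIT_S:
                raise ValueError(f"{name} must lie strictly inside +/-{TRACKING_LIMIT_S} s")
        if not (0.0 < self.lesion_fraction < 1.0):
            raise ValueError("lesion_fraction must lie in (0, 1)")
        if not (self.snr > 0):
            raise ValueError("snr must be positive (math.inf disables noise)")
        if self.n_territories < 2:
            raise ValueError("need at least 2 vascular territories")
        if self.motion_amplitude < 0:
            raise ValueError("motion_amplitude must be non-negative")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    lag_field: np.ndarray          # seconds, defined on brain+sinus, 0 elsewhere
    lesion_mask: np.ndarray        # perfusion lesion (delayed region)
    sinus_mask: np.ndarray         # reference region, outside the parenchyma
    territory_atlas: np.ndarray    # integer labels over the brain, 0 = background
    dwi_mask: np.ndarray           # infarct core, subset of the lesion
    slfo_signal: np.ndarray        # the shared low-frequency oscillation
    amplitude_field: np.ndarray    # per-voxel sLFO amplitude
    territory_names: dict[int, str] = field(default_factory=dict)


@dataclass
class SubjectBundle:
    """One synthetic acquisition: images, truth, motion."""

    series: BoldSeries
    truth: GroundTruth
    motion: MotionTrace
    subject_id: str = "sub-000"
    seed: int = 0


def generate_slfo(n_frames: int, tr: float, band: tuple[float, float],
                  seed: int | np.random.Generator) -> np.ndarray:
    """A zero-mean, unit-variance band-limited noise series.

    Gaussian white noise is brick-wall filtered to ``band`` in the frequency
    domain, then standardized, so essentially all spectral power lies inside
    the band without committing to any parametric waveform.
    """
    nyq = 0.5 / tr
    lo, hi = band
    if not (0.0 < lo < hi < nyq):
        raise ValueError(f"band {band} must lie strictly inside (0, Nyquist={nyq:g})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n_frames)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_frames, d=tr)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    if not np.any((freqs >= lo) & (freqs <= hi)):
        raise ValueError("band contains no frequency bins at this length/TR")
    x = np.fft.irfft(spec, n=n_frames)
    x -= x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate sLFO (zero variance)")
    return x / sd


def delay_series(signal_1d: np.ndarray, lags_s: np.ndarray, tr: float) -> np.ndarray:
    """Delay one series by many (fractional) lags via spectral phase ramps.

    Returns an (n_lags, n_frames) array where row v is ``signal(t - lag_v)``
    under the circular (periodic) extension — exact for band-limited input.
    """
    signal_1d = np.asarray(signal_1d, dtype=float).ravel()
    lags_s = np.atleast_1d(np.asarray(lags_s, dtype=float))
    n = signal_1d.size
    spec = np.fft.rfft(signal_1d)
    freqs = np.fft.rfftfreq(n, d=tr)
    ramp = np.exp(-2j * np.pi * freqs[None, :] * lags_s[:, None])
    return np.fft.irfft(spec[None, :] * ramp, n=n, axis=1)


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return acc <= 1.0


def _make_geometry(cfg: SyntheticConfig, rng: np.random.Generator):
    """Brain ellipsoid, sinus block, territory slabs, lesion and DWI core."""
    shape = cfg.grid_shape
    center = tuple((s - 1) / 2.0 for s in shape)
    semi = tuple(max(1.5, 0.38 * s) for s in shape)
    brain = _ellipsoid(shape, center, semi)

    # venous sinus: small block posterior to the brain (outside the parenchyma)
    sy = int(math.ceil(center[1] + semi[1]))
    sinus = np.zeros(shape, dtype=bool)
    x0, z0 = int(center[0]), int(center[2])
    sinus[max(0, x0 - 1): x0 + 2, sy: min(shape[1], sy + 2),
          max(0, z0 - 1): z0 + 2] = True
    sinus &= ~brain
    if not sinus.any():  # tiny grids: carve the sinus out of the edge of the mask
        sinus[x0, shape[1] - 1, z0] = True
        brain[x0, shape[1] - 1, z0] = False

    # vascular territories: anterior->posterior slabs over the brain
    atlas = np.zeros(shape, dtype=np.int32)
    ys = np.nonzero(brain)[1]
    edges = np.quantile(ys, np.linspace(0, 1, cfg.n_territories + 1))
    yy = np.broadcast_to(np.arange(shape[1])[None, :, None], shape)
    for k in range(cfg.n_territories):
        lo, hi = edges[k], edges[k + 1]
        sel = brain & (yy >= lo) & (yy <= hi if k == cfg.n_territories - 1 else yy < hi)
        atlas[sel & (atlas == 0)] = k + 1
    atlas[brain & (atlas == 0)] = cfg.n_territories  # guard against edge effects
    names = {k + 1: f"territory_{k + 1}" for k in range(cfg.n_territories)}

    # lesion: ellipsoid centred inside one randomly chosen territory
    target_vox = cfg.lesion_fraction * brain.sum()
    if target_vox < 1:
        raise ValueError(
            f"lesion_fraction {cfg.lesion_fraction} yields less than one voxel on this grid"
        )
    label = int(rng.integers(1, cfg.n_territories + 1))
    coords = np.array(np.nonzero(atlas == label))
    centroid = coords.mean(axis=1)
    jitter = rng.uniform(-1.5, 1.5, size=3)
    lcenter = np.clip(centroid + jitter, 1, np.array(shape) - 2)
    scale = (target_vox / max(brain.sum(), 1)) ** (1.0 / 3.0)
    lsemi = np.maximum(1.0, scale * np.array(semi))
    lesion = _ellipsoid(shape, lcenter, lsemi) & brain
    if not lesion.any():
        lesion = np.zeros(shape, dtype=bool)
        lesion[tuple(np.round(lcenter).astype(int))] = True
        lesion &= brain
        if not lesion.any():
            raise ValueError("lesion placement failed: centre fell outside the brain")

    dwi = _ellipsoid(shape, lcenter, np.maximum(0.75, 0.55 * lsemi)) & lesion
    if not dwi.any():
        core = tuple(c[0] for c in np.nonzero(lesion))
        dwi = np.zeros(shape, dtype=bool)
        dwi[core] = True
    return brain, sinus, atlas, names, lesion, dwi


def _smooth_field(shape, sigma, rng) -> np.ndarray:
    """Smooth random field rescaled to [-1, 1]."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    m = np.max(np.abs(f))
    return f / m if m > 0 else f


def _motion_trace(cfg: SyntheticConfig, rng: np.random.Generator) -> MotionTrace:
    n = cfg.n_frames
    if cfg.motion_amplitude == 0:
        return MotionTrace(np.zeros((n, 3)), np.zeros((n, 3)))
    # slow drifts: smoothed random walks, zero at frame 0
    def walk(scale: float) -> np.ndarray:
        steps = rng.standard_normal((n, 3))
        w = np.cumsum(steps, axis=0)
        w = ndimage.gaussian_filter1d(w, sigma=10.0, axis=0)
        w -= w[0]
        peak = np.max(np.abs(w)) or 1.0
        return w * (scale / peak)

    trans = walk(cfg.motion_amplitude)
    rot = walk(cfg.motion_amplitude / 50.0)  # comparable FD contribution on a 50 mm sphere
    return MotionTrace(trans, rot)


def generate_subject(cfg: SyntheticConfig) -> SubjectBundle:
    """One synthetic acquisition with ground truth.

    Voxel time course = amplitude x sLFO delayed by the voxel's true lag
    + white noise with standard deviation amplitude / snr, on a baseline of
    100 intensity units.  Sinus voxels carry lag 0 by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    brain, sinus, atlas, names, lesion, dwi = _make_geometry(cfg, rng)
    shape = cfg.grid_shape

    # spatially smooth lag field; lesion voxels remapped into the lesion range
    base = _smooth_field(shape, cfg.lag_smoothness_vox, rng)
    a, b = cfg.lag_range_normal
    lag = (a + b) / 2.0 + (b - a) / 2.0 * base
    la, lb = cfg.lag_range_lesion
    lesion_field = _smooth_field(shape, cfg.lag_smoothness_vox, rng)
    if lesion.any():
        # rescale within the lesion so its lags span the configured range
        lf = lesion_field[lesion]
        span = lf.max() - lf.min()
        if span > 0:
            lesion_field = (lesion_field - lf.min()) / span  # [0, 1] inside lesion
        else:
            lesion_field = np.full_like(lesion_field, 0.5)
        lag = np.where(lesion, la + (lb - la) * lesion_field, lag)
    lag[~(brain | sinus)] = 0.0
    lag[sinus] = 0.0

    amp = 1.0 + 0.3 * _smooth_field(shape, cfg.lag_smoothness_vox, rng)
    amp = np.clip(amp, 0.3, None)
    amp[sinus] = 1.5  # venous signal is sLFO-rich
    amp[~(brain | sinus)] = 0.0

    slfo = generate_slfo(cfg.n_frames, cfg.tr, cfg.slfo_band, rng)
    active = brain | sinus
    delayed = delay_series(slfo, lag[active], cfg.tr)

    data = np.full(shape + (cfg.n_frames,), 100.0)
    data[active] += amp[active][:, None] * delayed

    motion = _motion_trace(cfg, rng)
    if cfg.motion_coupling > 0 and cfg.motion_amplitude > 0:
        artifact = np.abs(motion.translations).sum(axis=1)
        artifact = artifact - artifact.mean()
        sd = artifact.std() or 1.0
        data[active] += (cfg.motion_coupling * amp[active])[:, None] * (artifact / sd)[None, :]

    if math.isfinite(cfg.snr):
        noise = rng.standard_normal(data.shape)
        sigma = np.where(active, amp / cfg.snr, 1.0 / cfg.snr)
        data += sigma[..., None] * noise

    series = BoldSeries(data=data, voxel_size=cfg.voxel_size, tr=cfg.tr, brain_mask=brain)
    truth = GroundTruth(lag_field=lag, lesion_mask=lesion, sinus_mask=sinus,
                        territory_atlas=atlas, dwi_mask=dwi, slfo_signal=slfo,
                        amplitude_field=amp, territory_names=names)
    return SubjectBundle(series=series, truth=truth, motion=motion,
                         subject_id=f"sub-{cfg.seed:05d}", seed=cfg.seed)


def derive_subject_seeds(master_seed: int, n_subjects: int) -> list[int]:
    """Distinct per-subject seeds derived deterministically from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(n_subjects)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def generate_cohort(cfg: SyntheticConfig, n_subjects: int, out_dir: str | Path,
                    seed: int | None = None) -> dict:
    """Write an n-subject cohort to disk and return the manifest.

    Per subject: 4D BOLD NIfTI, mask/atlas/truth NIfTIs, motion TSV and a
    truth sidecar JSON; a cohort-level ``manifest.json`` lists all paths and
    the derived seeds.
    """
    from . import io as bdio  # deferred: keeps nibabel off the hot import path

    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    master = cfg.seed if seed is None else seed
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, sub_seed in enumerate(derive_subject_seeds(master, n_subjects)):
        sub_cfg = dataclasses.replace(cfg, seed=sub_seed)
        bundle = generate_subject(sub_cfg)
        bundle.subject_id = f"sub-{i:03d}"
        sub_dir = out_dir / bundle.subject_id
        paths = bdio.save_subject(bundle, sub_dir)
        entries.append({"subject_id": bundle.subject_id, "seed": sub_seed,
                        "paths": {k: str(v) for k, v in paths.items()}})
    manifest = {
        "master_seed": master,
        "n_subjects": n_subjects,
        "config": dataclasses.asdict(cfg) | {"seed": master},
        "subjects": entries,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
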