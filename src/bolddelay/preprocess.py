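"""Preprocessing of 4D BOLD series for hemodynamic lag mapping.

The fixed pipeline order is: initial-volume discard -> rigid-motion confound
regression -> spatial smoothing -> zero-phase band-pass.  Zero-phase filtering
matters: any phase distortion in the temporal filter would bias the
cross-correlation delay estimates downstream.

Motion quality control follows the Power convention: framewise displacement
(FD) sums absolute frame-to-frame translation deltas plus rotation deltas
converted to millimetres on a 50 mm sphere; DVARS is the frame-to-frame root
mean square intensity change over brain voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "BoldSeries",
    "MotionTrace",
    "SegmentSpec",
    "discard_initial",
    "make_segments",
    "regress_confounds",
    "smooth_spatial",
    "band_pass",
    "framewise_displacement",
    "dvars",
    "FWHM_TO_SIGMA",
    "DEFAULT_HEAD_RADIUS_MM",
]

#: conversion factor between Gaussian FWHM and standard deviation
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # = 1/2.3548...

#: head radius (mm) used to convert rotations to displacements (Power convention)
DEFAULT_HEAD_RADIUS_MM = 50.0


@dataclass
class BoldSeries:
    """A 4D BOLD acquisition: intensities on a voxel grid plus geometry.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Voxel intensities.
    voxel_size : 3-tuple of float
        Voxel edge lengths in mm.
    tr : float
        Repetition time in seconds.
    brain_mask : ndarray of bool, shape (x, y, z)
        Parenchyma mask. QC metrics and lag mapping are restricted to it.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    tr: float
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x,y,z,t), got shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive reals, got {self.voxel_size}")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"brain_mask shape {self.brain_mask.shape} does not match "
                f"spatial shape {self.data.shape[:3]}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def duration(self) -> float:
        """Scan duration in seconds."""
        return self.n_frames * self.tr


@dataclass
class MotionTrace:
    """Per-frame rigid-body motion parameters.

    translations in mm, rotations in radians; one row per frame.  ``fd_series``
    and ``dvars_series`` are filled in by :func:`framewise_displacement` and
    :func:`dvars`; their first entry is NaN (undefined for the first frame).
    """

    translations: np.ndarray
    rotations: np.ndarray
    fd_series: np.ndarray | None = field(default=None)
    dvars_series: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.translations = np.asarray(self.translations, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        for name, arr in (("translations", self.translations), ("rotations", self.rotations)):
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"{name} must have shape (n_frames, 3), got {arr.shape}")
        if self.translations.shape[0] != self.rotations.shape[0]:
            raise ValueError("translations and rotations must have the same number of frames")

    @property
    def n_frames(self) -> int:
        return self.translations.shape[0]

    def truncate(self, start: int, stop: int) -> "MotionTrace":
        """Frames ``start:stop`` as a new trace (QC series are dropped)."""
        return MotionTrace(self.translations[start:stop], self.rotations[start:stop])

    def confound_matrix(self) -> np.ndarray:
        """The six rigid-body columns, frames x 6."""
        return np.hstack([self.translations, self.rotations])


@dataclass(frozen=True)
class SegmentSpec:
    """A prefix truncation of the post-discard scan.

    ``fraction`` refers to the original (pre-discard) scan length, so the
    reported duration of e.g. the 0.2 segment of an 850-frame, TR = 0.4 s
    acquisition is 68 s.
    """

    fraction: float
    n_frames_segment: int
    duration: float


def discard_initial(series: BoldSeries, n_discard: int) -> BoldSeries:
    """Drop the first ``n_discard`` volumes (magnetization equilibrium).

    Raises ``ValueError`` if nothing would remain.
    """
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= series.n_frames:
        raise ValueError(
            f"cannot discard {n_discard} of {series.n_frames} frames: empty result"
        )
    return replace(series, data=series.data[..., n_discard:])


def make_segments(
    series: BoldSeries,
    fractions: Sequence[float],
    n_original: int,
) -> list[tuple[SegmentSpec, BoldSeries]]:
    """Cut prefix segments of the post-discard series.

    ``fractions`` are relative to ``n_original``, the pre-discard frame count.
    Each segment keeps the first ``round(fraction * n_original)`` frames of the
    post-discard data, capped at its length (so fraction 1.0 yields the full
    post-discard series).  Reported duration is the kept frame count times TR.
    """
    if n_original < series.n_frames:
        raise ValueError("n_original must be at least the post-discard frame count")
    out: list[tuple[SegmentSpec, BoldSeries]] = []
    for frac in fractions:
        if not (0.0 < frac <= 1.0):
            raise ValueError(f"fraction must lie in (0, 1], got {frac}")
        n_seg = min(int(round(frac * n_original)), series.n_frames)
        if n_seg < 2:
            raise ValueError(f"fraction {frac} yields {n_seg} frames (< 2)")
        spec = SegmentSpec(fraction=float(frac), n_frames_segment=n_seg,
                           duration=n_seg * series.tr)
        out.append((spec, replace(series, data=series.data[..., :n_seg])))
    return out


def regress_confounds(series: BoldSeries, confounds: np.ndarray) -> BoldSeries:
    """Remove confound time courses from every voxel by OLS.

    The design is an intercept plus the confound columns; each voxel series is
    replaced by its residuals.  Collinear confound columns are dropped with a
    warning so the fit stays well-posed.
    """
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] != series.n_frames:
        raise ValueError(
            f"confounds have {confounds.shape[0]} rows, series has {series.n_frames} frames"
        )
    n_t = series.n_frames
    design = np.column_stack([np.ones(n_t), confounds])
    # drop columns that do not increase design rank (collinearity guard)
    keep = [0]
    rank = 1
    for j in range(1, design.shape[1]):
        cand = design[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            warnings.warn(
                f"confound column {j - 1} is collinear with the design and was dropped",
                stacklevel=2,
            )
    design = design[:, keep]

    flat = series.data.reshape(-1, n_t).T  # (t, voxels)
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ beta
    return replace(series, data=resid.T.reshape(series.data.shape))


def smooth_spatial(series: BoldSeries, fwhm: float) -> BoldSeries:
    """Per-frame 3D Gaussian smoothing with the kernel width given in mm."""
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return replace(series, data=series.data.copy())
    sigma_vox = tuple(fwhm * FWHM_TO_SIGMA / v for v in series.voxel_size)
    smoothed = ndimage.gaussian_filter(series.data, sigma=sigma_vox + (0.0,))
    return replace(series, data=smoothed)


def band_pass(series: BoldSeries, low: float, high: float) -> BoldSeries:
    """Zero-phase Butterworth band-pass along time; removes the mean.

    Implemented as a forward-backward second-order-sections filter
    (order 2 per direction) so the pass band incurs no phase shift —
    a lag-free filter is a precondition for unbiased delay estimates.
    """
    nyquist = 0.5 / series.tr
    if not (0.0 < low < high < nyquist):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyquist:g} Hz)"
        )
    sos = signal.butter(2, [low, high], btype="bandpass", fs=1.0 / series.tr, output="sos")
    filtered = signal.sosfiltfilt(sos, series.data, axis=-1)
    filtered = filtered - filtered.mean(axis=-1, keepdims=True)
    return replace(series, data=filtered)


def framewise_displacement(
    trace: MotionTrace, head_radius: float = DEFAULT_HEAD_RADIUS_MM
) -> tuple[np.ndarray, float, float]:
    """Power-style framewise displacement.

    FD_t = sum |Delta translations| + head_radius * sum |Delta rotations|,
    defined for frames t >= 2 (first entry NaN).  Returns the per-frame
    series, its mean over defined entries, and the mean rescaled by 10
    (the rescaling used when FD enters regression models alongside
    larger-scale covariates).
    """
    if trace.n_frames < 2:
        raise ValueError("framewise displacement needs at least 2 frames")
    dtrans = np.abs(np.diff(trace.translations, axis=0)).sum(axis=1)
    drot = np.abs(np.diff(trace.rotations, axis=0)).sum(axis=1)
    fd = np.concatenate([[np.nan], dtrans + head_radius * drot])
    mean_fd = float(np.nanmean(fd))
    return fd, mean_fd, mean_fd * 10.0


def dvars(series: BoldSeries) -> tuple[np.ndarray, float]:
    """Frame-to-frame RMS intensity change over brain voxels.

    DVARS_t = sqrt(mean over brain voxels of (I_t - I_{t-1})^2), t >= 2;
    the first entry is NaN.  Returns the series and its mean over defined
    entries.
    """
    if series.n_frames < 2:
        raise ValueError("DVARS needs at least 2 frames")
    if not series.brain_mask.any():
        raise ValueError("brain mask is empty")
    vox = series.data[series.brain_mask]  # (n_vox, t)
    diffs = np.diff(vox, axis=1)
    dv = np.concatenate([[np.nan], np.sqrt(np.mean(diffs**2, axis=0))])
    return dv, float(np.nanmean(dv))
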