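"""Automated perfusion-lesion delineation on delay-type maps.

The search is restricted to the vascular territory affected by the stroke —
the territory (or territories) containing the acute DWI lesion — and keeps
voxels whose delay strictly exceeds a threshold, after removing connected
components (26-connectivity) smaller than a minimum volume.  The same
procedure serves BOLD-delay maps (thresholds 0 / 2.3 / 4.6 s) and
Tmax-like maps (threshold 6 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .lagmap import LagMap

__all__ = [
    "TerritoryAtlas",
    "DelineationResult",
    "affected_territory",
    "delineate_lesion",
    "lesion_volume",
]

#: full 3D connectivity (26 neighbours) for cluster labelling
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class TerritoryAtlas:
    """Integer-labelled vascular territories; 0 is background."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("territory atlas must be a 3D label map")

    def mask_of(self, labels: set[int] | frozenset[int]) -> np.ndarray:
        return np.isin(self.labels, list(labels))


@dataclass
class DelineationResult:
    """A delineated perfusion lesion at one threshold."""

    lesion_mask: np.ndarray
    threshold: float
    volume_ml: float
    affected_labels: frozenset[int]
    map_kind: str = "bold_delay"  # or "tmax"
    n_clusters: int = 0


def affected_territory(atlas: TerritoryAtlas, dwi_mask: np.ndarray,
                       min_fraction: float = 0.05) -> set[int]:
    """Territory labels containing the acute DWI lesion.

    A label is affected if it holds at least ``min_fraction`` of the DWI
    lesion voxels; if no label reaches the cutoff the single label with the
    largest overlap is returned, so the result is never empty.
    """
    dwi_mask = np.asarray(dwi_mask, dtype=bool)
    if dwi_mask.shape != atlas.labels.shape:
        raise ValueError("DWI mask grid does not match the atlas")
    if not dwi_mask.any():
        raise ValueError("DWI mask is empty")
    in_atlas = dwi_mask & (atlas.labels > 0)
    if not in_atlas.any():
        raise ValueError("DWI lesion lies entirely outside the territory atlas")
    labels, counts = np.unique(atlas.labels[in_atlas], return_counts=True)
    fractions = counts / dwi_mask.sum()
    selected = {int(l) for l, f in zip(labels, fractions) if f >= min_fraction}
    if not selected:
        selected = {int(labels[np.argmax(counts)])}
    return selected


def lesion_volume(mask: np.ndarray, voxel_size) -> float:
    """Volume of a binary mask in mL (voxel count x voxel volume / 1000)."""
    mask = np.asarray(mask, dtype=bool)
    return float(mask.sum()) * float(np.prod(voxel_size)) / 1000.0


def delineate_lesion(
    delay_map: LagMap | np.ndarray,
    threshold: float,
    territory_labels: set[int],
    atlas: TerritoryAtlas,
    voxel_size,
    min_cluster_ml: float = 1.0,
    use_validity: bool = True,
    map_kind: str | None = None,
) -> DelineationResult:
    """Supra-threshold hypoperfusion within the affected territory.

    Keeps voxels with value strictly greater than ``threshold`` inside the
    union of ``territory_labels``; for :class:`LagMap` inputs only
    significance-passing voxels participate (when ``use_validity``).
    Connected components smaller than ``min_cluster_ml`` are discarded.
    An empty result is legal (volume 0).
    """
    if isinstance(delay_map, LagMap):
        values = delay_map.lags
        eligible = delay_map.valid if use_validity else np.ones_like(delay_map.valid)
        kind = map_kind or "bold_delay"
    else:
        values = np.asarray(delay_map, dtype=float)
        eligible = np.ones(values.shape, dtype=bool)
        kind = map_kind or "tmax"
    if values.shape != atlas.labels.shape:
        raise ValueError("map grid does not match the atlas")

    territory = atlas.mask_of(territory_labels)
    candidate = (values > threshold) & eligible & territory

    labelled, n_comp = ndimage.label(candidate, structure=_STRUCT_26)
    min_vox = min_cluster_ml * 1000.0 / float(np.prod(voxel_size))
    keep = np.zeros_like(candidate)
    n_kept = 0
    for comp in range(1, n_comp + 1):
        comp_mask = labelled == comp
        if comp_mask.sum() >= min_vox:
            keep |= comp_mask
            n_kept += 1
    return DelineationResult(
        lesion_mask=keep,
        threshold=float(threshold),
        volume_ml=lesion_volume(keep, voxel_size),
        affected_labels=frozenset(int(l) for l in territory_labels),
        map_kind=kind,
        n_clusters=n_kept,
    )
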