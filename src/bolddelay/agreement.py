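"""Spatial, volumetric and rating agreement statistics.

Dice similarity coefficient for mask overlap, Bland-Altman bias and 95%
limits of agreement (with percent bias relative to the mean of the two
methods) for volumes, and Cohen's kappa (unweighted or quadratic-weighted)
for categorical ratings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "AgreementReport",
    "RatingTable",
    "compute_dice",
    "bland_altman",
    "cohen_kappa",
]


@dataclass
class AgreementReport:
    """Agreement between two lesion measurements over a cohort.

    ``dice`` is None when undefined (both masks empty / not applicable).
    """

    bias_ml: float
    loa_low_ml: float
    loa_high_ml: float
    percent_bias: float
    n_pairs: int
    dice: float | None = None

    def __post_init__(self) -> None:
        if not (self.loa_low_ml <= self.bias_ml <= self.loa_high_ml):
            raise ValueError("limits of agreement must bracket the bias")
        if self.dice is not None and not (0.0 <= self.dice <= 1.0):
            raise ValueError("dice must lie in [0, 1] when defined")


@dataclass
class RatingTable:
    """k x k contingency table of two raters' ordinal ratings."""

    categories: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.categories)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k} to match the categories")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() < 1:
            raise ValueError("rating table must contain at least one rating")


def compute_dice(a: np.ndarray, b: np.ndarray) -> float | None:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|).

    Returns None (undefined, not zero) when both masks are empty; 0.0 when
    exactly one is empty.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return None
    return 2.0 * int((a & b).sum()) / (na + nb)


def bland_altman(v_test: Sequence[float], v_ref: Sequence[float]) -> AgreementReport:
    """Bland-Altman agreement of paired measurements.

    bias = mean(test - ref); 95% limits of agreement = bias +/- 1.96 x sample
    SD of the differences; percent bias = 100 x bias / (mean over pairs of the
    pairwise means), i.e. over/underestimation relative to the mean of both
    methods.
    """
    v_test = np.asarray(v_test, dtype=float)
    v_ref = np.asarray(v_ref, dtype=float)
    if v_test.shape != v_ref.shape or v_test.ndim != 1:
        raise ValueError("v_test and v_ref must be equal-length 1D sequences")
    n = v_test.size
    if n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs (SD undefined)")
    d = v_test - v_ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    mean_of_means = float(((v_test + v_ref) / 2.0).mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * bias / mean_of_means if mean_of_means != 0 else float("nan")
    return AgreementReport(bias_ml=bias, loa_low_ml=bias - 1.96 * sd,
                           loa_high_ml=bias + 1.96 * sd, percent_bias=pct,
                           n_pairs=n)


def cohen_kappa(table: RatingTable, weighting: str = "none") -> float | None:
    """Chance-corrected agreement from a k x k rating table.

    kappa = 1 - (sum of weighted observed disagreement) / (sum of weighted
    expected disagreement), with disagreement weights 0/1 off the diagonal
    (unweighted) or ((i - j) / (k - 1))^2 (quadratic).  Expected proportions
    come from the marginal products.  Returns None when the expected
    disagreement is zero (degenerate marginals).
    """
    if weighting not in ("none", "quadratic"):
        raise ValueError(f"unknown weighting {weighting!r}")
    k = len(table.categories)
    if k < 2:
        raise ValueError("kappa needs at least 2 categories")
    p = table.counts / table.counts.sum()
    i, j = np.indices((k, k))
    if weighting == "none":
        w = (i != j).astype(float)
    else:
        w = ((i - j) / (k - 1)) ** 2
    expected = np.outer(p.sum(axis=1), p.sum(axis=0))
    obs_dis = float((w * p).sum())
    exp_dis = float((w * expected).sum())
    if exp_dis == 0.0:
        return None
    return 1.0 - obs_dis / exp_dis
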