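"""Cross-validated Mahalanobis (crossnobis) distances with noise normalisation.

Multivoxel beta patterns (runs x conditions x voxels) are compared pairwise
with the cross-validated Mahalanobis distance. Cross-validation across runs
makes the estimator unbiased: a pair of conditions that differ only by noise
has expected distance zero, so individual estimates can be negative.
Multivariate noise normalisation whitens the patterns with a precision
matrix estimated from run-wise GLM residuals, shrunk toward its diagonal.

Distances are normalised by voxel count so values are comparable across
ROI sizes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg

__all__ = [
    "PatternSet",
    "Rdm",
    "estimate_noise_precision",
    "shrunk_covariance",
    "crossnobis_rdm",
    "mean_pairwise_distance",
]


@dataclass
class PatternSet:
    """Beta patterns and residuals for one participant and ROI.

    ``patterns`` has shape (n_runs, n_conditions, n_voxels); ``residuals``
    holds one (n_timepoints, n_voxels) residual matrix per run, used to
    estimate the noise covariance.
    """

    patterns: np.ndarray
    conditions: tuple[str, ...]
    residuals: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.patterns.ndim != 3:
            raise ValueError("patterns must be (runs, conditions, voxels)")
        n_runs, n_cond, _ = self.patterns.shape
        if n_cond != len(self.conditions):
            raise ValueError("condition labels do not match pattern shape")
        if n_runs < 2:
            raise ValueError("cross-validation requires at least 2 runs")

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[2]


@dataclass
class Rdm:
    """Condensed representational dissimilarity matrix."""

    conditions: tuple[str, ...]
    distances: np.ndarray  # condensed, itertools.combinations order

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(self.conditions, 2))

    @property
    def mean_distance(self) -> float:
        return float(self.distances.mean())

    def as_matrix(self) -> np.ndarray:
        n = len(self.conditions)
        mat = np.zeros((n, n))
        for (i, j), d in zip(itertools.combinations(range(n), 2), self.distances):
            mat[i, j] = mat[j, i] = d
        return mat


def shrunk_covariance(
    residuals: Sequence[np.ndarray] | np.ndarray,
    shrinkage: float | None = None,
) -> np.ndarray:
    """Residual covariance shrunk toward its diagonal.

    Residual rows are demeaned per run and pooled. With ``shrinkage=None``
    the off-diagonal shrinkage intensity is the analytic optimum of
    Schaefer & Strimmer (variance of the covariance entries over their
    squared magnitude), clipped to [0, 1]; a float fixes it explicitly
    (1.0 -> diagonal-only covariance).
    """
    if isinstance(residuals, np.ndarray) and residuals.ndim == 2:
        residuals = [residuals]
    demeaned = []
    for run in residuals:
        run = np.asarray(run, dtype=float)
        if run.ndim != 2 or run.shape[0] < 2:
            raise ValueError("each residual block needs >= 2 rows of voxels")
        demeaned.append(run - run.mean(axis=0, keepdims=True))
    x = np.vstack(demeaned)
    n = x.shape[0]
    cov = x.T @ x / (n - 1)

    zero_var = np.flatnonzero(np.diag(cov) <= 0)
    if zero_var.size:
        warnings.warn(
            f"{zero_var.size} zero-variance voxel(s) regularised", stacklevel=2
        )
        ridge = max(np.diag(cov).mean(), 1.0) * 1e-8
        cov[zero_var, zero_var] += ridge

    if shrinkage is None:
        # var of each covariance entry, from the per-sample cross products
        w = x[:, :, None] * x[:, None, :]
        var_cov = w.var(axis=0, ddof=1) * n / (n - 1) ** 2
        off = ~np.eye(cov.shape[0], dtype=bool)
        denom = (cov[off] ** 2).sum()
        shrinkage = 1.0 if denom == 0 else float(np.clip(var_cov[off].sum() / denom, 0, 1))
    elif not 0 <= shrinkage <= 1:
        raise ValueError("shrinkage must lie in [0, 1]")

    shrunk = (1.0 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
    return shrunk


def estimate_noise_precision(
    residuals: Sequence[np.ndarray] | np.ndarray,
    shrinkage: float | None = None,
) -> np.ndarray:
    """Voxel-by-voxel precision (inverse shrunk covariance), symmetrised."""
    cov = shrunk_covariance(residuals, shrinkage=shrinkage)
    precision = linalg.inv(cov)
    return 0.5 * (precision + precision.T)


def crossnobis_rdm(
    patterns: PatternSet,
    precision: np.ndarray | None = None,
    shrinkage: float | None = None,
) -> Rdm:
    """Cross-validated Mahalanobis RDM over all condition pairs.

    For each pair (i, j), the distance is the average over ordered run
    pairs (a != b) of (p_i^a - p_j^a)' P (p_i^b - p_j^b) / n_voxels, where
    P is the noise precision. Averaging over ordered pairs makes the RDM
    exactly symmetric; cross-run products make it unbiased under the null.
    """
    if precision is None:
        if patterns.residuals is None:
            raise ValueError("need either a precision matrix or residuals")
        precision = estimate_noise_precision(patterns.residuals, shrinkage=shrinkage)
    precision = np.asarray(precision, dtype=float)
    if precision.shape != (patterns.n_voxels, patterns.n_voxels):
        raise ValueError("precision matrix does not match voxel count")

    n_runs, n_cond, n_vox = patterns.patterns.shape
    pair_idx = list(itertools.combinations(range(n_cond), 2))
    # per-run matrices of pairwise pattern differences, whitened once
    deltas = np.stack(
        [
            patterns.patterns[:, i, :] - patterns.patterns[:, j, :]
            for (i, j) in pair_idx
        ],
        axis=1,
    )  # (runs, pairs, voxels)
    whitened = deltas @ precision

    total = np.zeros(len(pair_idx))
    count = 0
    for a in range(n_runs):
        for b in range(n_runs):
            if a == b:
                continue
            total += np.einsum("pv,pv->p", whitened[a], deltas[b])
            count += 1
    distances = total / (count * n_vox)
    return Rdm(conditions=tuple(patterns.conditions), distances=distances)


def mean_pairwise_distance(rdm: Rdm) -> float:
    """Arithmetic mean of all pairwise distances (the hand-ROI summary)."""
    return rdm.mean_distance
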