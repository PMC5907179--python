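"""Similarity kernels over standardized l-gram feature rows.

The scoring method uses the RBF kernel

    k(i, j) = exp(-gamma * ||x_i - x_j||^2),   gamma = 1 / (2 sigma^2),

with the bandwidth constrained to 0 < sigma < 1; identical rows give
exactly 1 and the value decays with Euclidean distance.  Linear and
degree-2 polynomial kernels are provided for comparison runs.  A
constant all-ones kernel is included as a diagnostic: it reduces the
downstream scoring to plain common-neighbour resource allocation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .features import FeatureMatrix

#: The bandwidth grid searched during parameter tuning.
SIGMA_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10))

KERNEL_KINDS = ("rbf", "linear", "polynomial", "ones")


@dataclass
class KernelParams:
    kind: str = "rbf"
    sigma: float | None = None  # rbf only, 0 < sigma < 1
    degree: int = 2  # polynomial only
    offset: float = 1.0  # polynomial only; 0 selects the homogeneous form

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")

    @property
    def gamma(self) -> float:
        if self.sigma is None:
            raise ValueError("gamma is only defined for an RBF kernel with sigma set")
        return 1.0 / (2.0 * self.sigma**2)


@dataclass
class KernelMatrix:
    entity_ids: list[str]
    values: np.ndarray  # square, symmetric


def _require_standardized(fm: FeatureMatrix) -> np.ndarray:
    if not fm.standardized:
        raise ValueError("kernels operate on standardized feature matrices")
    return fm.values


def rbf_kernel(fm: FeatureMatrix, sigma: float) -> KernelMatrix:
    """RBF similarity matrix with gamma = 1/(2 sigma^2), 0 < sigma < 1."""
    x = _require_standardized(fm)
    if not 0.0 < sigma < 1.0:
        raise ValueError(
            f"sigma must satisfy 0 < sigma < 1 (the RBF bandwidth constraint), got {sigma}"
        )
    gamma = 1.0 / (2.0 * sigma**2)
    d2 = squareform(pdist(x, metric="sqeuclidean"))
    k = np.exp(-gamma * d2)
    k = (k + k.T) / 2.0
    np.fill_diagonal(k, 1.0)
    return KernelMatrix(list(fm.entity_ids), k)


def linear_kernel(fm: FeatureMatrix) -> KernelMatrix:
    """Plain Gram matrix of row dot products."""
    x = _require_standardized(fm)
    k = x @ x.T
    return KernelMatrix(list(fm.entity_ids), (k + k.T) / 2.0)


def polynomial_kernel(fm: FeatureMatrix, degree: int = 2, offset: float = 1.0) -> KernelMatrix:
    """(x.y + offset)^degree; the inhomogeneous degree-2 form by default."""
    x = _require_standardized(fm)
    if degree < 1:
        raise ValueError(f"polynomial degree must be >= 1, got {degree}")
    k = (x @ x.T + offset) ** degree
    return KernelMatrix(list(fm.entity_ids), (k + k.T) / 2.0)


def ones_kernel(fm: FeatureMatrix) -> KernelMatrix:
    """Constant kernel of 1s (diagnostic: disables sequence weighting)."""
    n = len(fm.entity_ids)
    return KernelMatrix(list(fm.entity_ids), np.ones((n, n)))


def make_kernel(fm: FeatureMatrix, params: KernelParams) -> KernelMatrix:
    """Dispatch on :class:`KernelParams`."""
    if params.kind == "rbf":
        if params.sigma is None:
            raise ValueError("RBF kernel requires sigma")
        return rbf_kernel(fm, params.sigma)
    if params.kind == "linear":
        return linear_kernel(fm)
    if params.kind == "polynomial":
        return polynomial_kernel(fm, params.degree, params.offset)
    return ones_kernel(fm)
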